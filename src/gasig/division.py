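"""New-wall detection and division-plane orientation statistics.

Dividing cells are found by comparing segmentations at consecutive time
points through the lineage; the new wall is the shared boundary of the two
daughters, skeletonized to a polyline in the top-down projection. Its
orientation is the acute angle (0-90 degrees) between the wall's principal
direction and the radial axis from the SAM center to the wall midpoint:
90 degrees is a circumferential/transverse division, 0 a radial one.
Frequencies are tabulated in nine 10-degree bins.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from ._geometry import acute_angle_between, principal_direction_2d
from .cellseg import CellLabelMap
from .lineage import LineageMap
from .regions import RegionGeometry, classify_region

log = logging.getLogger(__name__)

ANGLE_BIN_EDGES = np.arange(0.0, 91.0, 10.0)


@dataclass
class DivisionEvent:
    """One new cell wall between consecutive time points."""

    parent: int
    children: tuple[int, int]
    wall_polyline_um: np.ndarray  # (n, 2) ordered (x, y) points
    midpoint_xy_um: tuple[float, float]
    angle_deg: float = np.nan  # acute angle to the radial axis, [0, 90]
    region: str = "unassigned"


@dataclass
class AngleHistogram:
    """Division-angle frequencies in nine 10-degree bins, in percent."""

    bin_edges: np.ndarray
    frequencies_pct: np.ndarray
    n_events: int
    cohort: str = "SAM"

    def __post_init__(self) -> None:
        if len(self.frequencies_pct) != len(self.bin_edges) - 1:
            raise ValueError("frequencies must have one entry per bin")
        if self.n_events > 0 and not np.isclose(self.frequencies_pct.sum(), 100.0):
            raise ValueError("frequencies must sum to 100%")


def detect_new_walls(
    labels_t: CellLabelMap,
    labels_t2: CellLabelMap,
    lineage: LineageMap,
) -> list[DivisionEvent]:
    """Extract new-wall geometry for every parent with >= 2 children.

    For a parent with k > 2 children (two division rounds in one interval)
    the k-1 walls are recovered by greedy sibling merging: the pair of
    child groups sharing the longest boundary corresponds to the most
    recent division; it is emitted and merged, and the procedure repeats.
    Children without a shared boundary are dropped with a log entry.
    """
    dy, dx = labels_t2.voxel_spacing_um[1:]
    events: list[DivisionEvent] = []
    for parent, children in sorted(lineage.divisions.items()):
        groups: dict[int, set[int]] = {c: {c} for c in children}
        footprints = {c: labels_t2.footprint(c) for c in children}
        pending: list[tuple[int, int, np.ndarray]] = []
        while len(groups) > 1:
            best = None
            keys = sorted(groups)
            for i, a in enumerate(keys):
                fa = np.zeros_like(footprints[children[0]])
                for m in groups[a]:
                    fa |= footprints[m]
                for b in keys[i + 1 :]:
                    fb = np.zeros_like(fa)
                    for m in groups[b]:
                        fb |= footprints[m]
                    touch = _shared_boundary(fa, fb)
                    n = int(touch.sum())
                    if best is None or n > best[0]:
                        best = (n, a, b, touch)
            n, a, b, touch = best
            if n == 0:
                log.info("detect_new_walls: children of %d share no boundary, dropped", parent)
                break
            pending.append((a, b, touch))
            groups[a] = groups[a] | groups[b]
            del groups[b]
        for a, b, touch in pending:
            poly = _skeleton_polyline(touch, (dy, dx))
            if poly is None or len(poly) < 2:
                log.info("detect_new_walls: degenerate wall for parent %d, dropped", parent)
                continue
            mid = poly[int(np.argmin(np.linalg.norm(poly - poly.mean(axis=0), axis=1)))]
            events.append(
                DivisionEvent(
                    parent=int(parent),
                    children=(int(a), int(b)),
                    wall_polyline_um=poly,
                    midpoint_xy_um=(float(mid[0]), float(mid[1])),
                )
            )
    return events


def _shared_boundary(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Pixels of footprint a 4-adjacent to footprint b, plus the converse."""
    s = ndimage.generate_binary_structure(2, 1)
    return (fa & ndimage.binary_dilation(fb, s)) | (fb & ndimage.binary_dilation(fa, s))


def _skeleton_polyline(mask: np.ndarray, spacing_yx) -> "np.ndarray | None":
    """Skeletonize a thin boundary band and order its pixels into a polyline."""
    sk = skeletonize(mask)
    if not sk.any():
        sk = mask
    yy, xx = np.nonzero(sk)
    if len(yy) == 0:
        return None
    pts = np.column_stack([xx * spacing_yx[1], yy * spacing_yx[0]])
    if len(pts) <= 2:
        return pts
    # order by walking from an endpoint to the nearest unvisited neighbour
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    neighbour_counts = np.array(
        [len(tree.query_ball_point(p, r=1.6 * max(spacing_yx))) - 1 for p in pts]
    )
    ends = np.nonzero(neighbour_counts == 1)[0]
    start = int(ends[0]) if len(ends) else 0
    order = [start]
    visited = {start}
    current = start
    while len(order) < len(pts):
        dists = np.linalg.norm(pts - pts[current], axis=1)
        dists[list(visited)] = np.inf
        nxt = int(np.argmin(dists))
        if not np.isfinite(dists[nxt]):
            break
        order.append(nxt)
        visited.add(nxt)
        current = nxt
    return pts[order]


def measure_division_angle(
    event: DivisionEvent,
    sam_center_xy_um: tuple[float, float],
    method: str = "tls",
) -> float:
    """Acute angle between the new wall and the radial axis.

    The wall direction is the total-least-squares line fit of the skeleton
    polyline (``method="chord"`` uses the endpoint-to-endpoint chord); the
    radial axis runs from the SAM center to the wall midpoint. Folded to
    [0, 90]: 90 = circumferential/transverse, 0 = radial.
    """
    poly = np.asarray(event.wall_polyline_um, dtype=float)
    if len(poly) < 2:
        raise ValueError("wall polyline needs at least two points")
    if method == "chord":
        direction = poly[-1] - poly[0]
        if np.linalg.norm(direction) == 0:
            raise ValueError("zero-length wall")
    elif method == "tls":
        direction = principal_direction_2d(poly)
    else:
        raise ValueError(f"unknown method {method!r}")
    radial = np.asarray(event.midpoint_xy_um) - np.asarray(sam_center_xy_um)
    if np.linalg.norm(radial) == 0:
        raise ValueError("SAM center coincides with the wall midpoint")
    return acute_angle_between(direction, radial)


def annotate_events(
    events: list[DivisionEvent],
    geometry: RegionGeometry,
    method: str = "tls",
) -> list[DivisionEvent]:
    """Fill angle and region class for every event (in place; returns the list)."""
    for ev in events:
        ev.angle_deg = measure_division_angle(ev, geometry.sam_center_xy_um, method=method)
        ev.region = classify_region(ev.midpoint_xy_um, geometry)
    return events


def division_histogram(
    angles_or_events, cohort: str = "SAM"
) -> AngleHistogram:
    """Frequency histogram of division angles in nine right-open 10-degree
    bins ([0,10), ..., [80,90]]; the last bin is closed so 90-degree events
    — the most informative, fully transverse class — are counted."""
    angles = np.asarray(
        [e.angle_deg for e in angles_or_events]
        if len(angles_or_events) and isinstance(angles_or_events[0], DivisionEvent)
        else angles_or_events,
        dtype=float,
    )
    if angles.size == 0:
        raise ValueError(f"empty cohort {cohort!r}")
    if np.any((angles < 0) | (angles > 90)):
        raise ValueError("angles must lie in [0, 90]")
    counts, _ = np.histogram(angles, bins=ANGLE_BIN_EDGES)
    return AngleHistogram(
        bin_edges=ANGLE_BIN_EDGES.copy(),
        frequencies_pct=100.0 * counts / counts.sum(),
        n_events=int(angles.size),
        cohort=cohort,
    )


def division_frequency(
    events: list[DivisionEvent],
    cells_per_region: dict[str, int],
    interval_h: "float | None" = None,
) -> dict[str, float]:
    """Divisions per cell per interval, by region class.

    Regions with zero cells are reported as NaN and logged, not raised.
    """
    out: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.region] = counts.get(ev.region, 0) + 1
    for region, n_cells in cells_per_region.items():
        if n_cells == 0:
            log.info("division_frequency: region %s has no cells", region)
            out[region] = float("nan")
            continue
        out[region] = counts.get(region, 0) / n_cells
    return out


def events_to_dataframe(events: list[DivisionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                parent=e.parent,
                child_a=e.children[0],
                child_b=e.children[1],
                midpoint_x_um=e.midpoint_xy_um[0],
                midpoint_y_um=e.midpoint_xy_um[1],
                angle_deg=e.angle_deg,
                region=e.region,
                n_polyline_points=len(e.wall_polyline_um),
            )
            for e in events
        ],
        columns=["parent", "child_a", "child_b", "midpoint_x_um", "midpoint_y_um",
                 "angle_deg", "region", "n_polyline_points"],
    )
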