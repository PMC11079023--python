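"""Temporal registration, cell lineage construction and surface-growth maps.

Consecutive time points of a SAM time-lapse are registered rigidly on the
cell-wall channel (3D translation + rotation about the optical axis — a
re-mounted meristem is approximately upright, so in-plane rotation is the
relevant degree of freedom). Lineages assign each cell at t+Δt to the
parent with maximal voxel overlap after registration; parents with two or
more children mark divisions. Per-parent surface growth is measured on
projected (top-down) cell footprints:

    growth intensity = (A(t+Δt) - A(t)) / (A(t) · Δt)      [1/h]

with A(t+Δt) summed over the children. Growth anisotropy compares the
principal second moments of the parent footprint with those of the union
of its children: with stretch ratios s1 >= s2 (square roots of paired
eigenvalue ratios), anisotropy = (s1 - s2) / (s1 + s2), which is 0 for
isotropic expansion or pure rotation and 1/3 for a two-fold uniaxial
stretch.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _rotate2d

from ._geometry import RigidTransform
from .cellseg import CellLabelMap
from .stack import ImageStack

log = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Raised when no credible rigid alignment is found."""


@dataclass
class LineageMap:
    """Parent -> children correspondence across one time interval."""

    transform: RigidTransform  # frame t -> frame t+Δt
    pairs: dict[int, list[int]]
    interval_h: float
    orphans: list[int] = field(default_factory=list)  # children with no parent

    def __post_init__(self) -> None:
        seen: dict[int, int] = {}
        for parent, children in self.pairs.items():
            for c in children:
                if c in seen:
                    raise ValueError(f"child {c} assigned to two parents")
                seen[c] = parent

    @property
    def divisions(self) -> dict[int, list[int]]:
        return {p: c for p, c in self.pairs.items() if len(c) >= 2}


@dataclass
class GrowthRecord:
    parent: int
    area_t_um2: float
    area_t2_um2: float
    growth_intensity_per_h: float
    anisotropy: float
    principal_direction: tuple[float, float]
    region: str = "unassigned"


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

def register_timepoints(
    stack_t: ImageStack,
    stack_t2: ImageStack,
    max_rotation_deg: float = 15.0,
    coarse_step_deg: float = 1.0,
    min_correlation: float = 0.2,
) -> RigidTransform:
    """Rigid registration of two wall-channel stacks.

    Searches rotation about z on a coarse-to-fine grid; at each candidate
    angle the in-plane translation comes from phase correlation of the
    top-down maximum projections, and the axial shift from 1D correlation
    of z mean-intensity profiles. Returns the transform mapping frame-t
    coordinates into frame-t2 coordinates; raises RegistrationError when
    the best normalised correlation stays below ``min_correlation``.
    """
    if stack_t.voxel_spacing_um != stack_t2.voxel_spacing_um:
        raise ValueError("stacks must share voxel spacing")
    dz, dy, dx = stack_t.voxel_spacing_um
    if not np.isclose(dy, dx):
        raise ValueError("square in-plane voxels required")
    a = np.asarray(stack_t.channel("wall"), dtype=np.float64)
    b = np.asarray(stack_t2.channel("wall"), dtype=np.float64)
    # mean (not max) projection: the bright outer surface saturates a max
    # projection into a featureless disc, hiding the anticlinal wall texture
    # that actually carries the rotation signal
    pa, pb = a.mean(axis=0), b.mean(axis=0)
    center_px = ((pa.shape[1] - 1) / 2.0, (pa.shape[0] - 1) / 2.0)  # (x, y)
    vb = pb - pb.mean()
    vb_norm = float(np.sqrt((vb**2).sum()))

    def score(angle: float) -> tuple[float, np.ndarray]:
        # skimage's positive rotation is clockwise in our (x, y=row) frame,
        # so our +angle maps to rotate(..., -angle)
        rot = _rotate2d(pa, -angle, center=center_px, preserve_range=True, order=1)
        shift, _, _ = phase_cross_correlation(pb, rot, upsample_factor=10)
        aligned = ndimage.shift(rot, shift, order=1)
        va = aligned - aligned.mean()
        denom = float(np.sqrt((va**2).sum())) * vb_norm
        corr = float((va * vb).sum() / denom) if denom > 0 else 0.0
        return corr, shift

    best = (-np.inf, 0.0, None)
    for ang in np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, coarse_step_deg):
        corr, shift = score(float(ang))
        if corr > best[0]:
            best = (corr, float(ang), shift)
    for ang in np.arange(best[1] - coarse_step_deg, best[1] + coarse_step_deg + 1e-9, 0.1):
        corr, shift = score(float(ang))
        if corr > best[0]:
            best = (corr, float(ang), shift)
    best_corr, angle, _ = best

    # final 3D translation by sub-voxel phase correlation at the chosen angle
    center_um = (center_px[0] * dx, center_px[1] * dy)
    rot_only = RigidTransform(rotation_deg=float(angle), center_xy_um=center_um)
    a_rot = rot_only.apply_volume(a, stack_t.voxel_spacing_um, order=1)
    shift_zyx, _, _ = phase_cross_correlation(b, a_rot, upsample_factor=10)
    transform = RigidTransform(
        translation_um=(
            float(shift_zyx[0] * dz),
            float(shift_zyx[1] * dy),
            float(shift_zyx[2] * dx),
        ),
        rotation_deg=float(angle),
        center_xy_um=center_um,
    )
    if best_corr < min_correlation:
        raise RegistrationError(
            f"registration failed: aligned correlation {best_corr:.3f} < {min_correlation}"
        )
    return transform


# --------------------------------------------------------------------------
# lineage
# --------------------------------------------------------------------------

def build_lineage(
    labels_t: CellLabelMap,
    labels_t2: CellLabelMap,
    transform: RigidTransform,
    interval_h: float,
    corrections: "pd.DataFrame | None" = None,
) -> LineageMap:
    """Assign every cell at t+Δt to the frame-t cell with maximal voxel
    overlap after applying ``transform`` to the frame-t labels.

    ``corrections`` (columns parent_label, child_label) overrides the
    automatic assignment verbatim — the hook for expert lineage curation.
    Children without any overlapping parent are reported as orphans, not
    errors.
    """
    warped = transform.apply_volume(labels_t.label_volume, labels_t.voxel_spacing_um, order=0)
    a = warped.ravel()
    b = labels_t2.label_volume.ravel()
    sel = (a > 0) & (b > 0)
    if sel.any():
        pair_ids = a[sel].astype(np.int64) * (int(b.max()) + 1) + b[sel].astype(np.int64)
        uniq, counts = np.unique(pair_ids, return_counts=True)
        parents = uniq // (int(b.max()) + 1)
        children = uniq % (int(b.max()) + 1)
    else:
        parents = children = counts = np.array([], dtype=np.int64)

    best: dict[int, tuple[int, int]] = {}
    for p, c, n in zip(parents, children, counts):
        if c not in best or n > best[c][1]:
            best[int(c)] = (int(p), int(n))
    pairs: dict[int, list[int]] = {}
    orphans = []
    for c in labels_t2.labels:
        c = int(c)
        if c in best:
            pairs.setdefault(best[c][0], []).append(c)
        else:
            orphans.append(c)
    if corrections is not None and len(corrections):
        for _, row in corrections.iterrows():
            p, c = int(row["parent_label"]), int(row["child_label"])
            for ch in pairs.values():
                if c in ch:
                    ch.remove(c)
            pairs.setdefault(p, []).append(c)
            if c in orphans:
                orphans.remove(c)
        pairs = {p: ch for p, ch in pairs.items() if ch}
    for ch in pairs.values():
        ch.sort()
    if orphans:
        log.info("build_lineage: %d orphan children without parent overlap", len(orphans))
    return LineageMap(transform=transform, pairs=pairs, interval_h=interval_h, orphans=orphans)


# --------------------------------------------------------------------------
# growth
# --------------------------------------------------------------------------

def compute_growth(
    labels_t: CellLabelMap,
    labels_t2: CellLabelMap,
    lineage: LineageMap,
    l1_only: bool = True,
    log_growth: bool = False,
) -> list[GrowthRecord]:
    """Per-parent projected-footprint growth intensity and anisotropy.

    Parent footprints are mapped through the lineage transform before the
    moment comparison so rigid drift does not masquerade as deformation.
    ``log_growth`` switches the intensity to log(A2/A1)/Δt. Parents with
    empty footprints are skipped and logged.
    """
    dy, dx = labels_t.voxel_spacing_um[1:]
    dy2, dx2 = labels_t2.voxel_spacing_um[1:]
    px1 = dy * dx
    px2 = dy2 * dx2
    l1_t = set(map(int, labels_t.cells.loc[labels_t.cells.is_l1, "label"])) if l1_only else None
    out: list[GrowthRecord] = []
    for parent, children in sorted(lineage.pairs.items()):
        if l1_t is not None and parent not in l1_t:
            continue
        fp1 = labels_t.footprint(parent)
        n1 = int(fp1.sum())
        if n1 == 0:
            log.info("compute_growth: parent %d has empty footprint, skipped", parent)
            continue
        fp2 = np.zeros(labels_t2.label_volume.shape[1:], dtype=bool)
        for c in children:
            fp2 |= labels_t2.footprint(c)
        n2 = int(fp2.sum())
        if n2 == 0:
            log.info("compute_growth: children of %d have empty footprints, skipped", parent)
            continue
        a1 = n1 * px1
        a2 = n2 * px2
        dt = lineage.interval_h
        gi = (np.log(a2 / a1) / dt) if log_growth else ((a2 - a1) / (a1 * dt))

        yy, xx = np.nonzero(fp1)
        pts1 = np.column_stack([xx * dx, yy * dy])
        pts1 = lineage.transform.apply_xy(pts1)
        yy, xx = np.nonzero(fp2)
        pts2 = np.column_stack([xx * dx2, yy * dy2])
        s1, s2, direction = _moment_stretch(pts1, pts2)
        out.append(
            GrowthRecord(
                parent=int(parent),
                area_t_um2=float(a1),
                area_t2_um2=float(a2),
                growth_intensity_per_h=float(gi),
                anisotropy=float((s1 - s2) / (s1 + s2)),
                principal_direction=(float(direction[0]), float(direction[1])),
            )
        )
    return out


def _moment_stretch(pts1: np.ndarray, pts2: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Principal stretch ratios of the linear map taking the footprint at t
    to the footprint at t+Δt, from second-moment (covariance) matching.

    Eigenvalues are paired largest-with-largest, so a pure rotation gives
    stretches (1, 1); the principal direction is the leading eigenvector of
    the child covariance.
    """
    c1 = np.cov(pts1.T) + 1e-12 * np.eye(2)
    c2 = np.cov(pts2.T) + 1e-12 * np.eye(2)
    w1, v1 = np.linalg.eigh(c1)
    w2, v2 = np.linalg.eigh(c2)
    # eigh returns ascending order; pair top-with-top
    s_major = np.sqrt(w2[1] / w1[1])
    s_minor = np.sqrt(w2[0] / w1[0])
    direction = v2[:, 1]
    if s_minor > s_major:
        s_major, s_minor = s_minor, s_major
        direction = v2[:, 0]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    return float(s_major), float(s_minor), direction


def growth_to_dataframe(records: list[GrowthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                parent=r.parent,
                area_t_um2=r.area_t_um2,
                area_t2_um2=r.area_t2_um2,
                growth_intensity_per_h=r.growth_intensity_per_h,
                anisotropy=r.anisotropy,
                dir_x=r.principal_direction[0],
                dir_y=r.principal_direction[1],
                region=r.region,
            )
            for r in records
        ],
        columns=["parent", "area_t_um2", "area_t2_um2", "growth_intensity_per_h",
                 "anisotropy", "dir_x", "dir_y", "region"],
    )
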