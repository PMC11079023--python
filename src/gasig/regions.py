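"""SAM region classification: central zone (CZ), primordia (P), inter-primordia region (IPR).

The central zone is the CLV3-marked stem-cell domain at the meristem summit;
primordia are the initiating lateral organs; the inter-primordia region is
the remaining peripheral tissue between primordia. Classification operates
on positions in the top-down (x, y) projection plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_CLASSES = ("CZ", "IPR", "P")


@dataclass(frozen=True)
class PrimordiumDisc:
    """A primordium footprint modelled as a disc in the projection plane."""

    center_xy_um: tuple[float, float]
    radius_um: float
    stage: int  # P_n stage index; P1 = youngest emerged primordium


@dataclass
class RegionGeometry:
    """Geometry needed to classify positions into CZ / P / IPR.

    ``outer_radius_um`` bounds the tissue footprint (used when rasterising
    region masks); positions outside it still classify as IPR so that
    classification is total.
    """

    sam_center_xy_um: tuple[float, float]
    cz_radius_um: float
    primordia: list[PrimordiumDisc] = field(default_factory=list)
    outer_radius_um: "float | None" = None

    def __post_init__(self) -> None:
        if self.cz_radius_um <= 0:
            raise ValueError("cz_radius_um must be positive")


def classify_region(position_xy_um, geometry: RegionGeometry) -> str:
    """Classify one (x, y) position: CZ within the CZ radius, P inside any
    primordium disc, IPR otherwise."""
    return str(classify_regions(np.asarray(position_xy_um)[np.newaxis], geometry)[0])


def classify_regions(points_xy_um: np.ndarray, geometry: RegionGeometry) -> np.ndarray:
    """Vectorised region classification of an (n, 2) array of positions."""
    pts = np.atleast_2d(np.asarray(points_xy_um, dtype=float))
    center = np.asarray(geometry.sam_center_xy_um, dtype=float)
    r = np.linalg.norm(pts - center, axis=1)
    out = np.full(len(pts), "IPR", dtype=object)
    in_p = np.zeros(len(pts), dtype=bool)
    for prim in geometry.primordia:
        d = np.linalg.norm(pts - np.asarray(prim.center_xy_um), axis=1)
        in_p |= d <= prim.radius_um
    out[in_p] = "P"
    out[r <= geometry.cz_radius_um] = "CZ"  # CZ takes precedence
    return out.astype(str)


def region_masks(
    geometry: RegionGeometry,
    shape_yx: tuple[int, int],
    spacing_yx_um: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Rasterise boolean region masks on a 2D pixel grid.

    Pixels outside ``outer_radius_um`` (when set) belong to no region, so the
    masks cover exactly the tissue footprint.
    """
    ny, nx = shape_yx
    dy, dx = spacing_yx_um
    yy, xx = np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    labels = classify_regions(pts, geometry).reshape(ny, nx)
    inside = np.ones(shape_yx, dtype=bool)
    if geometry.outer_radius_um is not None:
        cx, cy = geometry.sam_center_xy_um
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= geometry.outer_radius_um**2
    return {cls: (labels == cls) & inside for cls in REGION_CLASSES}
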