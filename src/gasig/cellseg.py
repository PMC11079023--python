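"""3D cell segmentation from the wall stain, L1 extraction and surface geometry.

Cells are segmented by seeded 3D watershed on the (smoothed) cell-wall
channel inside a tissue mask; seeds are h-minima of the wall signal.
The L1 (epidermal) layer is identified from the top-of-tissue surface,
which is also used to estimate per-cell surface curvature and the meristem
radius from incipient-primordium annotations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .stack import ImageStack

log = logging.getLogger(__name__)


@dataclass
class SegConfig:
    """Watershed segmentation parameters."""

    smooth_sigma_um: float = 1.0
    #: h-minima depth as a fraction of the wall-channel dynamic range
    h_minima_rel: float = 0.05
    #: structuring radius for closing small gaps in the tissue mask
    closing_radius_um: float = 1.0
    #: rind eroded off the mask before flooding (stain bleed / surface skin)
    core_erosion_um: float = 1.5
    #: minimum cell volume kept, µm^3
    min_cell_volume_um3: float = 20.0


@dataclass
class CellLabelMap:
    """Voxel-wise cell labels (0 = background) plus a per-cell table.

    ``cells`` columns: label, centroid z/y/x (µm), volume_um3, is_l1,
    region, l1_area_um2 (projected footprint area, filled for L1 cells).
    """

    label_volume: np.ndarray
    voxel_spacing_um: tuple[float, float, float]
    cells: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.cells["label"].to_numpy()

    def footprint(self, label: int) -> np.ndarray:
        """Projected (y, x) boolean footprint of one cell."""
        return (self.label_volume == label).any(axis=0)

    @classmethod
    def from_volume(
        cls, vol: np.ndarray, spacing: tuple[float, float, float]
    ) -> "CellLabelMap":
        """Build the per-cell table from an existing label volume
        (e.g. generator ground truth), with labels sorted by centroid."""
        vol = np.asarray(vol)
        out = cls(label_volume=vol, voxel_spacing_um=spacing, cells=_cell_table(vol, spacing))
        return out


def _cell_table(vol: np.ndarray, spacing) -> pd.DataFrame:
    labels = np.unique(vol)
    labels = labels[labels > 0]
    dz, dy, dx = spacing
    vox = dz * dy * dx
    if len(labels):
        coms = ndimage.center_of_mass(np.ones_like(vol, dtype=np.uint8), vol, labels)
        counts = ndimage.sum_labels(np.ones_like(vol, dtype=np.uint8), vol, labels)
    else:
        coms, counts = [], []
    rows = []
    for lbl, com, cnt in zip(labels, coms, counts):
        rows.append(
            dict(
                label=int(lbl),
                z_um=com[0] * dz,
                y_um=com[1] * dy,
                x_um=com[2] * dx,
                volume_um3=float(cnt) * vox,
                is_l1=False,
                region="unassigned",
                l1_area_um2=np.nan,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["label", "z_um", "y_um", "x_um", "volume_um3", "is_l1", "region", "l1_area_um2"],
    )
    return df.sort_values(["z_um", "y_um", "x_um"], kind="stable").reset_index(drop=True)


def tissue_mask(stack: ImageStack, cfg: "SegConfig | None" = None) -> np.ndarray:
    """Tissue support estimated from the wall channel: Otsu on the smoothed
    signal, small morphological closing, largest connected component.

    Holes are deliberately not filled: a single-layered dome encloses a
    signal-free cavity that is not tissue."""
    cfg = cfg or SegConfig()
    wall = np.asarray(stack.channel("wall"), dtype=np.float64)
    spacing = stack.voxel_spacing_um
    sm = ndimage.gaussian_filter(wall, sigma=[cfg.smooth_sigma_um / s for s in spacing])
    if np.ptp(sm) == 0:
        return np.zeros(wall.shape, dtype=bool)
    mask = sm > threshold_otsu(sm)
    if not mask.any():
        return mask
    mask = ndimage.binary_closing(mask, structure=_ball_structure(cfg.closing_radius_um, spacing))
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def _ball_structure(radius_um: float, spacing) -> np.ndarray:
    rz, ry, rx = (max(1, int(round(radius_um / s))) for s in spacing)
    zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (
        (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    ) <= radius_um**2


def segment_cells(stack: ImageStack, cfg: "SegConfig | None" = None) -> CellLabelMap:
    """Seeded 3D watershed on the wall channel.

    The threshold-based tissue mask overshoots the true surface by roughly
    the smoothing scale, and that thin rind of stain bleed is connected
    across cells, so flooding it lets basins crawl over the surface into
    neighbours. The watershed therefore runs on a core mask eroded by
    ``core_erosion_um`` (seeds = h-minima of the smoothed wall signal inside
    the core); the rind is then re-attached label-wise, first along the
    optical axis (consistent with the top-down projection conventions used
    throughout), then by 3D nearest distance for anything left. Output
    labels are renumbered by centroid (z, y, x) order so repeated runs are
    identical.
    """
    cfg = cfg or SegConfig()
    mask = tissue_mask(stack, cfg)
    if not mask.any():
        raise ValueError("empty tissue mask: no tissue found in the wall channel")
    wall = np.asarray(stack.channel("wall"), dtype=np.float64)
    spacing = stack.voxel_spacing_um
    sm = ndimage.gaussian_filter(wall, sigma=[cfg.smooth_sigma_um / s for s in spacing])
    h = cfg.h_minima_rel * float(np.ptp(sm[mask]))
    core = ndimage.binary_erosion(mask, structure=_ball_structure(cfg.core_erosion_um, spacing))
    if not core.any():
        core = mask
    minima = h_minima(sm, h) & core
    markers, n_seeds = ndimage.label(minima)
    if n_seeds == 0:
        raise ValueError("no watershed seeds found inside the tissue mask")
    ws = watershed(sm, markers=markers, mask=core)
    # re-attach the eroded rind: same-column nearest label first
    _, idx_z = ndimage.distance_transform_edt(
        ws == 0, sampling=(spacing[0], 1e9, 1e9), return_indices=True
    )
    out = ws[tuple(idx_z)]
    left = (out == 0) & mask
    if left.any():
        _, idx3 = ndimage.distance_transform_edt(out == 0, sampling=spacing, return_indices=True)
        out[left] = out[tuple(idx3)][left]
    out[~mask] = 0
    out = _drop_small(out, spacing, cfg.min_cell_volume_um3)
    out = _relabel_by_centroid(out)
    return CellLabelMap.from_volume(out, spacing)


def _drop_small(vol: np.ndarray, spacing, min_vol_um3: float) -> np.ndarray:
    vox = float(np.prod(spacing))
    labels, counts = np.unique(vol[vol > 0], return_counts=True)
    small = labels[counts * vox < min_vol_um3]
    if len(small):
        vol = vol.copy()
        vol[np.isin(vol, small)] = 0
    return vol


def _relabel_by_centroid(vol: np.ndarray) -> np.ndarray:
    labels = np.unique(vol)
    labels = labels[labels > 0]
    if not len(labels):
        return vol
    coms = np.array(ndimage.center_of_mass(np.ones_like(vol, dtype=np.uint8), vol, labels))
    order = np.lexsort((coms[:, 2], coms[:, 1], coms[:, 0]))
    lut = np.zeros(int(vol.max()) + 1, dtype=np.int32)
    for new, i in enumerate(order, start=1):
        lut[labels[i]] = new
    return lut[vol]


# --------------------------------------------------------------------------
# L1 extraction & surface geometry
# --------------------------------------------------------------------------

def top_surface_heightmap(labels: CellLabelMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(height z µm, owning label, validity mask) of the top tissue surface.

    For every (y, x) column the first tissue voxel seen from the top (max z)
    defines the outer epidermal surface — the natural outer boundary for a
    dome-shaped meristem imaged from above.
    """
    vol = labels.label_volume
    nz = vol.shape[0]
    fg = vol > 0
    any_col = fg.any(axis=0)
    # index of topmost tissue voxel per column
    top_idx = nz - 1 - np.argmax(fg[::-1], axis=0)
    owner = np.zeros(vol.shape[1:], dtype=vol.dtype)
    yy, xx = np.nonzero(any_col)
    owner[yy, xx] = vol[top_idx[yy, xx], yy, xx]
    height = top_idx * labels.voxel_spacing_um[0]
    return height, owner, any_col


def extract_L1(labels: CellLabelMap, min_surface_area_um2: float = 3.0) -> CellLabelMap:
    """Flag cells exposing at least ``min_surface_area_um2`` of the top
    tissue surface as L1, and record their projected footprint areas."""
    _, owner, valid = top_surface_heightmap(labels)
    dy, dx = labels.voxel_spacing_um[1:]
    px_area = dy * dx
    surf_labels, counts = np.unique(owner[valid & (owner > 0)], return_counts=True)
    exposed = dict(zip(surf_labels.tolist(), (counts * px_area).tolist()))
    cells = labels.cells.copy()
    cells["is_l1"] = [
        exposed.get(lbl, 0.0) >= min_surface_area_um2 for lbl in cells["label"]
    ]
    fp_area = {
        int(lbl): float((labels.label_volume == lbl).any(axis=0).sum() * px_area)
        for lbl in cells.loc[cells["is_l1"], "label"]
    }
    cells["l1_area_um2"] = [fp_area.get(int(lbl), np.nan) for lbl in cells["label"]]
    return CellLabelMap(labels.label_volume, labels.voxel_spacing_um, cells)


@dataclass
class SurfaceMesh:
    """Triangulated top surface with per-vertex and per-cell mean curvature.

    Vertices are (x, y, z) µm; curvature is signed so a dome convex towards
    the objective is positive (sphere of radius R -> 1/R).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_curvature: np.ndarray
    cell_curvature: dict[int, float]


def estimate_curvature(
    labels: CellLabelMap, smooth_sigma_um: float = 2.0, rim_margin_um: float = 3.0
) -> SurfaceMesh:
    """Mean curvature of the outer (top) tissue surface, averaged per L1 cell.

    The top surface height map is Gaussian-smoothed and differentiated; mean
    curvature follows the Monge-patch formula

        H = ((1+hy^2) hxx - 2 hx hy hxy + (1+hx^2) hyy) / (2 (1+hx^2+hy^2)^1.5)

    with the sign flipped so an upward-convex dome is positive. Vertices
    within ``rim_margin_um`` of the tissue rim are excluded from per-cell
    averages (one-sided derivative artefacts). A flat surface returns zero
    curvature with a warning.
    """
    height, owner, valid = top_surface_heightmap(labels)
    if not valid.any():
        raise ValueError("no tissue surface found")
    dy, dx = labels.voxel_spacing_um[1:]
    # inpaint outside-tissue pixels by nearest valid height before smoothing
    if (~valid).any():
        ind = ndimage.distance_transform_edt(
            ~valid, sampling=(dy, dx), return_distances=False, return_indices=True
        )
        height = height[tuple(ind)]
    h = ndimage.gaussian_filter(height.astype(float), sigma=(smooth_sigma_um / dy, smooth_sigma_um / dx))
    hy, hx = np.gradient(h, dy, dx)
    hyy, hyx = np.gradient(hy, dy, dx)
    _, hxx = np.gradient(hx, dy, dx)
    denom = 2.0 * (1.0 + hx**2 + hy**2) ** 1.5
    H = -((1.0 + hy**2) * hxx - 2.0 * hx * hy * hyx + (1.0 + hx**2) * hyy) / denom

    interior = ndimage.binary_erosion(
        valid, structure=_disc_structure(rim_margin_um, (dy, dx))
    )
    if np.ptp(h[valid]) < 1e-6:
        log.warning("degenerate flat surface: curvature set to zero")
        H = np.zeros_like(H)

    yy, xx = np.nonzero(valid)
    vert_index = -np.ones(valid.shape, dtype=int)
    vert_index[yy, xx] = np.arange(len(yy))
    vertices = np.column_stack([xx * dx, yy * dy, h[yy, xx]])
    curvature = H[yy, xx]
    faces = _grid_faces(valid, vert_index)

    cell_curv: dict[int, float] = {}
    use = interior[yy, xx]
    owners = owner[yy, xx]
    for lbl in np.unique(owners[owners > 0]):
        sel = (owners == lbl) & use
        if not sel.any():
            sel = owners == lbl
        cell_curv[int(lbl)] = float(curvature[sel].mean())
    return SurfaceMesh(
        vertices=vertices, faces=faces, vertex_curvature=curvature, cell_curvature=cell_curv
    )


def _disc_structure(radius_um: float, spacing_yx) -> np.ndarray:
    ry, rx = (max(1, int(round(radius_um / s))) for s in spacing_yx)
    yy, xx = np.mgrid[-ry : ry + 1, -rx : rx + 1]
    return ((yy * spacing_yx[0]) ** 2 + (xx * spacing_yx[1]) ** 2) <= radius_um**2


def _grid_faces(valid: np.ndarray, vert_index: np.ndarray) -> np.ndarray:
    """Two triangles per fully-valid 2x2 pixel quad."""
    v = valid
    q = v[:-1, :-1] & v[:-1, 1:] & v[1:, :-1] & v[1:, 1:]
    yy, xx = np.nonzero(q)
    a = vert_index[yy, xx]
    b = vert_index[yy, xx + 1]
    c = vert_index[yy + 1, xx]
    d = vert_index[yy + 1, xx + 1]
    return np.concatenate([np.column_stack([a, b, c]), np.column_stack([b, d, c])])


def sam_surface_center(mesh: SurfaceMesh) -> tuple[float, float]:
    """Geometric center of the SAM surface: centroid of the surface vertices
    projected to the top-down plane."""
    return (float(mesh.vertices[:, 0].mean()), float(mesh.vertices[:, 1].mean()))


def measure_meristem_radius(
    surface: "SurfaceMesh | None",
    i1_xy_um: tuple[float, float],
    i2_xy_um: tuple[float, float],
    center_xy_um: "tuple[float, float] | None" = None,
) -> float:
    """Meristem radius: mean top-down distance from the SAM center to the
    two incipient primordia I1 and I2 (the circle through I1/I2 centred on
    the SAM surface center). ``center_xy_um`` overrides the surface-derived
    center (expert annotation)."""
    if i1_xy_um is None or i2_xy_um is None:
        raise ValueError("I1 and I2 annotations are required")
    if center_xy_um is None:
        if surface is None:
            raise ValueError("provide either a surface mesh or an explicit center")
        center_xy_um = sam_surface_center(surface)
    c = np.asarray(center_xy_um, dtype=float)
    d1 = float(np.linalg.norm(np.asarray(i1_xy_um) - c))
    d2 = float(np.linalg.norm(np.asarray(i2_xy_um) - c))
    return 0.5 * (d1 + d2)
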