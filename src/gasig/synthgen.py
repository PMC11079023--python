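"""Synthetic shoot-apical-meristem (SAM) image generator with ground truth.

Generates multi-channel 3D stacks (cell-wall stain, ratiometric sensor,
reference, stem-cell-domain marker) of a dome-shaped L1 tissue, plus the
complete ground truth every downstream stage needs: cell label volumes,
per-nucleus true intensities, lineages, division events and rigid drift.

Model in brief
--------------
* The L1 is a single shell of thickness ``l1_thickness_um`` on a spherical
  cap. Cells are vertical prisms over a relaxed Voronoi tessellation of the
  projected cap disc, so projected footprint areas are controlled exactly.
* Each L1 cell carries one nucleus rendered as a 3D Gaussian blob. The two
  ratiometric channels are stoichiometric: sensor/reference = 3 - S(region),
  the inverse of the signaling readout S = 3 - ratio, making signaling-field
  recovery a round-trip test.
* Growth between frames is a radial area map in the projection plane with a
  piecewise-constant relative area rate (CZ rate inside the CZ radius, the
  peripheral rate outside); the dome radius inflates with the cap so the
  geometry stays valid over many frames. True per-cell area ratios and
  stretch anisotropies are recorded from the map Jacobian.
* A stated fraction of cells divides per interval; the daughter wall passes
  through the parent footprint centroid at an angle to the local radial
  direction drawn from a per-region circular (von Mises) distribution.
* A known rigid drift (xy/z translation + rotation about z) is applied
  between frames and recorded, to exercise registration.

Identical spec + seed gives bit-identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from ._geometry import RigidTransform, fold_angle
from .regions import PrimordiumDisc, RegionGeometry, classify_region, classify_regions
from .stack import ImageStack

GOLDEN_ANGLE_DEG = 137.50776405003785


def primordium_radius_um(stage: int) -> float:
    """Footprint radius of a stage-P_n primordium disc (grows with age)."""
    return 4.0 + 1.5 * stage


@dataclass
class SyntheticSAMSpec:
    """Parameters of one synthetic SAM acquisition (all lengths in µm)."""

    dome_radius_um: float = 30.0
    voxel_spacing_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    #: default density gives ~5 µm cells, matching SAM epidermis
    n_cells_l1: int = 80
    cz_radius_um: float = 8.0
    #: (azimuth deg, radial distance µm, stage index P_n)
    primordia: tuple = ((0.0, 18.0, 1), (137.5, 19.0, 2), (275.0, 20.0, 3))
    #: target signaling value per region, in [0, 3]; optional per-stage keys
    #: like "P3" override "P" for that stage.
    signaling_field: dict = field(
        default_factory=lambda: {"CZ": 1.8, "IPR": 2.5, "P": 1.0}
    )
    channel_gains: tuple[float, float] = (100.0, 100.0)  # (sensor, reference)
    noise_sigma: float = 2.0
    poisson: bool = False
    #: per-region circular law of raw division angles: region -> (mode deg, kappa)
    division_angle_params: dict = field(
        default_factory=lambda: {"CZ": (90.0, 1.0), "IPR": (90.0, 4.0), "P": (90.0, 1.0)}
    )
    #: relative projected-area growth rate per hour, per region
    growth_field: dict = field(
        default_factory=lambda: {"CZ": 0.01, "IPR": 0.03, "P": 0.03}
    )
    interval_h: float = 10.0
    seed: int = 0
    division_fraction: float = 0.15
    drift_max_translation_um: float = 5.0
    drift_max_z_um: float = 1.0
    drift_max_rotation_deg: float = 10.0
    nucleus_sigma_um: float = 1.5
    l1_thickness_um: float = 6.0
    cap_angle_deg: float = 50.0
    interior_fill: bool = False
    wall_gain: float = 200.0
    domain_gain: float = 150.0

    def __post_init__(self) -> None:
        if min(self.dome_radius_um, self.cz_radius_um, self.l1_thickness_um) <= 0:
            raise ValueError("all lengths must be positive")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        if self.cz_radius_um >= self.dome_radius_um:
            raise ValueError("cz_radius_um must be smaller than dome_radius_um")
        for key, val in self.signaling_field.items():
            if not 0.0 <= val <= 3.0:
                raise ValueError(f"signaling_field[{key!r}]={val} outside [0, 3]")
        for key, (_, kappa) in self.division_angle_params.items():
            if kappa < 0:
                raise ValueError(f"concentration for {key!r} must be >= 0")
        if not 0.0 <= self.division_fraction <= 1.0:
            raise ValueError("division_fraction must be in [0, 1]")
        if self.n_cells_l1 < 1:
            raise ValueError("need at least one L1 cell")
        # resolvability: mean cell diameter must span >= ~3 voxels
        rho = self.cap_radius_um
        diameter = 2.0 * rho / np.sqrt(self.n_cells_l1)
        if diameter < 3.0 * max(self.voxel_spacing_um[1:]):
            raise ValueError(
                f"mean cell diameter {diameter:.2f} µm is below 3 in-plane voxels; "
                "reduce n_cells_l1 or the voxel spacing"
            )

    @property
    def cap_radius_um(self) -> float:
        """Projected radius of the dome cap."""
        return self.dome_radius_um * np.sin(np.deg2rad(self.cap_angle_deg))

    def signaling_value(self, region: str, stage: "int | None" = None) -> float:
        if region == "P" and stage is not None:
            return float(self.signaling_field.get(f"P{stage}", self.signaling_field["P"]))
        return float(self.signaling_field[region])


@dataclass
class GroundTruth:
    """Everything the generator knows about one rendered frame."""

    cell_label_volume: np.ndarray
    nucleus_table: pd.DataFrame
    cell_table: pd.DataFrame
    lineage: dict[int, list[int]]  # parent label (previous frame) -> children here
    division_events: list[dict]
    sam_center_xy_um: tuple[float, float]
    clv3_centroid_xy_um: tuple[float, float]
    region_geometry: RegionGeometry
    transform: RigidTransform  # rigid drift mapping previous frame -> this frame
    growth_truth: "pd.DataFrame | None"
    dome_radius_um: float
    cap_radius_um: float

    def __post_init__(self) -> None:
        for ev in self.division_events:
            if ev["parent"] not in self.lineage:
                raise ValueError("division event parent missing from lineage")
            if not 0.0 <= ev["angle_true_deg"] <= 90.0:
                raise ValueError("true division angle outside [0, 90]")


# --------------------------------------------------------------------------
# circular division-angle law
# --------------------------------------------------------------------------

def _sample_raw_angle(mode_deg: float, kappa: float, rng: np.random.Generator) -> float:
    """Raw (unfolded) wall angle in degrees from the circular law."""
    if np.isinf(kappa):
        return float(mode_deg)
    if kappa == 0.0:
        return float(rng.uniform(0.0, 360.0))
    return float(np.degrees(rng.vonmises(np.deg2rad(mode_deg), kappa)))


def sample_division_angle(region: str, params: tuple[float, float], rng) -> float:
    """Draw one division-plane angle for ``region``, folded to [0, 90] degrees.

    ``params`` is (mode deg, concentration kappa) of a von Mises law on the
    raw wall angle; kappa = 0 gives the uniform law, kappa = inf the
    degenerate law at the mode. The folding rule maps a raw angle theta to
    min(|theta| mod 180, 180 - |theta| mod 180).
    """
    mode_deg, kappa = params
    if kappa < 0:
        raise ValueError("concentration must be >= 0")
    return float(fold_angle(_sample_raw_angle(mode_deg, kappa, rng)))


def folded_angle_cdf(angles_deg: np.ndarray, mode_deg: float, kappa: float) -> np.ndarray:
    """CDF of the folded division-angle law, evaluated numerically.

    Integrates the von Mises density on [0, 360) over the preimage of
    [0, a] under the folding rule; serves as the distributional reference
    for the generator's angle draws.
    """
    from scipy.stats import vonmises

    theta = np.linspace(0.0, 2 * np.pi, 14401)
    if kappa == 0.0:
        pdf = np.full_like(theta, 1.0 / (2 * np.pi))
    else:
        pdf = vonmises.pdf(theta, kappa, loc=np.deg2rad(mode_deg))
    t = np.degrees(theta) % 180.0
    folded = np.minimum(t, 180.0 - t)
    out = np.empty(np.size(angles_deg), dtype=float)
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    for i, ai in enumerate(a):
        out[i] = np.trapezoid(pdf * (folded <= ai), theta)
    total = np.trapezoid(pdf, theta)
    return out / total


# --------------------------------------------------------------------------
# growth map
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _RadialGrowthMap:
    """Radial area map r -> f(r) with piecewise-constant area factor.

    Area factor a_cz applies inside ``cz_radius``, a_out outside; f solves
    d(f^2)/dr = 2 a(r) r so the local projected-area scale equals a(r)
    everywhere.
    """

    cz_radius: float
    a_cz: float
    a_out: float

    def apply_r(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        inner = np.sqrt(self.a_cz) * r
        outer = np.sqrt(
            np.clip(
                self.a_cz * self.cz_radius**2 + self.a_out * (r**2 - self.cz_radius**2),
                0.0,
                None,
            )
        )
        return np.where(r <= self.cz_radius, inner, outer)

    def area_factor(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.where(r <= self.cz_radius, self.a_cz, self.a_out)

    def jacobian(self, r: float) -> tuple[float, float]:
        """(radial stretch, tangential stretch) at radius r."""
        r = float(r)
        if r == 0.0:
            s = float(np.sqrt(self.a_cz))
            return s, s
        f = float(self.apply_r(r))
        a = float(self.area_factor(r))
        return a * r / f, f / r

    def apply_points(self, pts: np.ndarray, center: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        d = pts - center
        r = np.linalg.norm(d, axis=1)
        f = self.apply_r(r)
        scale = np.divide(f, r, out=np.ones_like(r), where=r > 0)
        return center + d * scale[:, np.newaxis]


# --------------------------------------------------------------------------
# internal state & geometry planning
# --------------------------------------------------------------------------

@dataclass
class _VolumeGeometry:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    sam_center0: np.ndarray  # (x, y) of the undrifted dome axis
    z_apex: float
    rho_frames: list[float]
    radius_frames: list[float]

    @property
    def volume_center_xy(self) -> tuple[float, float]:
        _, ny, nx = self.shape
        _, dy, dx = self.spacing
        return ((nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0)


@dataclass
class _TissueState:
    seeds: np.ndarray  # (n, 2) tissue-frame xy of L1 cell centres
    labels: np.ndarray  # (n,) int labels
    interior_seeds: np.ndarray  # (m, 2)
    interior_labels: np.ndarray
    primordia: np.ndarray  # (k, 2) tissue-frame centres
    primordia_stages: list[int]
    next_label: int


_INTERIOR_DEPTH_UM = 10.0


def _growth_map(spec: SyntheticSAMSpec) -> _RadialGrowthMap:
    dt = spec.interval_h
    return _RadialGrowthMap(
        cz_radius=spec.cz_radius_um,
        a_cz=1.0 + spec.growth_field["CZ"] * dt,
        a_out=1.0 + spec.growth_field["IPR"] * dt,
    )


def _plan_geometry(spec: SyntheticSAMSpec, n_frames: int) -> _VolumeGeometry:
    gmap = _growth_map(spec)
    if gmap.a_cz <= 0.05 or gmap.a_out <= 0.05:
        raise ValueError("growth rates collapse cells below resolution")
    rho0 = spec.cap_radius_um
    rho_frames = [rho0]
    for _ in range(n_frames - 1):
        rho_frames.append(float(gmap.apply_r(rho_frames[-1])))
    radius_frames = [spec.dome_radius_um * rho / rho0 for rho in rho_frames]
    # final-frame cell size check
    diameter = 2.0 * rho_frames[-1] / np.sqrt(spec.n_cells_l1)
    if diameter < 3.0 * max(spec.voxel_spacing_um[1:]):
        raise ValueError("growth rates collapse cells below resolution")

    dz, dy, dx = spec.voxel_spacing_um
    drift_pad = spec.drift_max_translation_um * max(0, n_frames - 1)
    pad_xy = 6.0 + drift_pad
    half = rho_frames[-1] + pad_xy
    nx = int(np.ceil(2 * half / dx)) + 1
    ny = int(np.ceil(2 * half / dy)) + 1

    depth_max = spec.l1_thickness_um + (_INTERIOR_DEPTH_UM if spec.interior_fill else 0.0)
    tissue_depth = 0.0
    for rho, radius in zip(rho_frames, radius_frames):
        inner = max(radius - depth_max, 0.0)
        bottom = np.sqrt(max(inner**2 - rho**2, 0.0))
        tissue_depth = max(tissue_depth, radius - bottom)
    z_pad = 2.0 + spec.drift_max_z_um * max(0, n_frames - 1)
    z_apex = z_pad + tissue_depth
    nz = int(np.ceil((z_apex + z_pad) / dz)) + 1
    center0 = np.array([(nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0])
    return _VolumeGeometry(
        shape=(nz, ny, nx),
        spacing=(dz, dy, dx),
        sam_center0=center0,
        z_apex=z_apex,
        rho_frames=rho_frames,
        radius_frames=radius_frames,
    )


def _sunflower_disc(n: int, rho: float) -> np.ndarray:
    i = np.arange(n)
    r = rho * np.sqrt((i + 0.5) / n)
    theta = np.deg2rad(GOLDEN_ANGLE_DEG) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _relax_seeds(seeds: np.ndarray, rho: float, iterations: int = 5, px: float = 0.5) -> np.ndarray:
    """Lloyd relaxation of seed points on the disc via pixel assignment."""
    coords = np.arange(-rho, rho + px, px)
    xx, yy = np.meshgrid(coords, coords)
    inside = xx**2 + yy**2 <= rho**2
    pts = np.column_stack([xx[inside], yy[inside]])
    out = seeds.copy()
    for _ in range(iterations):
        idx = cKDTree(out).query(pts)[1]
        for j in range(len(out)):
            sel = idx == j
            if sel.any():
                out[j] = pts[sel].mean(axis=0)
        r = np.linalg.norm(out, axis=1)
        clip = r > rho - 0.5
        out[clip] *= ((rho - 0.5) / r[clip])[:, np.newaxis]
    return out


def _init_state(spec: SyntheticSAMSpec, geom: _VolumeGeometry, rng: np.random.Generator) -> _TissueState:
    rho = geom.rho_frames[0]
    n = spec.n_cells_l1
    seeds = _sunflower_disc(n, rho * 0.97)
    seeds += rng.normal(0.0, 0.15 * rho / np.sqrt(n), size=seeds.shape)
    seeds = _relax_seeds(seeds, rho)
    seeds = seeds + geom.sam_center0

    n_int = max(3, n // 8) if spec.interior_fill else 0
    interior = _sunflower_disc(n_int, rho * 0.85) + geom.sam_center0 if n_int else np.empty((0, 2))

    prim_xy = []
    stages = []
    for az, dist, stage in spec.primordia:
        a = np.deg2rad(az)
        prim_xy.append(geom.sam_center0 + dist * np.array([np.cos(a), np.sin(a)]))
        stages.append(int(stage))
    labels = np.arange(1, n + 1)
    interior_labels = np.arange(n + 1, n + n_int + 1)
    return _TissueState(
        seeds=seeds,
        labels=labels,
        interior_seeds=np.asarray(interior),
        interior_labels=interior_labels,
        primordia=np.asarray(prim_xy).reshape(-1, 2),
        primordia_stages=stages,
        next_label=n + n_int + 1,
    )


def _tissue_region_geometry(spec: SyntheticSAMSpec, state: _TissueState,
                            center: np.ndarray, rho: float) -> RegionGeometry:
    prims = [
        PrimordiumDisc(tuple(map(float, xy)), primordium_radius_um(st), st)
        for xy, st in zip(state.primordia, state.primordia_stages)
    ]
    return RegionGeometry(
        sam_center_xy_um=tuple(map(float, center)),
        cz_radius_um=spec.cz_radius_um,
        primordia=prims,
        outer_radius_um=float(rho),
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _add_blob(img: np.ndarray, pos_zyx: np.ndarray, sigma_um: float, amp: float,
              spacing: tuple[float, float, float]) -> None:
    dz, dy, dx = spacing
    nz, ny, nx = img.shape
    half = 3.0 * sigma_um
    z0, z1 = int(max(0, np.floor((pos_zyx[0] - half) / dz))), int(
        min(nz - 1, np.ceil((pos_zyx[0] + half) / dz))
    )
    y0, y1 = int(max(0, np.floor((pos_zyx[1] - half) / dy))), int(
        min(ny - 1, np.ceil((pos_zyx[1] + half) / dy))
    )
    x0, x1 = int(max(0, np.floor((pos_zyx[2] - half) / dx))), int(
        min(nx - 1, np.ceil((pos_zyx[2] + half) / dx))
    )
    if z1 < z0 or y1 < y0 or x1 < x0:
        return
    zz = (np.arange(z0, z1 + 1) * dz - pos_zyx[0]) ** 2
    yy = (np.arange(y0, y1 + 1) * dy - pos_zyx[1]) ** 2
    xx = (np.arange(x0, x1 + 1) * dx - pos_zyx[2]) ** 2
    d2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    img[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] += amp * np.exp(-d2 / (2.0 * sigma_um**2))


def _boundary_mask(vol: np.ndarray) -> np.ndarray:
    """Tissue voxels that touch a different label (or background) face-on."""
    b = np.zeros(vol.shape, dtype=bool)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        diff = vol[tuple(sl_a)] != vol[tuple(sl_b)]
        b[tuple(sl_a)] |= diff
        b[tuple(sl_b)] |= diff
    return b & (vol > 0)


def _render_frame(
    spec: SyntheticSAMSpec,
    geom: _VolumeGeometry,
    state: _TissueState,
    pose: RigidTransform,
    frame: int,
    rng: np.random.Generator,
    division_plans: list[dict],
):
    """Rasterise one frame. Returns (stack, labels, frame info dict)."""
    nz, ny, nx = geom.shape
    dz, dy, dx = geom.spacing
    rho = geom.rho_frames[frame]
    radius = geom.radius_frames[frame]
    thick = spec.l1_thickness_um

    center_f = np.asarray(pose.apply_xy(geom.sam_center0))
    zc = geom.z_apex + pose.translation_um[0] - radius

    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    r2 = (xs[None, :] - center_f[0]) ** 2 + (ys[:, None] - center_f[1]) ** 2
    inside2d = r2 <= rho**2

    posed_seeds = np.atleast_2d(pose.apply_xy(state.seeds))
    tree = cKDTree(posed_seeds)
    pts = np.column_stack([xs[None, :].repeat(ny, 0)[inside2d], ys[:, None].repeat(nx, 1)[inside2d]])
    nearest = tree.query(pts)[1]
    label2d = np.zeros((ny, nx), dtype=np.int32)
    label2d[inside2d] = state.labels[nearest]

    vol = np.zeros(geom.shape, dtype=np.int32)
    zs = np.arange(nz) * dz
    for iz, z in enumerate(zs):
        s2 = r2 + (z - zc) ** 2
        shell = (s2 <= radius**2) & (s2 >= (radius - thick) ** 2) & inside2d
        vol[iz][shell] = label2d[shell]

    if spec.interior_fill and len(state.interior_seeds):
        posed_int = np.atleast_2d(pose.apply_xy(state.interior_seeds))
        ri = np.linalg.norm(posed_int - center_f, axis=1)
        seed_rad = max(radius - thick - _INTERIOR_DEPTH_UM / 2.0, 1.0)
        zi = zc + np.sqrt(np.clip(seed_rad**2 - ri**2, 0.0, None))
        itree = cKDTree(np.column_stack([posed_int, zi]))
        inner_lo = max(radius - thick - _INTERIOR_DEPTH_UM, 0.0)
        for iz, z in enumerate(zs):
            s2 = r2 + (z - zc) ** 2
            band = (s2 < (radius - thick) ** 2) & (s2 >= inner_lo**2) & inside2d
            if not band.any():
                continue
            iy, ix = np.nonzero(band)
            q = np.column_stack([ix * dx, iy * dy, np.full(len(ix), z)])
            idx = itree.query(q)[1]
            vol[iz][band] = state.interior_labels[idx]

    # --- execute planned divisions -------------------------------------
    tissue_geom = _tissue_region_geometry(spec, state, geom.sam_center0, rho)
    events: list[dict] = []
    cancelled: set[int] = set()
    child_centroids: dict[int, np.ndarray] = {}
    for plan in division_plans:
        parent = plan["parent"]
        mask = vol == parent
        n_vox = int(mask.sum())
        if n_vox < 12:
            cancelled.add(parent)
            continue
        izv, iyv, ixv = np.nonzero(mask)
        px = ixv * dx
        py = iyv * dy
        m = np.array([px.mean(), py.mean()])
        d_hat = pose.apply_direction(plan["direction"])
        d_hat = d_hat / np.linalg.norm(d_hat)
        n_hat = np.array([-d_hat[1], d_hat[0]])
        side = (px - m[0]) * n_hat[0] + (py - m[1]) * n_hat[1] >= 0
        if side.sum() < 4 or (~side).sum() < 4:
            cancelled.add(parent)
            continue
        c1, c2 = plan["children"]
        vol[izv[side], iyv[side], ixv[side]] = c1
        vol[izv[~side], iyv[~side], ixv[~side]] = c2
        fp1 = (vol == c1).any(axis=0)
        fp2 = (vol == c2).any(axis=0)
        touch = fp1 & ndimage.binary_dilation(fp2)
        if not touch.any():
            touch = fp1 & ndimage.binary_dilation(fp2, iterations=2)
        by, bx = np.nonzero(touch)
        t = (bx * dx - m[0]) * d_hat[0] + (by * dy - m[1]) * d_hat[1]
        p_lo = m + t.min() * d_hat
        p_hi = m + t.max() * d_hat
        m_tissue = pose.inverse().apply_xy(m)
        region = classify_region(m_tissue, tissue_geom)
        events.append(
            {
                "parent": parent,
                "children": (c1, c2),
                "wall_endpoints_um": (tuple(p_lo), tuple(p_hi)),
                "midpoint_xy_um": tuple(m),
                "angle_true_deg": float(fold_angle(plan["raw_angle_deg"])),
                "raw_angle_deg": float(plan["raw_angle_deg"]),
                "region": region,
            }
        )
        for c, sel in ((c1, side), (c2, ~side)):
            cc = np.array([px[sel].mean(), py[sel].mean()])
            child_centroids[c] = np.asarray(pose.inverse().apply_xy(cc))

    # --- current cell roster (after divisions) --------------------------
    divided = {p["parent"] for p in division_plans if p["parent"] not in cancelled}
    rows = []
    inv_pose = pose.inverse()
    for lbl, seed in zip(state.labels, state.seeds):
        if lbl in divided:
            continue
        rows.append((lbl, seed, True))
    for plan in division_plans:
        if plan["parent"] in cancelled:
            continue
        for c in plan["children"]:
            rows.append((c, child_centroids[c], True))
    for lbl, seed in zip(state.interior_labels, state.interior_seeds):
        rows.append((lbl, seed, False))

    # --- channels -------------------------------------------------------
    sensor = np.zeros(geom.shape, dtype=np.float64)
    reference = np.zeros(geom.shape, dtype=np.float64)
    domain = np.zeros(geom.shape, dtype=np.float64)
    gain_s, gain_r = spec.channel_gains

    nuc_rows = []
    cell_rows = []
    for lbl, seed_tissue, is_l1 in rows:
        pos_xy = np.asarray(pose.apply_xy(seed_tissue))
        region = classify_region(seed_tissue, tissue_geom)
        stage = None
        if region == "P":
            d = np.linalg.norm(state.primordia - seed_tissue, axis=1)
            k = int(np.argmin(d))
            stage = state.primordia_stages[k]
        cell_rows.append(
            dict(label=int(lbl), x_um=float(pos_xy[0]), y_um=float(pos_xy[1]),
                 region=region, is_l1=bool(is_l1))
        )
        if not is_l1:
            continue
        rf = np.linalg.norm(pos_xy - center_f)
        z_nuc = zc + np.sqrt(max((radius - thick / 2.0) ** 2 - rf**2, 0.0))
        s_val = spec.signaling_value(region, stage)
        ratio_true = 3.0 - s_val
        amp_s = gain_s * ratio_true
        amp_r = gain_r
        pos_zyx = np.array([z_nuc, pos_xy[1], pos_xy[0]])
        _add_blob(sensor, pos_zyx, spec.nucleus_sigma_um, amp_s, geom.spacing)
        _add_blob(reference, pos_zyx, spec.nucleus_sigma_um, amp_r, geom.spacing)
        r_tissue = np.linalg.norm(seed_tissue - geom.sam_center0)
        amp_d = spec.domain_gain * np.exp(-((r_tissue / spec.cz_radius_um) ** 2))
        _add_blob(domain, pos_zyx, spec.nucleus_sigma_um, amp_d, geom.spacing)
        nuc_rows.append(
            dict(
                label=int(lbl),
                z_um=float(pos_zyx[0]),
                y_um=float(pos_zyx[1]),
                x_um=float(pos_zyx[2]),
                sensor_true=float(amp_s),
                reference_true=float(amp_r),
                ratio_true=float(ratio_true),
                signaling_true=float(s_val),
                region=region,
            )
        )

    boundary = _boundary_mask(vol)
    d_wall = ndimage.distance_transform_edt(~boundary, sampling=geom.spacing)
    wall = np.where(vol > 0, spec.wall_gain / (1.0 + (d_wall / 0.8) ** 2), 0.0)

    channels = {"wall": wall, "sensor": sensor, "reference": reference, "domain": domain}
    for name in ("wall", "sensor", "reference", "domain"):
        img = channels[name]
        if spec.poisson:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        channels[name] = img.astype(np.float32)

    stack = ImageStack(
        channels=channels,
        voxel_spacing_um=geom.spacing,
        metadata={"seed": spec.seed, "frame": frame, "generator": "gasig.synthgen"},
    )
    posed_geom = RegionGeometry(
        sam_center_xy_um=tuple(map(float, center_f)),
        cz_radius_um=spec.cz_radius_um,
        primordia=[
            PrimordiumDisc(
                tuple(map(float, pose.apply_xy(xy))), primordium_radius_um(st), st
            )
            for xy, st in zip(state.primordia, state.primordia_stages)
        ],
        outer_radius_um=float(rho),
    )
    info = dict(
        vol=vol,
        nucleus_table=pd.DataFrame(
            nuc_rows,
            columns=["label", "z_um", "y_um", "x_um", "sensor_true",
                     "reference_true", "ratio_true", "signaling_true", "region"],
        ),
        cell_table=pd.DataFrame(
            cell_rows, columns=["label", "x_um", "y_um", "region", "is_l1"]
        ),
        events=events,
        cancelled=cancelled,
        child_centroids=child_centroids,
        center_f=center_f,
        posed_geom=posed_geom,
    )
    return stack, info


# --------------------------------------------------------------------------
# public generators
# --------------------------------------------------------------------------

def generate_sam_stack(spec: SyntheticSAMSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a single synthetic SAM acquisition and its ground truth."""
    return generate_timelapse(spec, n_frames=1)[0]


def generate_timelapse(
    spec: SyntheticSAMSpec, n_frames: int = 2
) -> list[tuple[ImageStack, GroundTruth]]:
    """Render an ``n_frames`` synthetic time-lapse with growth, divisions and drift.

    Frame k's ground truth carries the lineage, division events and rigid
    drift of the interval (k-1 -> k); frame 0 has an identity transform and
    an empty lineage.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    geom = _plan_geometry(spec, n_frames)
    state = _init_state(spec, geom, rng)
    gmap = _growth_map(spec)
    pose = RigidTransform(center_xy_um=geom.volume_center_xy)
    frames: list[tuple[ImageStack, GroundTruth]] = []

    stack, info = _render_frame(spec, geom, state, pose, 0, rng, [])
    frames.append(
        (
            stack,
            _assemble_gt(info, lineage={}, transform=RigidTransform(
                center_xy_um=geom.volume_center_xy), growth_truth=None,
                geom=geom, frame=0),
        )
    )

    prev_info = info
    prev_pose = pose
    for k in range(1, n_frames):
        # growth (tissue frame). The imposed truth per cell integrates the
        # map Jacobian over the cell's current footprint, since cells that
        # straddle the CZ boundary genuinely grow at a mixture of the two
        # regional rates.
        growth_rows = []
        tissue_geom = _tissue_region_geometry(spec, state, geom.sam_center0, geom.rho_frames[k - 1])
        dz, dy, dx = geom.spacing
        inv_prev = prev_pose.inverse()
        prev_vol = prev_info["vol"]
        for lbl, seed in zip(state.labels, state.seeds):
            fp = (prev_vol == lbl).any(axis=0)
            if fp.any():
                yy, xx = np.nonzero(fp)
                pts = inv_prev.apply_xy(np.column_stack([xx * dx, yy * dy]))
                radii = np.linalg.norm(pts - geom.sam_center0, axis=1)
            else:
                radii = np.array([np.linalg.norm(seed - geom.sam_center0)])
            jac = np.array([gmap.jacobian(r) for r in radii])
            s_r = float(jac[:, 0].mean())
            s_t = float(jac[:, 1].mean())
            area_ratio = float(gmap.area_factor(radii).mean())
            growth_rows.append(
                dict(
                    parent=int(lbl),
                    region=classify_region(seed, tissue_geom),
                    area_ratio_true=area_ratio,
                    growth_intensity_true=float((area_ratio - 1.0) / spec.interval_h),
                    anisotropy_true=float(abs(s_r - s_t) / (s_r + s_t)),
                )
            )
        state.seeds = gmap.apply_points(state.seeds, geom.sam_center0)
        if len(state.interior_seeds):
            state.interior_seeds = gmap.apply_points(state.interior_seeds, geom.sam_center0)
        state.primordia = (
            gmap.apply_points(state.primordia, geom.sam_center0)
            if len(state.primordia)
            else state.primordia
        )
        growth_truth = pd.DataFrame(
            growth_rows,
            columns=["parent", "region", "area_ratio_true",
                     "growth_intensity_true", "anisotropy_true"],
        )

        # division plan (tissue frame, post-growth positions)
        tissue_geom = _tissue_region_geometry(spec, state, geom.sam_center0, geom.rho_frames[k])
        plans: list[dict] = []
        lineage: dict[int, list[int]] = {}
        u = rng.random(len(state.labels))
        for i, (lbl, seed) in enumerate(zip(state.labels, state.seeds)):
            if u[i] >= spec.division_fraction:
                lineage[int(lbl)] = [int(lbl)]
                continue
            region = classify_region(seed, tissue_geom)
            mode, kappa = spec.division_angle_params[region]
            raw = _sample_raw_angle(mode, kappa, rng)
            radial = seed - geom.sam_center0
            nr = np.linalg.norm(radial)
            radial = radial / nr if nr > 0 else np.array([1.0, 0.0])
            a = np.deg2rad(raw)
            direction = np.array(
                [
                    radial[0] * np.cos(a) - radial[1] * np.sin(a),
                    radial[0] * np.sin(a) + radial[1] * np.cos(a),
                ]
            )
            c1, c2 = state.next_label, state.next_label + 1
            state.next_label += 2
            plans.append(
                dict(parent=int(lbl), children=(c1, c2), direction=direction,
                     raw_angle_deg=raw)
            )
            lineage[int(lbl)] = [c1, c2]
        for lbl in state.interior_labels:
            lineage[int(lbl)] = [int(lbl)]

        # drift
        ang = rng.uniform(0.0, 2 * np.pi)
        tr = spec.drift_max_translation_um * np.sqrt(rng.uniform())
        tx, ty = tr * np.cos(ang), tr * np.sin(ang)
        tz = rng.uniform(-spec.drift_max_z_um, spec.drift_max_z_um)
        rot = rng.uniform(-spec.drift_max_rotation_deg, spec.drift_max_rotation_deg)
        drift = RigidTransform(
            translation_um=(float(tz), float(ty), float(tx)),
            rotation_deg=float(rot),
            center_xy_um=geom.volume_center_xy,
        )
        pose = drift.compose(pose)

        stack, info = _render_frame(spec, geom, state, pose, k, rng, plans)
        for parent in info["cancelled"]:
            lineage[parent] = [parent]
        # roster update
        divided = {p["parent"] for p in plans if p["parent"] not in info["cancelled"]}
        keep = ~np.isin(state.labels, list(divided)) if divided else np.ones(
            len(state.labels), dtype=bool
        )
        new_seeds = [state.seeds[keep]]
        new_labels = [state.labels[keep]]
        for plan in plans:
            if plan["parent"] in info["cancelled"]:
                continue
            for c in plan["children"]:
                new_seeds.append(info["child_centroids"][c][np.newaxis])
                new_labels.append(np.array([c]))
        state.seeds = np.vstack(new_seeds)
        state.labels = np.concatenate(new_labels)
        order = np.argsort(state.labels)
        state.seeds = state.seeds[order]
        state.labels = state.labels[order]

        frames.append(
            (
                stack,
                _assemble_gt(info, lineage=lineage, transform=drift,
                             growth_truth=growth_truth, geom=geom, frame=k),
            )
        )
        prev_info = info
        prev_pose = pose
    return frames


def _assemble_gt(info, lineage, transform, growth_truth, geom, frame) -> GroundTruth:
    return GroundTruth(
        cell_label_volume=info["vol"],
        nucleus_table=info["nucleus_table"],
        cell_table=info["cell_table"],
        lineage=lineage,
        division_events=info["events"],
        sam_center_xy_um=tuple(map(float, info["center_f"])),
        clv3_centroid_xy_um=tuple(map(float, info["center_f"])),
        region_geometry=info["posed_geom"],
        transform=transform,
        growth_truth=growth_truth,
        dome_radius_um=float(geom.radius_frames[frame]),
        cap_radius_um=float(geom.rho_frames[frame]),
    )


def spec_to_dict(spec: SyntheticSAMSpec) -> dict:
    """JSON-serialisable echo of a spec (for provenance sidecars)."""
    d = dataclasses.asdict(spec)
    d["primordia"] = [list(p) for p in spec.primordia]
    return d
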