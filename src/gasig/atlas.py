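"""Population-scale SAM atlas: multi-sample alignment, polar-grid averaging
and the statistical toolbox (Spearman, Kolmogorov-Smirnov, PCA, region
intensity ratios).

Individual meristems are aligned on the centroid of the stem-cell (CLV3)
domain — translation — and on the azimuth of an annotated reference
primordium — rotation — because the CLV3 domain itself is rotationally
symmetric. Aligned per-cell observations are averaged on a common polar
grid (radius x azimuth) centred on the CLV3 domain.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._geometry import PolarGrid, RigidTransform
from .regions import RegionGeometry, region_masks
from .stack import ImageStack

log = logging.getLogger(__name__)

#: quantities averaged into the atlas when present in the observations
ATLAS_QUANTITIES = ("signaling", "growth_intensity", "anisotropy", "clv3_intensity")


@dataclass
class SAMSample:
    """One quantified meristem ready for atlas alignment.

    ``observations`` needs columns x_um, y_um plus any of the atlas
    quantities; positions are in the sample's own frame. ``clv3_centroid``
    is the stem-cell-domain reference; ``ref_primordium_azimuth_deg`` the
    azimuth of the designated (youngest annotated) primordium.
    """

    sam_id: str
    observations: pd.DataFrame
    clv3_centroid_xy_um: "tuple[float, float] | None"
    ref_primordium_azimuth_deg: float = 0.0


@dataclass
class SAMAtlas:
    """Per-bin means on the polar atlas grid; bins with no data are masked."""

    grid: PolarGrid
    mean: dict[str, np.ma.MaskedArray]  # quantity -> (n_r, n_theta)
    n: np.ndarray  # observation count per bin
    n_sams: int


def align_sams(samples: list[SAMSample]) -> tuple[list[RigidTransform], pd.DataFrame]:
    """Express all samples in the common atlas frame.

    Per sample: translate the CLV3 centroid to the origin, then rotate so
    the reference primordium sits at azimuth 0. Samples without a CLV3
    reference are skipped with a log entry. Returns the per-sample
    transforms and the pooled observation table with atlas-frame
    coordinates (x_um, y_um, r_um, azimuth_deg) and a ``sam`` column.
    """
    transforms: list[RigidTransform] = []
    tables = []
    for s in samples:
        if s.clv3_centroid_xy_um is None:
            log.info("align_sams: sample %s lacks a CLV3 reference, skipped", s.sam_id)
            continue
        cx, cy = s.clv3_centroid_xy_um
        tr = RigidTransform(
            translation_um=(0.0, -cy, -cx),
            rotation_deg=-s.ref_primordium_azimuth_deg,
            center_xy_um=(cx, cy),
        )
        transforms.append(tr)
        obs = s.observations.copy()
        if {"x_um", "y_um"} - set(obs.columns):
            raise ValueError("observations need x_um and y_um columns")
        xy = tr.apply_xy(obs[["x_um", "y_um"]].to_numpy())
        obs["x_um"] = xy[:, 0]
        obs["y_um"] = xy[:, 1]
        obs["r_um"] = np.hypot(xy[:, 0], xy[:, 1])
        obs["azimuth_deg"] = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
        obs.insert(0, "sam", s.sam_id)
        tables.append(obs)
    if not tables:
        raise ValueError("no alignable samples (all lack CLV3 references)")
    pooled = pd.concat(tables, ignore_index=True)
    if "cell_id" in pooled.columns and pooled.duplicated(["sam", "cell_id"]).any():
        raise ValueError("duplicated (sam, cell) observation keys")
    return transforms, pooled


def average_map(observations: pd.DataFrame, grid: PolarGrid) -> SAMAtlas:
    """Unweighted per-bin mean of every atlas quantity across all cells of
    all samples; empty bins are masked, not zero."""
    if observations is None or len(observations) == 0:
        raise ValueError("empty observation set")
    r = observations["r_um"].to_numpy()
    th = observations["azimuth_deg"].to_numpy() % 360.0
    r_edges, t_edges = grid.r_edges, grid.theta_edges
    ri = np.clip(np.digitize(r, r_edges) - 1, 0, len(r_edges) - 2)
    ti = np.clip(np.digitize(th, t_edges) - 1, 0, len(t_edges) - 2)
    shape = (len(r_edges) - 1, len(t_edges) - 1)
    flat = ri * shape[1] + ti
    n = np.bincount(flat, minlength=shape[0] * shape[1]).reshape(shape)
    means: dict[str, np.ma.MaskedArray] = {}
    for q in ATLAS_QUANTITIES:
        if q not in observations.columns:
            continue
        v = observations[q].to_numpy(dtype=float)
        ok = np.isfinite(v)
        cnt = np.bincount(flat[ok], minlength=shape[0] * shape[1]).reshape(shape)
        tot = np.bincount(flat[ok], weights=v[ok], minlength=shape[0] * shape[1]).reshape(shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = tot / cnt
        means[q] = np.ma.masked_invalid(np.where(cnt > 0, m, np.nan))
    n_sams = observations["sam"].nunique() if "sam" in observations.columns else 1
    return SAMAtlas(grid=grid, mean=means, n=n, n_sams=int(n_sams))


def atlas_to_dataframe(atlas: SAMAtlas) -> pd.DataFrame:
    """Long-format per-bin table (one row per populated bin)."""
    r_edges, t_edges = atlas.grid.r_edges, atlas.grid.theta_edges
    rows = []
    for i in range(len(r_edges) - 1):
        for j in range(len(t_edges) - 1):
            if atlas.n[i, j] == 0:
                continue
            row = dict(
                r_lo_um=r_edges[i], r_hi_um=r_edges[i + 1],
                azimuth_lo_deg=t_edges[j], azimuth_hi_deg=t_edges[j + 1],
                n=int(atlas.n[i, j]),
            )
            for q, m in atlas.mean.items():
                row[q] = float(m[i, j]) if not m.mask[i, j] else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p). Constant input yields (nan, nan) with a warning
    rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the p-value
    is exact for small samples and asymptotic otherwise (scipy's 'auto').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def ks_critical_value(n1: int, n2: int, alpha: float = 0.01) -> float:
    """Asymptotic critical D for the two-sample KS test at level alpha."""
    c = np.sqrt(-0.5 * np.log(alpha / 2.0))
    return float(c * np.sqrt((n1 + n2) / (n1 * n2)))


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H-test across two or more groups."""
    res = sps.kruskal(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)


@dataclass
class PCAResult:
    variables: list[str]
    loadings: np.ndarray  # (n_vars, n_components)
    explained_variance_pct: np.ndarray
    scores: np.ndarray  # (n_obs, n_components)


def pca_cells(observations: pd.DataFrame, variables: list[str]) -> PCAResult:
    """PCA of z-scored per-cell variables.

    Zero-variance variables are dropped with a warning. Components are
    ordered by explained variance; each loading vector is flipped so its
    largest-magnitude entry is positive, making repeated runs bit-identical.
    """
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    X = observations[list(variables)].to_numpy(dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than variables")
    keep = []
    for j, name in enumerate(variables):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"dropping zero-variance variable {name!r}", stacklevel=2)
        else:
            keep.append(j)
    X = X[:, keep]
    names = [variables[j] for j in keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (len(Z) - 1)
    explained = 100.0 * var / var.sum()
    loadings = vt.T  # columns = components
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    return PCAResult(
        variables=names,
        loadings=loadings,
        explained_variance_pct=explained,
        scores=scores,
    )


def region_intensity_ratio(
    image: "ImageStack | np.ndarray",
    geometry: RegionGeometry,
    channel: str = "sensor",
    spacing_yx_um: "tuple[float, float] | None" = None,
) -> float:
    """Ratio of mean intensity in the IPR to the mean in the non-IPR
    (primordia excluded), over the tissue footprint in top-down projection.

    3D stacks are mean-projected along z; a 2D array is used directly, with
    ``spacing_yx_um`` pixel spacing (default 1 µm).
    """
    if isinstance(image, ImageStack):
        img = np.asarray(image.channel(channel), dtype=float).mean(axis=0)
        spacing_yx = image.voxel_spacing_um[1:]
    else:
        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=0)
        spacing_yx = spacing_yx_um or (1.0, 1.0)
    masks = region_masks(geometry, img.shape, spacing_yx)
    ipr = masks["IPR"]
    non_ipr = masks["CZ"]  # tissue minus IPR minus primordia
    if not ipr.any() or not non_ipr.any():
        raise ValueError("IPR and non-IPR regions must both be non-empty")
    return float(img[ipr].mean() / img[non_ipr].mean())
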