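"""Per-nucleus ratiometric quantification of GA signaling activity.

The biosensor expresses a GA-degradable sensor fluorophore (VENUS-tagged
mRGA) stoichiometrically with a GA-insensitive reference fluorophore
(TagBFP). Per nucleus, signaling activity is read out as

    signaling = 3 - sensor_mean / reference_mean

so that high GA signaling (strong sensor degradation) gives values near 3
and absent signaling gives values near 0. Detection runs on the reference
channel, which is present in every nucleus regardless of signaling level.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import blob_log
from skimage.filters import threshold_otsu

from .stack import ImageStack

log = logging.getLogger(__name__)


@dataclass
class NucleusRecord:
    """One detected nucleus and its ratiometric readout."""

    id: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    sensor_mean: float = np.nan
    reference_mean: float = np.nan
    ratio: float = np.nan
    signaling: float = np.nan
    region: str = "unassigned"
    out_of_range: bool = False  # signaling outside [0, 3]


@dataclass
class QuantConfig:
    """Detection and aggregation parameters (micrometres unless noted)."""

    detection_scale_range_um: tuple[float, float] = (1.0, 2.5)
    min_blob_distance_um: float = 2.5
    background_percentile: float = 5.0
    aggregation_radius_um: float = 2.0
    min_reference: "float | None" = None  # None -> 3 x background MAD
    detection_threshold: float = 0.05  # on the max-normalised LoG response
    iso_spacing_um: float = 1.0  # isotropic resampling pitch for detection

    def __post_init__(self) -> None:
        lo, hi = self.detection_scale_range_um
        if not 0 < lo <= hi:
            raise ValueError("detection scales must be positive and ordered")
        if min(self.min_blob_distance_um, self.aggregation_radius_um, self.iso_spacing_um) <= 0:
            raise ValueError("distances must be positive")


def detect_nuclei(stack: ImageStack, cfg: "QuantConfig | None" = None) -> list[NucleusRecord]:
    """Detect nuclei on the reference channel by multi-scale LoG blob detection.

    The stack is resampled to isotropic spacing first; centroids are
    reported in physical µm in the original frame, sorted by (z, y, x).
    An empty or flat image yields an empty list.
    """
    cfg = cfg or QuantConfig()
    ref = np.asarray(stack.channel("reference"), dtype=np.float64)
    if not np.any(ref > 0) or np.ptp(ref) == 0:
        return []
    iso = cfg.iso_spacing_um
    img = _resample_isotropic(ref, stack.voxel_spacing_um, iso)
    vmax = img.max()
    if vmax <= 0:
        return []
    img = img / vmax

    sig_lo, sig_hi = (s / iso for s in cfg.detection_scale_range_um)
    blobs = blob_log(
        img,
        min_sigma=sig_lo,
        max_sigma=sig_hi,
        num_sigma=4,
        threshold=cfg.detection_threshold,
    )
    if blobs.size == 0:
        return []
    centers = blobs[:, :3] * iso  # physical µm
    # responses for merge priority: image value at the blob centre
    idx = np.clip(np.round(blobs[:, :3]).astype(int), 0, np.array(img.shape) - 1)
    strength = img[idx[:, 0], idx[:, 1], idx[:, 2]]
    keep = _merge_close(centers, strength, cfg.min_blob_distance_um)
    centers = centers[keep]
    centers = np.array(
        [_refine_centroid(ref, c, stack.voxel_spacing_um) for c in centers]
    ).reshape(-1, 3)
    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))
    centers = centers[order]
    return [
        NucleusRecord(id=i, centroid_um=tuple(map(float, c))) for i, c in enumerate(centers)
    ]


def _resample_isotropic(img: np.ndarray, spacing, iso: float) -> np.ndarray:
    """Linear resampling onto an isotropic grid physically aligned at the origin."""
    if all(abs(s - iso) < 1e-9 for s in spacing):
        return img
    extents = [(n - 1) * s for n, s in zip(img.shape, spacing)]
    axes = [np.arange(0.0, e + 1e-9, iso) / s for e, s in zip(extents, spacing)]
    grids = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(img, np.stack(grids), order=1, mode="nearest")


def _refine_centroid(
    img: np.ndarray, center_um: np.ndarray, spacing, radius_um: float = 2.0, n_iter: int = 3
) -> np.ndarray:
    """Iterated intensity center-of-mass in a small ball around the detection."""
    spacing = np.asarray(spacing, dtype=float)
    c = np.asarray(center_um, dtype=float)
    for _ in range(n_iter):
        sel = _sphere_indices(c, radius_um, img.shape, spacing)
        if sel is None:
            return c
        w = np.clip(img[sel], 0.0, None)
        total = w.sum()
        if total <= 0:
            return c
        c = np.array([(g * s * w).sum() / total for g, s in zip(sel, spacing)])
    return c


def _merge_close(centers: np.ndarray, strength: np.ndarray, min_dist: float) -> np.ndarray:
    """Greedy suppression: keep the strongest of any pair closer than min_dist."""
    order = np.argsort(-strength)
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(centers[i] - centers[j]) >= min_dist for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def estimate_background(
    stack: ImageStack, channel: str, cfg: "QuantConfig | None" = None
) -> tuple[float, float]:
    """(background level, background MAD) of a channel over non-tissue voxels.

    Non-tissue voxels come from the wall channel (below Otsu of its smoothed
    version) when present, otherwise from the channel itself. The level is
    the configured percentile of those voxels.
    """
    cfg = cfg or QuantConfig()
    img = np.asarray(stack.channel(channel), dtype=np.float64)
    probe_role = "wall" if stack.has_channel("wall") else channel
    probe = np.asarray(stack.channel(probe_role), dtype=np.float64)
    sm = ndimage.gaussian_filter(probe, sigma=[1.5 / s for s in stack.voxel_spacing_um])
    if np.ptp(sm) == 0:
        non_tissue = np.ones(img.shape, dtype=bool)
    else:
        non_tissue = sm < threshold_otsu(sm)
    if not non_tissue.any():
        non_tissue = np.ones(img.shape, dtype=bool)
    vals = img[non_tissue]
    level = float(np.percentile(vals, cfg.background_percentile))
    mad = float(np.median(np.abs(vals - np.median(vals))))
    return level, mad


def measure_intensities(
    stack: ImageStack,
    nuclei: list[NucleusRecord],
    cfg: "QuantConfig | None" = None,
) -> tuple[list[NucleusRecord], dict]:
    """Fill background-subtracted sensor/reference means over spheres around
    each detected centroid, and compute ratio and signaling.

    Records whose reference mean falls below ``min_reference`` (default:
    3 x the background MAD of the reference channel) or whose aggregation
    sphere lies fully outside the image are dropped and counted in the
    returned QC dict.
    """
    cfg = cfg or QuantConfig()
    qc = {"n_detected": len(nuclei), "n_dropped_low_reference": 0, "n_dropped_outside": 0}
    sensor = np.asarray(stack.channel("sensor"), dtype=np.float64)
    reference = np.asarray(stack.channel("reference"), dtype=np.float64)
    bg_s, _ = estimate_background(stack, "sensor", cfg)
    bg_r, mad_r = estimate_background(stack, "reference", cfg)
    min_ref = cfg.min_reference if cfg.min_reference is not None else 3.0 * mad_r
    qc["background"] = {"sensor": bg_s, "reference": bg_r}
    qc["min_reference"] = float(min_ref)

    spacing = np.asarray(stack.voxel_spacing_um)
    out: list[NucleusRecord] = []
    for rec in nuclei:
        sel = _sphere_indices(rec.centroid_um, cfg.aggregation_radius_um, stack.shape, spacing)
        if sel is None:
            qc["n_dropped_outside"] += 1
            continue
        s_mean = float(sensor[sel].mean()) - bg_s
        r_mean = float(reference[sel].mean()) - bg_r
        if r_mean < min_ref:
            qc["n_dropped_low_reference"] += 1
            continue
        ratio = s_mean / r_mean
        signaling = compute_signaling(ratio)
        out.append(
            replace(
                rec,
                sensor_mean=s_mean,
                reference_mean=r_mean,
                ratio=ratio,
                signaling=signaling,
                out_of_range=not (0.0 <= signaling <= 3.0),
            )
        )
    qc["n_kept"] = len(out)
    if qc["n_dropped_low_reference"] or qc["n_dropped_outside"]:
        log.info("measure_intensities dropped %d low-reference and %d outside records",
                 qc["n_dropped_low_reference"], qc["n_dropped_outside"])
    return out, qc


def _sphere_indices(center_um, radius_um, shape, spacing) -> "tuple | None":
    lo = np.floor((np.asarray(center_um) - radius_um) / spacing).astype(int)
    hi = np.ceil((np.asarray(center_um) + radius_um) / spacing).astype(int)
    if np.any(hi < 0) or np.any(lo >= np.asarray(shape)):
        return None
    lo = np.clip(lo, 0, np.asarray(shape) - 1)
    hi = np.clip(hi, 0, np.asarray(shape) - 1)
    grids = np.meshgrid(
        *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
    )
    d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, spacing, center_um)))
    inside = d2 <= radius_um**2
    if not inside.any():
        return None
    return tuple(g[inside] for g in grids)


def compute_signaling(ratio: float) -> float:
    """GA signaling activity: 3 minus the sensor/reference intensity ratio.

    Values outside [0, 3] are returned unclipped — a value below 0 (ratio
    above 3) indicates miscalibration and is flagged at the record level
    rather than silently hidden.
    """
    ratio = float(ratio)
    if not np.isfinite(ratio):
        raise ValueError(f"ratio must be finite, got {ratio}")
    return 3.0 - ratio


def standardize_ratios(records: list[NucleusRecord]) -> list[NucleusRecord]:
    """Divide each ratio by the per-image mean ratio so the standardized
    distribution is centred on 1; signaling is recomputed from the
    standardized ratio. Raises if the mean ratio is not positive."""
    if not records:
        raise ValueError("no records to standardize")
    ratios = np.array([r.ratio for r in records], dtype=float)
    mean = float(ratios.mean())
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"per-image mean ratio must be positive, got {mean}")
    out = []
    for rec in records:
        ratio = rec.ratio / mean
        signaling = compute_signaling(ratio)
        out.append(
            replace(rec, ratio=ratio, signaling=signaling,
                    out_of_range=not (0.0 <= signaling <= 3.0))
        )
    return out


def records_to_dataframe(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                id=r.id,
                z_um=r.centroid_um[0],
                y_um=r.centroid_um[1],
                x_um=r.centroid_um[2],
                sensor_mean=r.sensor_mean,
                reference_mean=r.reference_mean,
                ratio=r.ratio,
                signaling=r.signaling,
                region=r.region,
                out_of_range=r.out_of_range,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["id", "z_um", "y_um", "x_um", "sensor_mean", "reference_mean",
                 "ratio", "signaling", "region", "out_of_range"],
    )
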