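"""Rigid transforms and small geometric helpers shared across the pipeline.

World coordinates are physical micrometres. Volumes are indexed (z, y, x)
with voxel (iz, iy, ix) located at (iz*dz, iy*dy, ix*dx). Planar points are
(x, y) pairs; rotations are about the optical (z) axis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def rotation_matrix_2d(angle_deg: float) -> np.ndarray:
    """Counter-clockwise rotation matrix acting on (x, y) column points."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: rotation about the z axis, then translation.

    Maps source-frame coordinates to target-frame coordinates:

        (x', y') = R(rotation_deg) @ ((x, y) - center_xy) + center_xy + (tx, ty)
        z'       = z + tz

    Parameters
    ----------
    translation_um : (tz, ty, tx) in micrometres.
    rotation_deg : rotation about z, counter-clockwise in the (x, y) plane.
    center_xy_um : (x, y) pivot of the rotation, micrometres.
    """

    translation_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0
    center_xy_um: tuple[float, float] = (0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and all(t == 0.0 for t in self.translation_um)

    def apply_xy(self, pts: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array (or single pair) of (x, y) points."""
        single = np.ndim(pts) == 1
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center_xy_um, dtype=float)
        out = (pts - c) @ rotation_matrix_2d(self.rotation_deg).T + c
        out[:, 0] += self.translation_um[2]
        out[:, 1] += self.translation_um[1]
        return out[0] if single else out

    def apply_direction(self, d: np.ndarray) -> np.ndarray:
        """Rotate an (x, y) direction vector (no translation)."""
        return rotation_matrix_2d(self.rotation_deg) @ np.asarray(d, dtype=float)

    def inverse(self) -> "RigidTransform":
        tz = -self.translation_um[0]
        cand = RigidTransform(rotation_deg=-self.rotation_deg, center_xy_um=self.center_xy_um)
        # pick the xy translation that sends the forward image of the origin back
        probe = np.array([0.0, 0.0])
        residual = probe - cand.apply_xy(self.apply_xy(probe))
        return RigidTransform(
            translation_um=(tz, float(residual[1]), float(residual[0])),
            rotation_deg=-self.rotation_deg,
            center_xy_um=self.center_xy_um,
        )

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return self ∘ first (apply ``first``, then ``self``)."""
        rot = self.rotation_deg + first.rotation_deg
        cand = RigidTransform(rotation_deg=rot, center_xy_um=self.center_xy_um)
        probe = np.array([0.0, 0.0])
        delta = self.apply_xy(first.apply_xy(probe)) - cand.apply_xy(probe)
        tz = self.translation_um[0] + first.translation_um[0]
        return RigidTransform(
            translation_um=(tz, float(delta[1]), float(delta[0])),
            rotation_deg=rot,
            center_xy_um=self.center_xy_um,
        )

    def apply_volume(
        self,
        vol: np.ndarray,
        spacing: tuple[float, float, float],
        order: int = 0,
        cval: float = 0.0,
    ) -> np.ndarray:
        """Resample ``vol`` (z, y, x) so the result shows the transformed scene.

        Requires square in-plane voxels (dy == dx) since the rotation is about
        z. ``order=0`` preserves integer labels.
        """
        dz, dy, dx = spacing
        if not np.isclose(dy, dx):
            raise ValueError("apply_volume requires square in-plane voxels")
        theta = np.deg2rad(self.rotation_deg)
        c, s = np.cos(theta), np.sin(theta)
        # affine_transform computes input_vox = m @ output_vox + offset, i.e. the
        # inverse map. Inverse: u = R(-theta) @ (v - c - t) + c in (y, x) voxels.
        # World CCW rotation by -theta acts on (y, x) index pairs as
        # [[cos, -sin], [sin, cos]] evaluated at theta (sign worked out from
        # x' = cx - sy, y' = sx + cy).
        m = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        pivot = np.array([0.0, self.center_xy_um[1] / dy, self.center_xy_um[0] / dx])
        t_vox = np.array(
            [
                self.translation_um[0] / dz,
                self.translation_um[1] / dy,
                self.translation_um[2] / dx,
            ]
        )
        offset = pivot - m @ (pivot + t_vox)
        return ndimage.affine_transform(
            vol, m, offset=offset, order=order, cval=cval, mode="constant", prefilter=False
        )


def fold_angle(angle_deg) -> "np.ndarray | float":
    """Fold a raw line angle to the acute range [0, 90] degrees.

    A line is direction-free, so its angle is defined modulo 180; the acute
    representative is min(t, 180 - t) with t = |angle| mod 180.
    """
    t = np.abs(np.asarray(angle_deg, dtype=float)) % 180.0
    out = np.minimum(t, 180.0 - t)
    if np.ndim(angle_deg) == 0:
        return float(out)
    return out


def acute_angle_between(d: np.ndarray, u: np.ndarray) -> float:
    """Acute angle in degrees between two planar directions."""
    d = np.asarray(d, dtype=float)
    u = np.asarray(u, dtype=float)
    nd, nu = np.linalg.norm(d), np.linalg.norm(u)
    if nd == 0 or nu == 0:
        raise ValueError("zero-length direction")
    cosang = abs(float(np.dot(d, u)) / (nd * nu))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def principal_direction_2d(points: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction of an (n, 2) point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two points for a line fit")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


@dataclass(frozen=True)
class PolarGrid:
    """Polar binning (radius x azimuth) for the population atlas frame."""

    r_max_um: float
    dr_um: float = 2.0
    dtheta_deg: float = 5.0

    @property
    def r_edges(self) -> np.ndarray:
        n = max(1, int(np.ceil(self.r_max_um / self.dr_um - 1e-9)))
        return np.linspace(0.0, n * self.dr_um, n + 1)

    @property
    def theta_edges(self) -> np.ndarray:
        n = max(1, int(round(360.0 / self.dtheta_deg)))
        return np.linspace(0.0, 360.0, n + 1)
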