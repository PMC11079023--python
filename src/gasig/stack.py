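"""Multi-channel 3D image container and OME-TIFF I/O.

An :class:`ImageStack` bundles the channels of one confocal acquisition of a
shoot apical meristem (SAM): a cell-wall stain (PI-like), the GA-sensitive
sensor channel (VENUS-like), the GA-insensitive reference channel
(TagBFP-like) and optionally a stem-cell-domain marker (pCLV3-driven
nuclear reporter). Channels share one voxel grid; spacing is physical
micrometres in (z, y, x) order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: canonical channel order used when writing multi-channel files
CHANNEL_ORDER = ("wall", "sensor", "reference", "domain")


@dataclass
class ImageStack:
    """A multi-channel 3D voxel grid with physical spacing and channel roles.

    Parameters
    ----------
    channels : dict mapping role -> 3D float array (z, y, x)
        Recognised roles: ``wall``, ``sensor``, ``reference``, ``domain``.
    voxel_spacing_um : (dz, dy, dx) in micrometres.
    metadata : free-form provenance (generator spec echo, seed, ...).
    """

    channels: dict[str, np.ndarray]
    voxel_spacing_um: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def has_channel(self, role: str) -> bool:
        return role in self.channels

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"stack has no {role!r} channel (present: {sorted(self.channels)})"
            ) from None

    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_spacing_um
        return float(dz * dy * dx)

    # ------------------------------------------------------------------ I/O
    def write_ome_tiff(self, path: str | Path) -> None:
        """Write channels as an OME-TIFF (axes CZYX, channel names = roles)."""
        roles = [r for r in CHANNEL_ORDER if r in self.channels]
        roles += [r for r in self.channels if r not in roles]
        data = np.stack([np.asarray(self.channels[r], dtype=np.float32) for r in roles])
        dz, dy, dx = self.voxel_spacing_um
        tifffile.imwrite(
            str(path),
            data,
            ome=True,
            metadata={
                "axes": "CZYX",
                "Channel": {"Name": list(roles)},
                "PhysicalSizeZ": dz,
                "PhysicalSizeY": dy,
                "PhysicalSizeX": dx,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
            },
        )

    @classmethod
    def read_tiff(
        cls,
        path: str | Path,
        channel_roles: "list[str] | None" = None,
        voxel_spacing_um: "tuple[float, float, float] | None" = None,
    ) -> "ImageStack":
        """Read a TIFF/OME-TIFF stack.

        Channel names and physical voxel sizes are taken from OME metadata
        when present; ``channel_roles`` / ``voxel_spacing_um`` override or
        supply them for plain TIFFs.
        """
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            names: list[str] | None = None
            spacing = voxel_spacing_um
            if tf.ome_metadata:
                names, meta_spacing = _parse_ome(tf.ome_metadata)
                if spacing is None:
                    spacing = meta_spacing
        data = np.asarray(data, dtype=np.float32)
        if "C" not in axes:
            data = data[np.newaxis]
            axes = "C" + axes
        order = [axes.index(a) for a in "CZYX" if a in axes]
        data = np.transpose(data, order)
        if data.ndim == 3:  # single z-plane: promote to (C, 1, Y, X)
            data = data[:, np.newaxis]
        if channel_roles is not None:
            names = list(channel_roles)
        if names is None or len(names) != data.shape[0]:
            names = list(CHANNEL_ORDER[: data.shape[0]])
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
        return cls(
            channels={n: data[i] for i, n in enumerate(names)},
            voxel_spacing_um=tuple(float(s) for s in spacing),
        )


def _parse_ome(ome_xml: str) -> tuple["list[str] | None", "tuple[float, float, float] | None"]:
    """Best-effort extraction of channel names and voxel sizes from OME-XML."""
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pix is None:
        return None, None
    names = [
        ch.get("Name") or f"channel{i}"
        for i, ch in enumerate(pix.findall("ome:Channel", ns) if ns else pix.findall("Channel"))
    ]
    try:
        spacing = (
            float(pix.get("PhysicalSizeZ", "nan")),
            float(pix.get("PhysicalSizeY", "nan")),
            float(pix.get("PhysicalSizeX", "nan")),
        )
        if any(np.isnan(spacing)):
            spacing = None
    except (TypeError, ValueError):
        spacing = None
    return (names or None), spacing
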