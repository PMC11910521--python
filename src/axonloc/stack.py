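"""Multi-channel 3D image container with physical voxel sizes."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A multi-channel voxel grid with physical voxel dimensions.

    Parameters
    ----------
    channels
        Mapping of channel name to a non-negative ``(z, y, x)`` intensity
        array. All channels must share one shape.
    voxel_xy
        Lateral voxel size in μm (isotropic in x and y).
    voxel_z
        Axial (z-step) voxel size in μm.

    Physical positions are voxel centers: voxel index ``i`` along an axis
    with voxel size ``v`` sits at ``(i + 0.5) * v`` μm.
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_xy: float = 0.07
    voxel_z: float = 0.25

    def __post_init__(self) -> None:
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        for ch, shape in shapes.items():
            if len(shape) != 3 or min(shape) < 1:
                raise ValueError(f"channel {ch!r} must be a 3D (z,y,x) array")
        if len({s for s in shapes.values()}) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, a in self.channels.items():
            a = np.asarray(a, dtype=np.float32)
            if np.any(a < 0):
                raise ValueError(f"channel {ch!r} has negative intensities")
            self.channels[ch] = a

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def physical_extent(self) -> tuple[float, float, float]:
        """Stack extent in μm as ``(x, y, z)``."""
        nz, ny, nx = self.shape
        return nx * self.voxel_xy, ny * self.voxel_xy, nz * self.voxel_z

    def voxel_of(self, positions_um: np.ndarray) -> np.ndarray:
        """Map μm positions ``(n, 3)`` of ``(x, y, z)`` to voxel indices ``(n, 3)`` of ``(z, y, x)``."""
        p = np.atleast_2d(np.asarray(positions_um, dtype=float))
        ix = np.floor(p[:, 0] / self.voxel_xy).astype(int)
        iy = np.floor(p[:, 1] / self.voxel_xy).astype(int)
        iz = np.floor(p[:, 2] / self.voxel_z).astype(int)
        return np.column_stack([iz, iy, ix])

    def voxel_center(self, voxels: np.ndarray) -> np.ndarray:
        """Map voxel indices ``(n, 3)`` of ``(z, y, x)`` to μm centers ``(n, 3)`` of ``(x, y, z)``."""
        v = np.atleast_2d(np.asarray(voxels, dtype=float))
        x = (v[:, 2] + 0.5) * self.voxel_xy
        y = (v[:, 1] + 0.5) * self.voxel_xy
        z = (v[:, 0] + 0.5) * self.voxel_z
        return np.column_stack([x, y, z])

    # ---- TIFF I/O -------------------------------------------------------
    def save_tiff(self, path) -> None:
        """Write as a multi-page TIFF, one series page block per channel."""
        data = np.stack([self.channels[ch] for ch in self.channel_names])
        meta = {
            "channel_names": self.channel_names,
            "voxel_xy_um": self.voxel_xy,
            "voxel_z_um": self.voxel_z,
            "axes": "CZYX",
        }
        tifffile.imwrite(path, data.astype(np.float32), description=json.dumps(meta))

    @classmethod
    def load_tiff(cls, path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if data.ndim == 3:
            data = data[None]
        channels = dict(zip(meta["channel_names"], data))
        return cls(channels=channels, voxel_xy=meta["voxel_xy_um"], voxel_z=meta["voxel_z_um"])
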