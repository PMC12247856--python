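"""Core volumetric data model.

All image data is held as :class:`VoxelGrid` objects in a fixed ``(z, y, x)``
axis order with anisotropic physical voxel spacing in nanometres.  Physical
quantities are carried in nm internally; derived measurements (volumes, areas)
are reported in µm³ / µm² by downstream modules.  Voxel centres sit at integer
multiples of the spacing (0-based, voxel-centre convention), which is also the
convention used when extracting iso-surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VoxelGrid",
    "SegmentationParams",
    "LocalizationCutoffs",
    "DEFAULT_CHANNEL_PARAMS",
    "load_stack",
    "save_stack",
    "physical_coords",
]


@dataclass
class VoxelGrid:
    """One channel's 3D intensity array with physical anisotropic spacing.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Non-negative intensities.
    spacing : (dz, dy, dx)
        Voxel pitch in nm; all components strictly positive.
    channel : str
        Channel label (e.g. ``"dapi"``, ``"lamin"``, ``"psyn"``).
    bit_depth : int
        Nominal acquisition bit depth (metadata only).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (300.0, 65.0, 65.0)
    channel: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (z, y, x), got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"each axis must have >= 2 voxels, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.number) and self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_nm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return replace(self, data=data)


@dataclass
class SegmentationParams:
    """Intensity-thresholding parameters for one channel.

    ``absolute`` mode keeps voxels inside the closed band
    ``[threshold_low, threshold_high]`` after Gaussian pre-smoothing at scale
    ``grain_um``; ``local_contrast`` subtracts a rolling-background estimate
    first and thresholds the residual at ``background_subtraction``.
    """

    mode: str = "absolute"  # "absolute" | "local_contrast"
    threshold_low: float = 0.0
    threshold_high: float = np.inf
    grain_um: float = 0.1
    background_subtraction: float = 0.0
    #: edge length (µm) of the box used for the local-contrast background
    #: estimate; must exceed the diameter of the structures to keep
    background_box_um: float = 8.0
    min_voxels: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "local_contrast"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")
        if not self.threshold_low < self.threshold_high:
            raise ValueError("threshold_low must be < threshold_high")
        if self.grain_um < 0:
            raise ValueError("grain_um must be >= 0")
        if self.min_voxels < 0:
            raise ValueError("min_voxels must be >= 0")


#: Channel defaults used by the murine-tissue analysis workflow: absolute
#: intensity bands for lamin and phospho-synuclein, background-subtracted
#: local contrast for DAPI, and a separate band for human-tissue pathology.
DEFAULT_CHANNEL_PARAMS: dict[str, SegmentationParams] = {
    "lamin": SegmentationParams("absolute", 929.58, 6042.27, grain_um=0.15),
    "psyn": SegmentationParams("absolute", 251.685, 868.0, grain_um=0.1),
    "psyn_human": SegmentationParams("absolute", 1385.42, 7707.77, grain_um=0.0378),
    "dapi": SegmentationParams("local_contrast", grain_um=0.095, background_subtraction=25.5,
                               threshold_low=0.0, threshold_high=np.inf),
}


@dataclass(frozen=True)
class LocalizationCutoffs:
    """Minimum penetration depths (nm) required to call a structure nuclear.

    Defaults are twice the lateral (~120 nm) and axial (~300 nm) resolution of
    the acquisition, so that a call is conservative with respect to surface
    overlap error: 240 nm in-plane, 600 nm along the optical axis.
    """

    lateral_nm: float = 240.0
    axial_nm: float = 600.0

    def __post_init__(self) -> None:
        if self.lateral_nm <= 0 or self.axial_nm <= 0:
            raise ValueError("cutoffs must be positive")
        if self.axial_nm < self.lateral_nm:
            raise ValueError("axial cutoff must be >= lateral cutoff")


def load_stack(
    path: str | Path,
    spacing: Sequence[float] = (300.0, 65.0, 65.0),
    channel_names: Sequence[str] | None = None,
) -> list[VoxelGrid]:
    """Read a single- or multi-channel TIFF/OME-TIFF into VoxelGrids.

    Axis order is normalised to ``(z, y, x)``.  A 4D array is interpreted as
    channel-first ``(c, z, y, x)`` unless axis 1 (and not axis 0) matches
    ``len(channel_names)``, in which case ``(z, c, y, x)`` is assumed.
    ``spacing`` overrides any file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")

    if arr.ndim == 3:
        channels = [arr]
    elif arr.ndim == 4:
        n = len(channel_names) if channel_names else arr.shape[0]
        if arr.shape[0] == n:
            channels = [arr[c] for c in range(arr.shape[0])]
        elif arr.shape[1] == n:
            channels = [arr[:, c] for c in range(arr.shape[1])]
        else:
            raise ValueError(
                f"cannot locate a channel axis of size {n} in array shape {arr.shape}"
            )
    else:
        raise ValueError(f"expected 3D or 4D TIFF, got ndim={arr.ndim}")

    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(len(channels))]
    if len(channel_names) != len(channels):
        raise ValueError(
            f"channel count mismatch: file has {len(channels)}, names give {len(channel_names)}"
        )
    bit_depth = arr.dtype.itemsize * 8
    return [
        VoxelGrid(ch, spacing=spacing, channel=name, bit_depth=bit_depth)
        for ch, name in zip(channels, channel_names)
    ]


def save_stack(path: str | Path, grids: Sequence[VoxelGrid]) -> None:
    """Write one or more same-shape VoxelGrids as a (c, z, y, x) TIFF."""
    if not grids:
        raise ValueError("no channels to save")
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    arr = np.stack([g.data for g in grids], axis=0)
    if arr.shape[0] == 1:
        arr = arr[0]
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def physical_coords(grid: VoxelGrid, index: Sequence[int]) -> tuple[float, float, float]:
    """Physical position (nm) of a voxel centre; linear in index per axis."""
    idx = tuple(int(i) for i in index)
    if len(idx) != 3:
        raise ValueError("index must have 3 components (z, y, x)")
    for i, n in zip(idx, grid.shape):
        if i < 0 or i >= n:
            raise IndexError(f"index {idx} out of bounds for shape {grid.shape}")
    return tuple(i * s for i, s in zip(idx, grid.spacing))
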