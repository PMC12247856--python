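"""Nuclear/cytoplasmic partitioning of a stain and per-cell volume.

The nuclear border for the RNA partition is the DNA-stain (DAPI) derived
mask — everything stained outside it counts as cytoplasmic.  Bright
intranuclear foci (nucleoli) count as nuclear signal; there is no exclusion.
Whole-cell volume comes from a cytoskeletal (α-tubulin-like) channel,
normalised by the number of nuclei in the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import SegmentationParams, VoxelGrid
from .segmentation import segment_channel

__all__ = ["CompartmentReport", "nc_ratio", "cell_volume_per_field"]


@dataclass(frozen=True)
class CompartmentReport:
    cell_id: int
    nuclear_volume_um3: float
    cytoplasmic_volume_um3: float
    nc_ratio: float
    cell_volume_um3: float
    n_nuclei_in_field: int


def nc_ratio(stain_mask: np.ndarray, nucleus_mask: np.ndarray,
             voxel_volume_nm3: float | None = None):
    """Nuclear-to-cytoplasmic volume ratio of a stained region.

    Returns ``(ratio, nuclear_um3, cytoplasmic_um3)`` when
    ``voxel_volume_nm3`` is given, else the bare ratio.  The ratio is
    ``inf`` when all stained signal is nuclear.
    """
    stain = np.asarray(stain_mask, dtype=bool)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    if stain.shape != nuc.shape:
        raise ValueError("masks must share one grid")
    if not stain.any():
        raise ValueError("stain mask is empty")
    if not nuc.any():
        raise ValueError("nucleus mask is empty")
    n_nuc = int((stain & nuc).sum())
    n_cyt = int((stain & ~nuc).sum())
    ratio = math.inf if n_cyt == 0 else n_nuc / n_cyt
    if voxel_volume_nm3 is None:
        return ratio
    return ratio, n_nuc * voxel_volume_nm3 / 1e9, n_cyt * voxel_volume_nm3 / 1e9


def cell_volume_per_field(
    tubulin_grid: VoxelGrid, params: SegmentationParams, n_nuclei: int
) -> float:
    """Total segmented cytoskeletal volume per nucleus in the field (µm³)."""
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    labels = segment_channel(tubulin_grid, params)
    total_um3 = int((labels > 0).sum()) * tubulin_grid.voxel_volume_nm3 / 1e9
    return total_um3 / n_nuclei
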