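"""Rule-based morphology taxonomy for aggregates and nuclei.

Aggregates fall into six classes defined by measurable geometry/topology:

* **I**   cell-body-filling mass continuous into a neurite,
* **II**  ring around the nucleus *with* a connecting loop ("basket"),
* **III** >= 3 skein-like tubes from a common point caging the nucleus,
* **IV**  ring around the nucleus without the connecting loop,
* **V**   > 5 disconnected puncta inside the nuclear compartment,
* **VI**  isolated elongated inclusion outside the cell body (neurite-like).

Each verbal criterion is bound to one measurable feature with a named,
configurable threshold, and the decision list is evaluated in a fixed order
(first match wins).  Nuclei are classified by severity precedence
ruptured > multi-lobed > malformed > normal, the operational reading of
"classified as the more predominant irregularity".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import SurfaceObject, extract_surface

__all__ = [
    "MorphologyFeatures",
    "MorphologyThresholds",
    "extract_features",
    "classify_aggregate",
    "classify_nucleus",
    "compare_distributions",
    "distribution_table",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

AGGREGATE_CLASSES = ("I", "II", "III", "IV", "V", "VI")
NUCLEUS_CLASSES = ("normal", "multi_lobed", "malformed", "ruptured")


@dataclass
class MorphologyFeatures:
    n_components: int
    component_sizes_um3: list[float]
    betti1: int
    branch_count_from_max_junction: int
    elongation: float
    encircles_nucleus: bool
    continuous_into_neurite: bool
    intranuclear_puncta: int
    cell_body_fill_fraction: float
    soma_overlap_fraction: float
    cage_coverage: float
    #: punctate pathology with an attached fibril-like (elongated) component
    fibril_component: bool = False

    def __post_init__(self) -> None:
        if self.n_components < 0 or self.intranuclear_puncta < 0:
            raise ValueError("counts must be >= 0")
        if self.elongation < 1.0 - 1e-9:
            raise ValueError("elongation is major/minor and must be >= 1")


@dataclass(frozen=True)
class MorphologyThresholds:
    """Named thresholds binding the verbal class criteria to features."""

    elongation_min: float = 4.0        # E_min: rod-like inclusions (VI)
    cage_coverage_min: float = 0.5     # C_min: fraction of nuclear solid angle (III)
    fill_fraction_min: float = 0.5     # F_min: cell-body fill (I)
    puncta_max_um3: float = 0.5        # size cap for a "punctum" (V)
    puncta_min_count: int = 6          # "> 5 puncta" (V)
    soma_overlap_max: float = 0.25     # "not in the cell body" (VI)


def _largest_component(labels: np.ndarray) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == np.argmax(counts)


def _euler_characteristic_3d(mask: np.ndarray) -> int:
    """χ of the voxel set viewed as a union of closed unit cubes (exact)."""
    p = np.pad(np.asarray(mask, dtype=bool), 1)

    def _or(a, axis):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[axis] = slice(None, -1)
        sl1[axis] = slice(1, None)
        return a[tuple(sl0)] | a[tuple(sl1)]

    C = int(p.sum())
    F = sum(int(_or(p, ax).sum()) for ax in range(3))
    E = 0
    for ax in range(3):
        others = [a for a in range(3) if a != ax]
        e = _or(_or(p, others[0]), others[1])
        E += int(e.sum())
    V = int(_or(_or(_or(p, 0), 1), 2).sum())
    return V - E + F - C


def _betti1_of_component(comp: np.ndarray, spacing=None) -> int:
    """Independent loops (first Betti number) of one solid component.

    β1 = β0 + β2 - χ with β0 = 1 for a single component and β2 the number of
    enclosed cavities (hole-filled interior components).  Computed on the
    cubical complex, which is robust for thin tubes where a triangulated
    surface would pick up spurious handles.
    """
    chi = _euler_characteristic_3d(comp)
    interior = ndimage.binary_fill_holes(comp) & ~comp
    _, beta2 = ndimage.label(interior, structure=_CONN26)
    return max(0, 1 + int(beta2) - chi)


def _skeleton_max_junction(comp: np.ndarray) -> int:
    from skimage.morphology import skeletonize

    skel = skeletonize(comp)
    if not skel.any():
        return 0
    neigh = ndimage.convolve(skel.astype(np.uint8), _CONN26.astype(np.uint8),
                             mode="constant") - skel
    return int(neigh[skel].max())


def _elongation(comp: np.ndarray, spacing) -> float:
    coords = np.argwhere(comp) * np.asarray(spacing)
    if len(coords) < 4:
        return 1.0
    cov = np.cov((coords - coords.mean(axis=0)).T)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ev = np.maximum(ev, 1e-9)
    return float(math.sqrt(ev[0] / ev[1]))


def _encircles(comp: np.ndarray, nucleus_center_nm: np.ndarray, spacing,
               n_bins: int = 36, min_cover: float = 0.9,
               slab_nm: float = 700.0) -> bool:
    """Ring test: aggregate voxels surround the nucleus centre in some plane.

    For each candidate ring normal (the three grid axes and the component's
    principal axes), the voxels within a thin slab through the nucleus
    centre must cover nearly all azimuths around it while leaving the centre
    itself clear — a ring, not a disc.  The slab confines the test to the
    ring's plane so attached material (e.g. a basket's connecting loop) does
    not mask it.
    """
    coords = np.argwhere(comp) * np.asarray(spacing)
    if len(coords) < 8:
        return False
    centred = coords - coords.mean(axis=0)
    _, evecs = np.linalg.eigh(np.cov(centred.T))
    candidates = [np.eye(3)[i] for i in range(3)] + [evecs[:, i] for i in range(3)]
    rel_all = coords - np.asarray(nucleus_center_nm)
    for normal in candidates:
        along = rel_all @ normal
        slab = np.abs(along) <= slab_nm
        if slab.sum() < 8:
            continue
        rel = rel_all[slab]
        # in-plane basis
        ref = np.eye(3)[np.argmin(np.abs(normal))]
        e1 = np.cross(normal, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        u, v = rel @ e1, rel @ e2
        radii = np.hypot(u, v)
        if radii.min() < 0.25 * np.median(radii):
            continue  # material at the centre: a disc, not a ring
        ang = np.arctan2(v, u)
        occupied = np.unique(((ang + math.pi) / (2 * math.pi) * n_bins).astype(int) % n_bins)
        if len(occupied) / n_bins >= min_cover:
            return True
    return False


def _cage_coverage(comp: np.ndarray, nucleus_center_nm, spacing,
                   n_polar: int = 4, n_azimuth: int = 8) -> float:
    """Fraction of the nuclear solid angle subtended by the aggregate."""
    coords = np.argwhere(comp) * np.asarray(spacing)
    rel = coords - np.asarray(nucleus_center_nm)
    r = np.linalg.norm(rel, axis=1)
    keep = r > 1e-6
    if not keep.any():
        return 0.0
    rel, r = rel[keep], r[keep]
    cosz = np.clip(rel[:, 0] / r, -1, 1)
    phi = np.arctan2(rel[:, 1], rel[:, 2])
    iz = np.minimum(((cosz + 1) / 2 * n_polar).astype(int), n_polar - 1)
    ip = ((phi + math.pi) / (2 * math.pi) * n_azimuth).astype(int) % n_azimuth
    return len(np.unique(iz * n_azimuth + ip)) / (n_polar * n_azimuth)


def extract_features(
    aggregate_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    soma_mask: np.ndarray,
    spacing,
    puncta_max_um3: float = 0.5,
) -> MorphologyFeatures:
    """Measure the geometry/topology features the class rules consume."""
    agg = np.asarray(aggregate_mask, dtype=bool)
    if not agg.any():
        raise ValueError("aggregate mask is empty")
    nuc = np.asarray(nucleus_mask, dtype=bool)
    soma = np.asarray(soma_mask, dtype=bool)
    spacing = tuple(float(s) for s in spacing)
    vox_um3 = spacing[0] * spacing[1] * spacing[2] / 1e9

    labels, n_comp = ndimage.label(agg, structure=_CONN26)
    sizes = np.bincount(labels.ravel())[1:] * vox_um3
    largest = _largest_component(labels)

    intranuclear = 0
    for cid in range(1, n_comp + 1):
        comp = labels == cid
        if sizes[cid - 1] <= puncta_max_um3 and (comp & ~nuc).sum() == 0:
            intranuclear += 1

    nucleus_center = (
        np.array(ndimage.center_of_mass(nuc)) * np.asarray(spacing)
        if nuc.any() else np.array(ndimage.center_of_mass(agg)) * np.asarray(spacing)
    )
    fibril = any(
        _elongation(labels == cid, spacing) >= 4.0
        for cid in range(1, n_comp + 1)
        if (labels == cid).sum() >= 20
    ) and intranuclear >= 1
    soma_vox = int(soma.sum())
    agg_vox = int(agg.sum())
    in_soma = int((agg & soma).sum())
    exits_soma = bool((largest & ~soma).any() and (largest & soma).any())

    return MorphologyFeatures(
        n_components=int(n_comp),
        component_sizes_um3=[float(s) for s in sizes],
        betti1=_betti1_of_component(largest, spacing),
        branch_count_from_max_junction=_skeleton_max_junction(largest),
        elongation=_elongation(largest, spacing),
        encircles_nucleus=_encircles(largest, nucleus_center, spacing),
        continuous_into_neurite=exits_soma,
        intranuclear_puncta=intranuclear,
        cell_body_fill_fraction=float(in_soma / soma_vox) if soma_vox else 0.0,
        soma_overlap_fraction=float(in_soma / agg_vox),
        cage_coverage=_cage_coverage(agg, nucleus_center, spacing),
        fibril_component=bool(fibril),
    )


def classify_aggregate(
    features: MorphologyFeatures,
    thresholds: MorphologyThresholds = MorphologyThresholds(),
) -> str:
    """Fixed-order decision list over the measured features; first match wins."""
    f, t = features, thresholds
    if (f.elongation >= t.elongation_min and not f.encircles_nucleus
            and f.soma_overlap_fraction <= t.soma_overlap_max):
        return "VI"
    if f.intranuclear_puncta >= t.puncta_min_count and not f.encircles_nucleus:
        return "V"
    if f.encircles_nucleus and f.betti1 >= 2:
        return "II"
    if f.encircles_nucleus and f.betti1 == 1:
        return "IV"
    if (f.branch_count_from_max_junction >= 3
            and f.cage_coverage >= t.cage_coverage_min
            and f.cell_body_fill_fraction < t.fill_fraction_min):
        return "III"
    if f.cell_body_fill_fraction >= t.fill_fraction_min and f.continuous_into_neurite:
        return "I"
    return "unclassified"


def _lobe_count(nucleus_mask: np.ndarray, spacing, min_lobe_fraction: float = 0.2,
                peak_sep_nm: float = 2000.0) -> int:
    """Lobes by watershed of the internal distance map from its maxima."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    edt = ndimage.distance_transform_edt(nucleus_mask, sampling=spacing)
    fp = tuple(max(1, int(round(peak_sep_nm / s))) for s in spacing)
    peaks = peak_local_max(edt, footprint=np.ones(fp), labels=nucleus_mask,
                           exclude_border=False)
    if len(peaks) < 2:
        return max(1, len(peaks))
    markers = np.zeros_like(nucleus_mask, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    ws = watershed(-edt, markers, mask=nucleus_mask)
    total = nucleus_mask.sum()
    sizes = np.bincount(ws.ravel())[1:]
    return int((sizes >= min_lobe_fraction * total).sum())


def classify_nucleus(
    surface: SurfaceObject,
    enclosed_lamin_components: int = 1,
    psi_threshold: float = 0.47,
) -> str:
    """Severity-ordered nucleus call: ruptured > multi_lobed > malformed > normal."""
    if not surface.watertight:
        return "ruptured"
    lobes = enclosed_lamin_components
    if surface.mask is not None:
        lobes = max(lobes, _lobe_count(surface.mask, surface.spacing))
    if lobes >= 2:
        return "multi_lobed"
    if surface.sphericity < psi_threshold:
        return "malformed"
    return "normal"


def distribution_table(labels_by_group: dict[str, list[str]],
                       classes=AGGREGATE_CLASSES) -> pd.DataFrame:
    """Counts per class per group label (rows = groups, columns = classes)."""
    rows = {}
    for group, labels in labels_by_group.items():
        rows[group] = {c: sum(1 for x in labels if x == c) for c in classes}
    return pd.DataFrame(rows).T[list(classes)]


def compare_distributions(d1, d2, **fisher_kwargs) -> float:
    """Exact (Freeman–Halton) p-value for two morphology count vectors.

    ``d1``/``d2`` are per-class counts over the same class set (dict, Series
    or sequence).  Classes absent from both groups are collapsed away; a
    group with zero total is degenerate and raises.
    """
    from .stats import fisher_exact_rxc

    def as_array(d):
        if isinstance(d, dict):
            return np.array([d[k] for k in sorted(d)], dtype=np.int64)
        if isinstance(d, pd.Series):
            return d.to_numpy(dtype=np.int64)
        return np.asarray(list(d), dtype=np.int64)

    a, b = as_array(d1), as_array(d2)
    if a.shape != b.shape:
        raise ValueError("distributions must cover the same class set")
    table = np.stack([a, b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 informative classes")
    return fisher_exact_rxc(table, **fisher_kwargs)
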