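"""Synthetic 3D multichannel scenes with ground truth.

The generator emulates the statistical structure of super-resolution
spinning-disc stacks of brain tissue: an anisotropic voxel grid (300 nm
z-step, 65 nm lateral pitch by default), nuclei as DNA-filled regions bounded
by a thin lamin shell, protein aggregates of six idealised morphologies
placed at controlled depths inside or outside the shell, nuclear puncta, an
RNA stain split between nucleus and cytoplasm, a whole-cell (tubulin-like)
channel, Gaussian PSF blur (σ from the ~120 nm lateral / ~300 nm axial
resolution), and Poisson-Gaussian noise.  Truth masks and tables reflect the
pre-blur geometry, so every downstream stage can be scored against them.

Morphology recipes (geometric idealisations of the verbal class criteria):

* ``I``    cell-body-filling mass continuous into a neurite tube;
* ``II``   ring (torus) around the nucleus plus a connecting arc ("basket");
* ``III``  >= 3 curved tubes from a common point caging the nucleus;
* ``IV``   ring around the nucleus without a connecting loop;
* ``V``    >= 6 disconnected small puncta inside the nuclear compartment;
* ``VI``   isolated elongated tube away from the cell body (neurite-like);
* ``blob`` single sphere at a prescribed signed depth (test primitive).

Nucleus recipes: ``none`` (perfect sphere; truth sphericity exactly 1),
``malformed`` (large-amplitude low-order angular perturbation),
``multi_lobed`` (union of two overlapping lobes), ``ruptured`` (lamin shell
with a spherical-cap hole).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VoxelGrid

__all__ = [
    "AggregateSpec",
    "NoiseParams",
    "SceneParams",
    "SceneTruth",
    "generate_scene",
    "generate_cohort",
    "generate_viability_plate",
    "sample_cohort_summaries",
]

# FWHM -> sigma for the stated 120 nm lateral / 300 nm axial resolution
PSF_SIGMA_XY_NM = 120.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
PSF_SIGMA_Z_NM = 300.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: clean signal amplitudes per channel, chosen so that the default absolute
#: intensity bands of the analysis segment the synthetic channels directly
CHANNEL_AMPLITUDE = {
    "dapi": 200.0, "lamin": 2000.0, "psyn": 500.0,
    "53bp1": 2000.0, "rna": 300.0, "tubulin": 300.0,
}


@dataclass(frozen=True)
class AggregateSpec:
    """One aggregate to place: class, multiplicity, signed placement depth.

    ``depth_nm`` > 0 places the object that far inside the lamin boundary;
    < 0 places it outside (classes II/IV/VI ignore it and use their own
    geometry).  ``count`` repeats the recipe (one aggregate id each).
    """

    morphology: str = "blob"
    count: int = 1
    depth_nm: float = 1000.0

    def __post_init__(self) -> None:
        if self.morphology not in ("I", "II", "III", "IV", "V", "VI", "blob"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Poisson shot noise (per-intensity-unit gain) + additive Gaussian read noise."""

    poisson_gain: float = 0.1
    gaussian_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SceneParams:
    field_size: tuple[int, int, int] = (32, 192, 192)
    spacing: tuple[float, float, float] = (300.0, 65.0, 65.0)
    n_nuclei: int = 1
    nucleus_radius_um: tuple[float, float] = (3.0, 0.25)  # mean, sd
    nucleus_deformation: dict[str, float] = field(default_factory=lambda: {"none": 1.0})
    aggregates: list[AggregateSpec] = field(default_factory=list)
    puncta_per_nucleus: float = 0.0
    puncta_min_sep_nm: float = 0.0
    rna_nuclear_fraction: float | None = None
    psf_sigma: tuple[float, float] = (PSF_SIGMA_Z_NM, PSF_SIGMA_XY_NM)  # (σz, σxy) nm
    noise: NoiseParams | None = NoiseParams()
    blur: bool = True
    background: float = 50.0
    rupture_hole_deg: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.field_size):
            raise ValueError("field too small")
        total = sum(self.nucleus_deformation.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("nucleus_deformation fractions must sum to 1")
        for k in self.nucleus_deformation:
            if k not in ("none", "malformed", "multi_lobed", "ruptured"):
                raise ValueError(f"unknown deformation class {k!r}")
        if self.rna_nuclear_fraction is not None and not 0 <= self.rna_nuclear_fraction <= 1:
            raise ValueError("rna_nuclear_fraction must be in [0, 1]")
        if self.puncta_per_nucleus < 0:
            raise ValueError("puncta_per_nucleus must be >= 0")
        if any(s <= 0 for s in self.psf_sigma):
            raise ValueError("psf sigma must be > 0")


@dataclass
class SceneTruth:
    """Pre-blur geometry: label masks plus per-object truth tables."""

    nucleus_labels: np.ndarray
    lamin_mask: np.ndarray
    dna_mask: np.ndarray
    aggregate_labels: np.ndarray
    puncta_centers_nm: np.ndarray  # (n, 3) z,y,x
    puncta_nucleus_ids: np.ndarray
    rna_mask: np.ndarray | None
    cell_labels: np.ndarray
    nuclei: pd.DataFrame
    aggregates: pd.DataFrame
    spacing: tuple[float, float, float]


# ---------------------------------------------------------------------------
# geometry helpers (all positions in nm, axis order z, y, x)
# ---------------------------------------------------------------------------

def _coord_grids(shape, spacing):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return zz * spacing[0], yy * spacing[1], xx * spacing[2]


def _ball(shape, spacing, center, radius) -> np.ndarray:
    z, y, x = _coord_grids(shape, spacing)
    return (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2 <= radius ** 2


def _tube(shape, spacing, points: np.ndarray, radius: float) -> np.ndarray:
    """Voxels within ``radius`` of a sampled polyline (points: (n, 3) nm)."""
    from scipy.spatial import cKDTree

    lo = points.min(axis=0) - radius - np.asarray(spacing)
    hi = points.max(axis=0) + radius + np.asarray(spacing)
    sl = tuple(
        slice(max(0, int(lo[i] // spacing[i])), min(shape[i], int(hi[i] // spacing[i]) + 2))
        for i in range(3)
    )
    idx = np.mgrid[sl].reshape(3, -1).T
    coords = idx * np.asarray(spacing)
    tree = cKDTree(points)
    d, _ = tree.query(coords, k=1)
    mask = np.zeros(shape, dtype=bool)
    inside = idx[d <= radius]
    mask[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return mask


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _random_direction(rng, max_abs_cos_z: float = 1.0) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n < 1e-9:
            continue
        v = v / n
        if abs(v[0]) <= max_abs_cos_z:
            return v


def _angular_field(rng, n_terms: int = 12, freq: float = 8.0):
    """Rough random function of direction, normalised to [-1, 1].

    A sum of cosine waves of projections onto random axes; ``freq`` sets the
    angular wavelength of the surface corrugation.
    """
    us = [_random_direction(rng) for _ in range(n_terms)]
    amps = rng.uniform(0.5, 1.0, size=n_terms) * rng.choice([-1, 1], size=n_terms)
    phases = rng.uniform(0, 2 * math.pi, size=n_terms)

    def f(dirs: np.ndarray) -> np.ndarray:
        out = np.zeros(dirs.shape[:-1])
        for u, a, ph in zip(us, amps, phases):
            out += a * np.cos(freq * math.pi * (dirs @ u) + ph)
        m = np.abs(out).max()
        return out / m if m > 0 else out

    return f


def _perturbed_ball(shape, spacing, center, radius, rng, amplitude, n_terms=12, freq=8.0):
    z, y, x = _coord_grids(shape, spacing)
    dz, dy, dx = z - center[0], y - center[1], x - center[2]
    dist = np.sqrt(dz ** 2 + dy ** 2 + dx ** 2)
    dist = np.maximum(dist, 1e-6)
    dirs = np.stack(np.broadcast_arrays(dz / dist, dy / dist, dx / dist), axis=-1)
    f = _angular_field(rng, n_terms=n_terms, freq=freq)
    local_r = radius * (1.0 + amplitude * f(dirs))
    return dist <= local_r


# ---------------------------------------------------------------------------
# nucleus recipes
# ---------------------------------------------------------------------------

def _make_nucleus(shape, spacing, center, radius, kind, rng, hole_deg):
    """Returns (nucleus_mask, hole_direction or None, truth_sphericity or None)."""
    if kind == "none":
        return _ball(shape, spacing, center, radius), None, 1.0
    if kind == "malformed":
        mask = _perturbed_ball(shape, spacing, center, 0.9 * radius, rng,
                               amplitude=0.6, n_terms=12, freq=8.0)
        # keep it a single contiguous piece containing the centre
        lab, n = ndimage.label(mask)
        if n > 1:
            cidx = tuple(int(round(center[i] / spacing[i])) for i in range(3))
            keep = lab[cidx] or np.argmax(np.bincount(lab.ravel())[1:]) + 1
            mask = lab == keep
        return mask, None, None
    if kind == "multi_lobed":
        off = _random_direction(rng, max_abs_cos_z=0.3) * 0.75 * radius
        a = _ball(shape, spacing, center + off, 0.8 * radius)
        b = _ball(shape, spacing, center - off, 0.8 * radius)
        return a | b, None, None
    if kind == "ruptured":
        hole_dir = _random_direction(rng)
        return _ball(shape, spacing, center, radius), hole_dir, 1.0
    raise ValueError(f"unknown nucleus kind {kind!r}")


def _lamin_shell(nucleus_mask, spacing, thickness_nm=350.0, hole_dir=None,
                 center=None, hole_deg=25.0):
    edt = ndimage.distance_transform_edt(nucleus_mask, sampling=spacing)
    shell = nucleus_mask & (edt <= thickness_nm)
    if hole_dir is not None:
        z, y, x = _coord_grids(nucleus_mask.shape, spacing)
        dz, dy, dx = z - center[0], y - center[1], x - center[2]
        dist = np.maximum(np.sqrt(dz ** 2 + dy ** 2 + dx ** 2), 1e-6)
        cosang = (dz * hole_dir[0] + dy * hole_dir[1] + dx * hole_dir[2]) / dist
        shell = shell & ~(cosang >= math.cos(math.radians(hole_deg)))
    return shell


# ---------------------------------------------------------------------------
# aggregate recipes
# ---------------------------------------------------------------------------

def _place_inside(rng, center, r_nuc, depth, obj_radius, spacing, shape, max_cos_z=0.45):
    rad_pos = r_nuc - depth - obj_radius
    if rad_pos < 0:
        raise ValueError(
            f"aggregate placement infeasible: depth {depth} nm + radius {obj_radius} nm "
            f"exceeds nucleus radius {r_nuc} nm"
        )
    d = _random_direction(rng, max_abs_cos_z=max_cos_z)
    return center + d * rad_pos


def _recipe_blob(shape, spacing, center, r_nuc, rng, depth, radius=300.0):
    if depth >= 0:
        pos = _place_inside(rng, center, r_nuc, depth, radius, spacing, shape)
    else:
        d = _random_direction(rng, max_abs_cos_z=0.2)
        pos = center + d * (r_nuc - depth + radius)  # depth < 0: outside
    return _ball(shape, spacing, pos, radius)


def _recipe_V(shape, spacing, center, r_nuc, rng, depth, n_puncta=6, radius=250.0,
              min_sep=900.0):
    mask = np.zeros(shape, dtype=bool)
    placed = []
    tries = 0
    while len(placed) < n_puncta and tries < 3000:
        tries += 1
        pos = _place_inside(rng, center, r_nuc, depth, radius, spacing, shape, max_cos_z=0.6)
        # uniform radial jitter inward
        pos = center + (pos - center) * rng.uniform(0.2, 1.0)
        if all(np.linalg.norm(pos - q) >= min_sep for q in placed):
            placed.append(pos)
    if len(placed) < n_puncta:
        raise ValueError("could not place the requested intranuclear puncta")
    for pos in placed:
        mask |= _ball(shape, spacing, pos, radius)
    return mask


def _ring_points(center, R, n=200, plane="xy", phase=0.0, span=2 * math.pi):
    t = phase + np.linspace(0.0, span, n)
    pts = np.tile(np.asarray(center, dtype=float), (n, 1))
    if plane == "xy":
        pts[:, 1] += R * np.sin(t)
        pts[:, 2] += R * np.cos(t)
    else:  # xz: arc over the top of the nucleus
        pts[:, 0] += R * np.sin(t)
        pts[:, 2] += R * np.cos(t)
    return pts


def _recipe_ring(shape, spacing, center, r_nuc, rng, connecting_arc: bool,
                 clearance=450.0, tube_r=250.0):
    R = r_nuc + clearance
    mask = _tube(shape, spacing, _ring_points(center, R), tube_r)
    if connecting_arc:
        arc = _ring_points(center, R, n=120, plane="xz", span=math.pi)
        mask |= _tube(shape, spacing, arc, tube_r)
    return mask


def _recipe_III(shape, spacing, center, r_nuc, rng, n_skeins=4, tube_r=250.0,
                clearance=700.0):
    """Curved tubes from one common point wrapping the nucleus (cage)."""
    c = np.asarray(center, dtype=float)
    a = r_nuc + clearance
    p0 = c + np.array([0.0, 0.0, a])  # common origin on +x side, mid-plane
    mask = np.zeros(shape, dtype=bool)
    for k in range(n_skeins):
        phi = 2 * math.pi * k / n_skeins + rng.uniform(-0.2, 0.2)
        # mid control point out to the side; end points fan out on the far side
        mid = c + a * 1.25 * np.array([0.55 * math.sin(phi), 0.9 * math.cos(phi), 0.0])
        end = c + a * np.array([0.5 * math.sin(phi), 0.5 * math.cos(phi), -0.95])
        t = np.linspace(0, 1, 150)[:, None]
        bez = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * mid + t ** 2 * end
        mask |= _tube(shape, spacing, bez, tube_r)
    return mask


def _recipe_I(shape, spacing, center, r_nuc, soma_mask, nucleus_mask, rng,
              neurite_r=300.0):
    """Soma-filling mass, continuous into a neurite leaving the soma."""
    body = soma_mask & ~ndimage.binary_dilation(
        nucleus_mask, iterations=2
    )
    c = np.asarray(center, dtype=float)
    x_end = (shape[2] - 2) * spacing[2]
    line = np.linspace([c[0], c[1], c[2]], [c[0], c[1], x_end], 120)
    neurite = _tube(shape, spacing, line, neurite_r) & ~soma_mask
    return body | neurite


def _recipe_VI(shape, spacing, center, r_soma, rng, length=6000.0, tube_r=250.0):
    c = np.asarray(center, dtype=float)
    # keep the tube inside the field on whichever x side has more room
    extent_x = (shape[2] - 1) * spacing[2]
    room_pos = extent_x - c[2] - tube_r - 3 * spacing[2]
    room_neg = c[2] - tube_r - 3 * spacing[2]
    side = 1.0 if room_pos >= room_neg else -1.0
    room = max(room_pos, room_neg)
    x_off = side * min(r_soma + tube_r + 300.0, room)
    if abs(x_off) < r_soma + tube_r - 100.0:
        raise ValueError("field too small to place a neuritic inclusion outside the soma")
    start = c + np.array([0.0, -length / 2.0, x_off])
    end = c + np.array([0.0, length / 2.0, x_off])
    return _tube(shape, spacing, np.linspace(start, end, 100), tube_r)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _corrupt(clean: np.ndarray, params: SceneParams, spacing, rng) -> np.ndarray:
    out = clean + params.background
    if params.blur:
        sz, sxy = params.psf_sigma
        out = ndimage.gaussian_filter(out, sigma=(sz / spacing[0], sxy / spacing[1],
                                                  sxy / spacing[2]))
    if params.noise is not None:
        g = params.noise.poisson_gain
        if g > 0:
            out = rng.poisson(np.maximum(out, 0) * g) / g
        if params.noise.gaussian_sd > 0:
            out = out + rng.normal(0.0, params.noise.gaussian_sd, size=out.shape)
    return np.maximum(out, 0.0)


def _nucleus_centers(params: SceneParams, r_mean_nm: float):
    nz, ny, nx = params.field_size
    dz, dy, dx = params.spacing
    cz = (nz - 1) / 2 * dz
    n = params.n_nuclei
    if n == 1:
        return [np.array([cz, (ny - 1) / 2 * dy, (nx - 1) / 2 * dx])]
    cols = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / cols))
    centers = []
    for i in range(n):
        r, c = divmod(i, cols)
        centers.append(np.array([
            cz,
            (r + 0.5) / rows * (ny - 1) * dy,
            (c + 0.5) / cols * (nx - 1) * dx,
        ]))
    return centers


def generate_scene(params: SceneParams) -> tuple[dict[str, VoxelGrid], SceneTruth]:
    """Render one multichannel scene and its ground truth.

    Deterministic given ``params`` (including ``params.seed``).  Channels are
    the pre-blur shape masks scaled to per-channel amplitudes, convolved with
    the anisotropic Gaussian PSF and corrupted with Poisson-Gaussian noise;
    the returned truth reflects the pre-blur geometry.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.field_size)
    spacing = tuple(params.spacing)

    r_mean, r_sd = params.nucleus_radius_um
    centers = _nucleus_centers(params, r_mean * 1000)

    # assign deformation classes deterministically by fractions
    kinds, fracs = zip(*sorted(params.nucleus_deformation.items()))
    counts = np.floor(np.asarray(fracs) * params.n_nuclei).astype(int)
    while counts.sum() < params.n_nuclei:
        counts[int(np.argmax(np.asarray(fracs) - counts / max(params.n_nuclei, 1)))] += 1
    kind_list = [k for k, c in zip(kinds, counts) for _ in range(c)]
    rng.shuffle(kind_list)

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    lamin = np.zeros(shape, dtype=bool)
    dna = np.zeros(shape, dtype=bool)
    agg_labels = np.zeros(shape, dtype=np.int32)
    rna_mask = np.zeros(shape, dtype=bool) if params.rna_nuclear_fraction is not None else None
    puncta_centers: list[np.ndarray] = []
    puncta_nids: list[int] = []
    nuc_rows, agg_rows = [], []
    next_agg_id = 1

    for nid, (center, kind) in enumerate(zip(centers, kind_list), start=1):
        # clamp draws to +-1.5 sd: fields are sized for ~the mean radius and
        # extreme draws would push peripheral recipes off the grid
        radius = float(np.clip(rng.normal(r_mean, r_sd),
                               max(1.2, r_mean - 1.5 * r_sd),
                               r_mean + 1.5 * r_sd)) * 1000.0
        nuc_mask, hole_dir, psi_true = _make_nucleus(
            shape, spacing, center, radius, kind, rng, params.rupture_hole_deg
        )
        shell = _lamin_shell(nuc_mask, spacing, hole_dir=hole_dir, center=center,
                             hole_deg=params.rupture_hole_deg)
        interior = nuc_mask & ~shell
        if psi_true is None:
            from .segmentation import extract_surface

            psi_true = extract_surface(nuc_mask.astype(np.int8), 1, spacing).sphericity
        nucleus_labels[nuc_mask] = nid
        lamin |= shell
        dna |= interior

        r_soma = 1.6 * radius
        soma = _ball(shape, spacing, center, r_soma)
        cell_labels[soma & (cell_labels == 0)] = nid

        # aggregates attached to this nucleus
        for spec in params.aggregates:
            for _ in range(spec.count):
                if spec.morphology == "blob":
                    m = _recipe_blob(shape, spacing, center, radius, rng, spec.depth_nm)
                elif spec.morphology == "V":
                    m = _recipe_V(shape, spacing, center, radius, rng, spec.depth_nm)
                elif spec.morphology == "II":
                    m = _recipe_ring(shape, spacing, center, radius, rng, connecting_arc=True)
                elif spec.morphology == "IV":
                    m = _recipe_ring(shape, spacing, center, radius, rng, connecting_arc=False)
                elif spec.morphology == "III":
                    m = _recipe_III(shape, spacing, center, radius, rng)
                elif spec.morphology == "I":
                    m = _recipe_I(shape, spacing, center, radius, soma, nuc_mask, rng)
                elif spec.morphology == "VI":
                    m = _recipe_VI(shape, spacing, center, r_soma, rng)
                if not m.any():
                    raise ValueError(f"recipe {spec.morphology} rendered no voxels")
                agg_labels[m] = next_agg_id
                agg_rows.append(dict(
                    aggregate_id=next_agg_id, nucleus_id=nid,
                    morphology=spec.morphology, depth_nm=spec.depth_nm,
                    true_inside=bool(spec.morphology in ("V", "blob") and spec.depth_nm > 0),
                ))
                next_agg_id += 1

        # nuclear puncta
        n_puncta = int(rng.poisson(params.puncta_per_nucleus))
        pint = ndimage.distance_transform_edt(interior, sampling=spacing) >= 400.0
        cand = np.argwhere(pint) * np.asarray(spacing)
        placed = []
        if n_puncta > 0 and len(cand):
            order = rng.permutation(len(cand))
            for i in order:
                p = cand[i]
                if params.puncta_min_sep_nm <= 0 or all(
                    np.linalg.norm(p - q) >= params.puncta_min_sep_nm for q in placed
                ):
                    placed.append(p)
                if len(placed) == n_puncta:
                    break
        for p in placed:
            puncta_centers.append(p)
            puncta_nids.append(nid)

        # RNA partition: innermost nuclear voxels + cytoplasm band at the border
        if rna_mask is not None:
            p = params.rna_nuclear_fraction
            cyt = soma & ~nuc_mask
            n_nucv, n_cytv = int(nuc_mask.sum()), int(cyt.sum())
            total = int(0.8 * min(
                n_nucv / max(p, 1e-6), n_cytv / max(1 - p, 1e-6)
            ))
            k_nuc = int(round(p * total))
            k_cyt = total - k_nuc
            if k_nuc > 0:
                edt_in = ndimage.distance_transform_edt(nuc_mask, sampling=spacing)
                vals = edt_in[nuc_mask]
                thr = np.partition(vals, len(vals) - k_nuc)[len(vals) - k_nuc]
                rna_mask |= nuc_mask & (edt_in >= thr)
            if k_cyt > 0:
                edt_out = ndimage.distance_transform_edt(~nuc_mask, sampling=spacing)
                vals = edt_out[cyt]
                thr = np.partition(vals, k_cyt - 1)[k_cyt - 1]
                rna_mask |= cyt & (edt_out <= thr)

        nuc_rows.append(dict(
            nucleus_id=nid, z_nm=center[0], y_nm=center[1], x_nm=center[2],
            radius_nm=radius, abnormality=kind if kind != "none" else "normal",
            true_sphericity=psi_true, n_puncta=len(placed),
        ))

    # ------------------------------------------------------------------ channels
    puncta_arr = (np.asarray(puncta_centers).reshape(-1, 3)
                  if puncta_centers else np.zeros((0, 3)))

    def puncta_field():
        f = np.zeros(shape)
        sig = (200.0, 150.0, 150.0)
        for p in puncta_arr:
            idx = tuple(int(round(p[i] / spacing[i])) for i in range(3))
            if all(0 <= idx[i] < shape[i] for i in range(3)):
                f[idx] += 1.0
        f = ndimage.gaussian_filter(f, sigma=[s / sp for s, sp in zip(sig, spacing)])
        m = f.max()
        return f / m if m > 0 else f

    clean = {
        "dapi": dna.astype(float),
        "lamin": lamin.astype(float),
        "psyn": (agg_labels > 0).astype(float),
        "53bp1": puncta_field(),
        "rna": (rna_mask.astype(float) if rna_mask is not None else np.zeros(shape)),
        "tubulin": (cell_labels > 0).astype(float),
    }
    channels = {
        name: VoxelGrid(
            _corrupt(arr * CHANNEL_AMPLITUDE[name], params, spacing, rng),
            spacing=spacing, channel=name,
        )
        for name, arr in clean.items()
    }
    truth = SceneTruth(
        nucleus_labels=nucleus_labels, lamin_mask=lamin, dna_mask=dna,
        aggregate_labels=agg_labels, puncta_centers_nm=puncta_arr,
        puncta_nucleus_ids=np.asarray(puncta_nids, dtype=int),
        rna_mask=rna_mask, cell_labels=cell_labels,
        nuclei=pd.DataFrame(nuc_rows), aggregates=pd.DataFrame(agg_rows),
        spacing=spacing,
    )
    return channels, truth


def generate_cohort(
    conditions: dict[str, SceneParams], n_fields: int, seed: int = 0
):
    """Scenes for each condition × field, with per-field derived seeds.

    Yields ``(condition, field_index, channels, truth)``; seeds are
    ``seed + 1000 * condition_index + field_index`` so cohorts are
    reproducible and fields independent.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    for ci, (label, base) in enumerate(sorted(conditions.items())):
        for f in range(n_fields):
            p = replace(base, seed=(seed + 1000 * ci + f) % (2 ** 31 - 1))
            channels, truth = generate_scene(p)
            yield label, f, channels, truth


def cohort_truth_tables(cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy nucleus and aggregate truth tables keyed by condition/field."""
    nuc, agg = [], []
    for label, f, _, truth in cohort:
        nuc.append(truth.nuclei.assign(condition=label, field=f))
        agg.append(truth.aggregates.assign(condition=label, field=f))
    return (
        pd.concat(nuc, ignore_index=True) if nuc else pd.DataFrame(),
        pd.concat(agg, ignore_index=True) if agg else pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# plate-level and summary-level generators
# ---------------------------------------------------------------------------

def generate_viability_plate(
    ic50_uM: dict[str, float],
    doses_uM,
    hill: float = 1.0,
    reps: int = 3,
    noise_sd_pct: float = 2.0,
    amplitude: float = 10000.0,
    background: float = 500.0,
    n_background_wells: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Luminescence plate for a sigmoid dose-kill model per condition.

    luminescence = background + amplitude / (1 + (dose / IC50)^hill), with
    multiplicative Gaussian well noise and media-only background wells.
    """
    doses = np.asarray(list(doses_uM), dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose list")
    if (doses <= 0).any():
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, ic50 in sorted(ic50_uM.items()):
        for d in doses:
            signal = amplitude / (1.0 + (d / ic50) ** hill)
            for _ in range(reps):
                lum = background + signal * (1.0 + rng.normal(0, noise_sd_pct / 100.0))
                rows.append(dict(condition=cond, dose_uM=d, luminescence=lum,
                                 is_background=False))
    for _ in range(n_background_wells):
        rows.append(dict(
            condition="media", dose_uM=np.nan,
            luminescence=background * (1.0 + rng.normal(0, noise_sd_pct / 100.0)),
            is_background=True,
        ))
    return pd.DataFrame(rows)


def sample_cohort_summaries(
    n_per_group: int,
    sphericity_means=(0.5836, 0.3550),
    sphericity_sds=(0.0826, 0.0714),
    puncta_means=(29.64, 66.89),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-nucleus summary draws at the generator's group conditions.

    Sphericity per nucleus is Normal (clipped to (0, 1]); puncta counts are
    Poisson.  Defaults are the control/pathology group settings the imaging
    generator targets (group SDs derived from 95% CIs at n = 105/group).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, sm, ss, pm in zip(("control", "pathology"), sphericity_means,
                                sphericity_sds, puncta_means):
        psi = np.clip(rng.normal(sm, ss, size=n_per_group), 1e-3, 1.0)
        counts = rng.poisson(pm, size=n_per_group)
        for p, c in zip(psi, counts):
            rows.append(dict(condition=cond, sphericity=p, puncta=int(c)))
    return pd.DataFrame(rows)
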