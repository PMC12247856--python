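import math

import numpy as np
import pytest

from nucmorph.core import SegmentationParams, VoxelGrid
from nucmorph.segmentation import (
    extract_surface,
    nucleus_from_shell,
    segment_channel,
    shell_interior,
    sphericity,
    surfaces_report,
)

ANISO = (300.0, 65.0, 65.0)


def digitized_ellipsoid(radii_nm, spacing=ANISO, pad=6):
    shape = tuple(int(2 * r / s) + 2 * pad for r, s in zip(radii_nm, spacing))
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    c = [(n - 1) / 2 * s for n, s in zip(shape, spacing)]
    d = ((zz * spacing[0] - c[0]) / radii_nm[0]) ** 2 + \
        ((yy * spacing[1] - c[1]) / radii_nm[1]) ** 2 + \
        ((xx * spacing[2] - c[2]) / radii_nm[2]) ** 2
    return (d <= 1.0).astype(np.int8), shape


def prolate_psi(a, b):
    """Closed-form sphericity of a prolate spheroid with semi-axes a > b = c."""
    e = math.sqrt(1 - (b / a) ** 2)
    area = 2 * math.pi * b * b * (1 + (a / (b * e)) * math.asin(e))
    vol = 4.0 / 3.0 * math.pi * a * b * b
    return sphericity(vol, area)


class TestSphericityFormula:
    def test_unit_sphere_is_1(self):
        assert sphericity(4 * math.pi / 3, 4 * math.pi) == pytest.approx(1.0)

    def test_unit_cube(self):
        assert sphericity(1.0, 6.0) == pytest.approx((36 * math.pi) ** (1 / 3) / 6,
                                                     rel=1e-12)
        assert sphericity(1.0, 6.0) == pytest.approx(0.80600, abs=5e-6)

    def test_prolate_2_to_1(self):
        assert prolate_psi(2.0, 1.0) == pytest.approx(0.9287, abs=1e-3)

    def test_scale_invariance(self):
        for s in (0.1, 3.0, 250.0):
            assert sphericity(5.0 * s**3, 9.0 * s**2) == pytest.approx(
                sphericity(5.0, 9.0), rel=1e-12
            )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)


class TestSegmentChannel:
    def test_uniform_zero_gives_no_objects(self):
        g = VoxelGrid(np.zeros((8, 32, 32)), ANISO)
        labels = segment_channel(g, SegmentationParams("absolute", 10, 100))
        assert labels.max() == 0

    def test_single_sphere_one_object(self):
        mask, _ = digitized_ellipsoid((900, 900, 900))
        g = VoxelGrid(mask * 500.0, ANISO)
        labels = segment_channel(g, SegmentationParams("absolute", 250, 868, grain_um=0.1))
        assert labels.max() == 1

    def test_two_separated_spheres_two_objects(self):
        arr = np.zeros((16, 96, 96))
        zz, yy, xx = np.ogrid[:16, :96, :96]
        for cx in (30, 70):
            d = ((zz - 8) * 300.0) ** 2 + ((yy - 48) * 65.0) ** 2 + ((xx - cx) * 65.0) ** 2
            arr[d <= 700.0**2] = 500.0
        g = VoxelGrid(arr, ANISO)
        labels = segment_channel(g, SegmentationParams("absolute", 250, 868, grain_um=0.1))
        # oracle: connected components of the generating mask
        from scipy import ndimage

        _, n_true = ndimage.label(arr > 0, structure=np.ones((3, 3, 3)))
        assert labels.max() == n_true == 2

    def test_upper_band_excludes_saturated(self):
        mask, _ = digitized_ellipsoid((900, 900, 900))
        g = VoxelGrid(mask * 5000.0, ANISO)
        labels = segment_channel(g, SegmentationParams("absolute", 250, 868, grain_um=0.0))
        assert labels.max() == 0

    def test_idempotent_on_binary_band(self):
        mask, _ = digitized_ellipsoid((900, 900, 900))
        g = VoxelGrid(mask * 500.0, ANISO)
        params = SegmentationParams("absolute", 250, 868, grain_um=0.0)
        labels1 = segment_channel(g, params)
        g2 = VoxelGrid((labels1 > 0) * 500.0, ANISO)
        labels2 = segment_channel(g2, params)
        np.testing.assert_array_equal(labels1 > 0, labels2 > 0)

    def test_local_contrast_keeps_object_on_sloped_background(self):
        mask, shape = digitized_ellipsoid((1200, 1500, 1500))
        ramp = np.linspace(0, 400, shape[2])[None, None, :] * np.ones(shape)
        g = VoxelGrid(mask * 200.0 + ramp, ANISO)
        labels = segment_channel(
            g, SegmentationParams("local_contrast", grain_um=0.095,
                                  background_subtraction=100.0)
        )
        assert labels.max() >= 1
        got = labels > 0
        overlap = (got & (mask > 0)).sum() / (mask > 0).sum()
        assert overlap > 0.9

    def test_min_voxels_filter(self):
        arr = np.zeros((8, 16, 16))
        arr[4, 8, 8] = 500.0
        g = VoxelGrid(arr, ANISO)
        labels = segment_channel(g, SegmentationParams("absolute", 250, 868, grain_um=0.0))
        assert labels.max() == 0  # single voxel < default min size


class TestExtractSurface:
    def test_digitized_isotropic_sphere(self):
        mask, _ = digitized_ellipsoid((2000, 2000, 2000), spacing=(65.0, 65.0, 65.0))
        s = extract_surface(mask, 1, (65.0, 65.0, 65.0))
        assert s.sphericity >= 0.97
        true_v = 4 / 3 * math.pi * 2.0**3
        assert s.volume_um3 == pytest.approx(true_v, rel=0.05)
        assert s.watertight

    def test_digitized_anisotropic_sphere(self):
        mask, _ = digitized_ellipsoid((2000, 2000, 2000))
        s = extract_surface(mask, 1, ANISO)
        assert abs(s.sphericity - 1.0) <= 0.03

    def test_prolate_spheroid_matches_closed_form(self):
        mask, _ = digitized_ellipsoid((2000, 1000, 1000))
        s = extract_surface(mask, 1, ANISO)
        assert s.sphericity == pytest.approx(prolate_psi(2.0, 1.0), abs=0.03)

    def test_mesh_volume_close_to_voxel_volume(self):
        mask, _ = digitized_ellipsoid((1500, 1800, 1200))
        s = extract_surface(mask, 1, ANISO)
        assert s.voxel_count >= 500
        vox_v = s.voxel_count * (300 * 65 * 65) / 1e9
        assert s.volume_um3 == pytest.approx(vox_v, rel=0.05)

    def test_vertices_within_grid_bounds(self):
        mask, shape = digitized_ellipsoid((1000, 1000, 1000))
        s = extract_surface(mask, 1, ANISO)
        hi = [n * sp for n, sp in zip(shape, ANISO)]
        assert (s.mesh.vertices >= -np.asarray(ANISO)).all()
        assert (s.mesh.vertices <= np.asarray(hi)).all()

    def test_missing_object_raises(self):
        mask, _ = digitized_ellipsoid((800, 800, 800))
        with pytest.raises(ValueError):
            extract_surface(mask, 5, ANISO)

    def test_report_table(self):
        mask, _ = digitized_ellipsoid((800, 800, 800))
        df = surfaces_report([extract_surface(mask, 1, ANISO, channel="lamin")])
        assert set(df.columns) >= {"object_id", "channel", "volume_um3", "area_um2",
                                   "sphericity", "watertight"}
        assert df.channel.iloc[0] == "lamin"


def shell_with_optional_hole(hole: bool, r=2000.0, thickness=400.0, hole_deg=25.0):
    shape = (int(2 * r / 300) + 8, int(2 * r / 65) + 10, int(2 * r / 65) + 10)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    c = [(n - 1) / 2 * s for n, s in zip(shape, ANISO)]
    d = np.sqrt(((zz * 300.0 - c[0])) ** 2 + ((yy * 65.0 - c[1])) ** 2
                + ((xx * 65.0 - c[2])) ** 2)
    shell = (d <= r) & (d >= r - thickness)
    if hole:
        cosang = (yy * 65.0 - c[1]) / np.maximum(d, 1)
        shell &= ~(cosang >= math.cos(math.radians(hole_deg)))
    return shell, d <= r


class TestShellsAndCapping:
    def test_closed_shell_encloses_cavity(self):
        shell, _ = shell_with_optional_hole(False)
        _, closed = shell_interior(shell)
        assert closed
        s = extract_surface(shell.astype(np.int8), 1, ANISO, shell=True)
        assert s.watertight

    def test_holed_shell_is_open(self):
        shell, _ = shell_with_optional_hole(True)
        _, closed = shell_interior(shell)
        assert not closed
        s = extract_surface(shell.astype(np.int8), 1, ANISO, shell=True)
        assert not s.watertight

    def test_capping_recovers_interior(self):
        shell, full = shell_with_optional_hole(True)
        nucleus, closed, capped = nucleus_from_shell(shell, ANISO)
        assert not closed and capped
        assert nucleus.sum() >= 0.9 * full.sum()

    def test_intact_shell_not_capped(self):
        shell, full = shell_with_optional_hole(False)
        nucleus, closed, capped = nucleus_from_shell(shell, ANISO)
        assert closed and not capped
        assert nucleus.sum() == pytest.approx(full.sum(), rel=0.02)


class TestPsiMonotoneUnderDeformation:
    def test_malformed_amplitude_ladder(self):
        """ψ strictly decreases as the perturbation amplitude grows."""
        from nucmorph.synth import _perturbed_ball

        shape, spacing = (30, 180, 180), ANISO
        center = np.array([(n - 1) / 2 * s for n, s in zip(shape, spacing)])
        psis = []
        for amp in (0.0, 0.1, 0.2, 0.35, 0.5):
            rng = np.random.default_rng(42)  # same field, scaled amplitude
            mask = _perturbed_ball(shape, spacing, center, 2500.0, rng, amp)
            psis.append(extract_surface(mask.astype(np.int8), 1, spacing).sphericity)
        assert all(a > b for a, b in zip(psis, psis[1:]))
        assert psis[0] > 0.98
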