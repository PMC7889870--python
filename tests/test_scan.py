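"""Scan simulation: determinism, geometry arithmetic, and the 1/sqrt(NEX) law."""

import numpy as np
import pytest

from radphantom.image import ImageVolume
from radphantom.scan import ScanProtocol, one_factor_grid, simulate_scan


@pytest.fixture(scope="module")
def truth():
    rng = np.random.default_rng(77)
    data = np.full((60, 60, 40), 0.0)
    data[10:50, 10:50, :] = 200.0 + rng.normal(0, 10, size=(40, 40, 40))
    return ImageVolume(data, spacing=(1, 1, 1), origin=(0.5, 0.5, 0.5))


class TestProtocol:
    def test_pixel_size_is_fov_over_matrix(self):
        p = ScanProtocol(fov=256.0, matrix=192)
        assert p.pixel_size == 256.0 / 192

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            ScanProtocol(nex=0)
        with pytest.raises(ValueError):
            ScanProtocol(noise_sigma=-1)
        with pytest.raises(ValueError):
            ScanProtocol(sequence="PDlike")


class TestSimulateScan:
    def test_noise_free_scan_deterministic(self, truth):
        proto = ScanProtocol(noise_sigma=0.0, fov=60.0, matrix=30)
        a = simulate_scan(truth, proto)
        b = simulate_scan(truth, proto)
        np.testing.assert_array_equal(a.data, b.data)

    def test_seed_required_with_noise(self, truth):
        proto = ScanProtocol(noise_sigma=2.0, fov=60.0, matrix=30)
        with pytest.raises(ValueError, match="seed"):
            simulate_scan(truth, proto)

    def test_slice_count_geometry(self):
        # 103 mm of 1 mm truth: 2 mm slices -> 52, 4 mm slices -> 26 (ceiling)
        data = np.zeros((10, 10, 103))
        vol = ImageVolume(data, origin=(0.5, 0.5, 0.5))
        thin = simulate_scan(vol, ScanProtocol(noise_sigma=0, slice_thickness=2, fov=10, matrix=10))
        thick = simulate_scan(vol, ScanProtocol(noise_sigma=0, slice_thickness=4, fov=10, matrix=10))
        assert thin.shape[2] == 52
        assert thick.shape[2] == 26
        assert thin.spacing[2] == 2.0 and thick.spacing[2] == 4.0

    def test_output_matrix_and_spacing(self, truth):
        proto = ScanProtocol(noise_sigma=0.0, fov=90.0, matrix=45, slice_thickness=2.0)
        out = simulate_scan(truth, proto)
        assert out.shape[:2] == (45, 45)
        assert out.spacing[0] == pytest.approx(2.0)

    def test_finer_target_than_truth_rejected(self, truth):
        proto = ScanProtocol(noise_sigma=0.0, fov=30.0, matrix=60)  # 0.5 mm pixels
        with pytest.raises(ValueError, match="finer"):
            simulate_scan(truth, proto)

    def test_nan_shift_rejected(self, truth):
        proto = ScanProtocol(noise_sigma=0.0, fov=60.0, matrix=30)
        with pytest.raises(ValueError, match="finite"):
            simulate_scan(truth, proto, reposition=(np.nan, 0, 0))

    def test_negative_shift_allowed(self, truth):
        proto = ScanProtocol(noise_sigma=0.0, fov=60.0, matrix=30)
        out = simulate_scan(truth, proto, reposition=(-0.7, 0.3, -0.2))
        assert out.shape == (30, 30, 14)  # ceil(40 mm / 3 mm slices)

    def test_nex_noise_ratio_half(self):
        """Background noise SD at NEX=4 vs NEX=1 is 0.5 within 3 MC standard errors.

        On pure background the magnitude is Rayleigh with SD proportional to
        sigma_eff = sigma / sqrt(NEX), so the ratio is exactly 0.5 in
        expectation regardless of the Rayleigh-vs-Gaussian regime.
        """
        zeros = ImageVolume(np.zeros((100, 100, 1)), origin=(0.5, 0.5, 0.5))
        sds = {}
        for nex in (1, 4):
            proto = ScanProtocol(
                nex=nex, noise_sigma=5.0, fov=100.0, matrix=100, slice_thickness=1.0
            )
            out = simulate_scan(zeros, proto, seed=1234)
            sds[nex] = out.data.ravel()[:10_000].std()
        ratio = sds[4] / sds[1]
        n = 10_000
        # SE of an SD ratio ~ sqrt(2 * (1/(2n) + 1/(2n))) = sqrt(2/n) relative
        mc_se = 0.5 * np.sqrt(2.0 / n)
        assert abs(ratio - 0.5) < 3 * mc_se + 0.01

    def test_intensity_scale_applied(self, truth):
        base = ScanProtocol(noise_sigma=0.0, fov=60.0, matrix=30)
        scaled = ScanProtocol(noise_sigma=0.0, fov=60.0, matrix=30, intensity_scale=2.0)
        a = simulate_scan(truth, base)
        b = simulate_scan(truth, scaled)
        np.testing.assert_allclose(b.data, 2.0 * a.data)


class TestOneFactorGrid:
    def test_seven_distinct_conditions(self):
        base = ScanProtocol(noise_sigma=0.0)
        conditions, members = one_factor_grid(base)
        assert len(conditions) == 7  # 3 + 3 + 3 minus the shared default twice
        assert sorted(members) == ["fov", "nex", "slice_thickness"]
        assert all(len(keys) == 3 for keys in members.values())
        default_key = ScanProtocol(noise_sigma=0.0).condition_key()
        assert sum(default_key in keys for keys in members.values()) == 3

    def test_family_sweeps_vary_only_their_factor(self):
        conditions, members = one_factor_grid(ScanProtocol(noise_sigma=0.0))
        for key in members["nex"]:
            proto = conditions[key]
            assert proto.slice_thickness == 3.0 and proto.fov == 256.0
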