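"""Phantom geometry, texture fields, ROI rasterization, population bounds."""

import numpy as np
import pytest

from radphantom.phantom import (
    MaterialSpec,
    PhantomSpec,
    build_phantom,
    default_materials,
    make_cylindrical_roi,
    synth_population_bounds,
)


class TestMaterials:
    def test_twenty_pairwise_distinct_materials(self):
        mats = default_materials()
        assert len(mats) == 20
        fingerprints = {
            (
                m.base_intensity["T1like"],
                m.base_intensity["T2like"],
                m.texture_amplitude,
                m.texture_correlation_length,
            )
            for m in mats
        }
        assert len(fingerprints) == 20

    def test_invalid_material_rejected(self):
        with pytest.raises(ValueError):
            MaterialSpec(1, {"T1like": -5.0}, 1.0, 1.0)
        with pytest.raises(ValueError):
            MaterialSpec(1, {"T1like": 5.0}, -1.0, 1.0)
        with pytest.raises(ValueError):
            MaterialSpec(0, {"T1like": 5.0}, 1.0, 1.0)


class TestBuildPhantom:
    def test_default_build_returns_twenty_masks(self, small_phantom):
        _, truth, masks = small_phantom
        assert len(masks) == 20
        assert truth.shape == (145, 178, 103)

    def test_masks_pairwise_disjoint(self, small_phantom):
        _, _, masks = small_phantom
        total = np.zeros(masks[0].shape, dtype=int)
        for m in masks:
            total += m.mask
        assert total.max() == 1

    def test_zero_amplitude_material_is_constant(self):
        mats = default_materials()
        mats[0] = MaterialSpec(1, mats[0].base_intensity, 0.0, 1.0)
        spec = PhantomSpec(materials=mats)
        truth, masks = build_phantom(spec, seed=5)
        vals = truth.data[masks[0].mask]
        assert np.all(vals == mats[0].base_intensity["T1like"])

    def test_texture_matches_material_amplitude(self, small_phantom):
        spec, truth, masks = small_phantom
        for mat, mask in zip(spec.materials[:3], masks[:3]):
            vals = truth.data[mask.mask]
            assert vals.mean() == pytest.approx(
                mat.base_intensity["T1like"], rel=0.05
            )
            if mat.texture_amplitude > 0:
                assert vals.std() == pytest.approx(mat.texture_amplitude, rel=0.25)

    def test_deterministic_under_seed(self):
        spec = PhantomSpec()
        t1, _ = build_phantom(spec, seed=9)
        t2, _ = build_phantom(spec, seed=9)
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            build_phantom(PhantomSpec(), seed=None)

    def test_overlapping_inserts_rejected(self):
        centers = PhantomSpec().insert_centers
        centers = [centers[0]] * 2 + centers[2:]
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(insert_centers=centers)


class TestCylindricalROI:
    def test_roi_inside_its_insert(self, small_phantom):
        spec, truth, masks = small_phantom
        roi = make_cylindrical_roi(spec.insert_centers[0], 18.0, 100.0, truth)
        assert roi.count() > 0
        assert not (roi.mask & ~masks[0].mask).any()

    def test_voxel_count_matches_analytic_volume(self, small_phantom):
        spec, truth, _ = small_phantom
        roi = make_cylindrical_roi(spec.insert_centers[5], 18.0, 100.0, truth)
        analytic = np.pi * 9.0**2 * 100.0
        assert roi.count() * truth.voxel_volume() == pytest.approx(analytic, rel=0.05)

    def test_small_roi_strictly_smaller(self, small_phantom):
        spec, truth, _ = small_phantom
        big = make_cylindrical_roi(spec.insert_centers[3], 18.0, 100.0, truth)
        small = make_cylindrical_roi(spec.insert_centers[3], 12.0, 100.0, truth)
        assert small.count() < big.count()
        assert not (small.mask & ~big.mask).any()

    def test_outside_grid_rejected(self, small_phantom):
        _, truth, _ = small_phantom
        with pytest.raises(ValueError, match="outside the grid"):
            make_cylindrical_roi((5.0, 5.0, 51.5), 18.0, 100.0, truth)
        with pytest.raises(ValueError):
            make_cylindrical_roi((70.0, 90.0, 51.5), -1.0, 100.0, truth)


class TestPopulationBounds:
    def test_mean_sd_arithmetic(self):
        b = synth_population_bounds(["f"], means={"f": 10.0}, sds={"f": 2.0})
        assert b.lower("f") == 6.0 and b.upper("f") == 14.0
        assert b.contains_value("f", 6.0) and b.contains_value("f", 14.0)
        assert not b.contains_value("f", 14.001)

    def test_zero_sd_degenerate(self):
        b = synth_population_bounds(["f"], means={"f": 3.0}, sds={"f": 0.0})
        assert b.lower("f") == b.upper("f") == 3.0

    def test_unknown_feature_rejected(self):
        b = synth_population_bounds(["f"], means={"f": 1.0}, sds={"f": 1.0})
        with pytest.raises(KeyError):
            b.contains_value("g", 0.0)
        with pytest.raises(KeyError):
            synth_population_bounds(["g"], means={"f": 1.0}, sds={"f": 1.0})

    def test_reference_table_reproducible(self, rng):
        import pandas as pd

        ref = pd.DataFrame({"a": rng.normal(5, 1, 40), "b": rng.normal(-2, 3, 40)})
        b1 = synth_population_bounds(["a", "b"], reference_values=ref, seed=3)
        b2 = synth_population_bounds(["a", "b"], reference_values=ref, seed=3)
        assert b1.means == b2.means and b1.sds == b2.sds
        assert b1.lower("a") <= b1.upper("a")
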