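"""Synthetic generators: determinism, calibration recovery, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import i0

from cellmorph.edge_fractal import box_count, extract_edge_mask, peripheral_roughness
from cellmorph.morphometry import measure_labels
from cellmorph.syngen import (
    GeneratorPreset, PlacementError, _draw_phi, fd_to_beta, list_presets,
    load_preset, make_fluor_cell, make_fractal_contour, make_height_map,
    make_nucleus_field,
)


class TestPresets:
    def test_library_loads_and_validates(self):
        names = list_presets()
        assert {"u2os_control", "u2os_capsaicin", "saos2_control"} <= set(names)
        for n in names:
            p = load_preset(n)
            assert p.nuclear_area_mean > 0
            assert 1.0 <= p.target_fd < 1.5
            assert 0 < p.nc_ratio_mean < 1

    def test_override(self):
        p = load_preset("u2os_control", noise_sd=0.0)
        assert p.noise_sd == 0.0

    def test_invalid_values_raise(self):
        with pytest.raises(ValueError):
            GeneratorPreset(target_fd=1.6)
        with pytest.raises(ValueError):
            GeneratorPreset(nc_ratio_mean=1.2)
        with pytest.raises(ValueError):
            GeneratorPreset(nuclear_area_mean=-5)
        with pytest.raises(KeyError):
            load_preset("no_such_condition")


class TestDeterminism:
    def test_nucleus_field_bit_identical(self):
        p = load_preset("u2os_control", nuclear_area_mean=120.0, nuclear_area_sd=20.0)
        f1 = make_nucleus_field(p, 10, seed=5)
        f2 = make_nucleus_field(p, 10, seed=5)
        assert np.array_equal(f1.image.data, f2.image.data)
        assert np.array_equal(f1.labels, f2.labels)
        pd.testing.assert_frame_equal(f1.truth, f2.truth)

    def test_contour_and_fluorcell_bit_identical(self):
        p = load_preset("u2os_capsaicin")
        c1 = make_fractal_contour(p, 256, seed=9)
        c2 = make_fractal_contour(p, 256, seed=9)
        assert np.array_equal(c1.filled, c2.filled)
        assert np.array_equal(c1.polygon, c2.polygon)
        f1 = make_fluor_cell(p, seed=9)
        f2 = make_fluor_cell(p, seed=9)
        assert np.array_equal(f1.src.data, f2.src.data)

    def test_different_seeds_differ(self):
        p = load_preset("u2os_capsaicin")
        assert not np.array_equal(make_fluor_cell(p, seed=1).src.data,
                                  make_fluor_cell(p, seed=2).src.data)


class TestNucleusField:
    def test_drawn_area_mean_within_3_sem(self):
        p = load_preset("u2os_control")  # 553.7 µm²
        nf = make_nucleus_field(p, 200, seed=12)
        areas = nf.truth.area_um2
        sem = areas.std(ddof=1) / np.sqrt(len(areas))
        assert abs(areas.mean() - 553.7) <= 3 * sem
        assert len(nf.truth) == 200
        assert nf.labels.max() == 200

    def test_single_circular_nucleus_orientation_undefined(self):
        p = load_preset("u2os_control", aspect_ratio_mean=1.0)
        nf = make_nucleus_field(p, 1, seed=3)
        assert not nf.truth.orientation_defined[0]
        rec = measure_labels(nf.labels, p.pixel_size)[0]
        assert rec.orientation_class == "undefined"

    def test_perpendicular_bias_fraction_matches_integration_oracle(self):
        kappa = 20.0
        rng = np.random.default_rng(8)
        phis = _draw_phi(rng, "perpendicular_biased", kappa, 500)
        frac = np.mean(np.cos(2 * np.deg2rad(phis)) <= -0.5)
        # oracle: ∫ von-Mises(2φ; µ=180°, κ) over 2φ ∈ [120°, 240°]
        dens = lambda t: np.exp(kappa * np.cos(t - np.pi)) / (2 * np.pi * i0(kappa))
        expect, _ = quad(dens, 2 * np.pi / 3, 4 * np.pi / 3)
        assert expect > 0.99
        assert frac > 0.9
        assert frac == pytest.approx(expect, abs=3 * np.sqrt(expect * (1 - expect) / 500) + 0.01)

    def test_nuclei_do_not_overlap_and_are_separated(self):
        p = load_preset("u2os_control", nuclear_area_mean=150.0, nuclear_area_sd=30.0)
        nf = make_nucleus_field(p, 30, seed=2)
        # labels already enforce disjointness; check 8-neighbor separation
        from scipy import ndimage as ndi
        for lab in range(1, 31):
            grown = ndi.binary_dilation(nf.labels == lab, np.ones((3, 3), bool))
            touched = set(np.unique(nf.labels[grown])) - {0, lab}
            assert not touched

    def test_density_limit_raises_placement_error(self):
        p = load_preset("u2os_control", nuclear_area_mean=400.0, nuclear_area_sd=10.0)
        with pytest.raises(PlacementError, match="dense"):
            make_nucleus_field(p, 50, seed=1, field_shape=(220, 220), max_retries=40)

    def test_ground_truth_cos2phi_consistent(self):
        p = load_preset("u2os_stretch")
        nf = make_nucleus_field(p, 20, seed=6)
        np.testing.assert_allclose(
            nf.truth.cos2phi, np.cos(2 * np.deg2rad(nf.truth.phi_deg)), atol=1e-9)


class TestFractalContour:
    def test_smooth_target_measures_near_one(self):
        p = load_preset("u2os_control", target_fd=1.0)
        fds = []
        for s in range(5):
            fc = make_fractal_contour(p, 1024, seed=100 + s)
            fds.append(box_count(fc.edge).fd)
        assert 0.97 <= np.mean(fds) <= 1.03

    def test_koch_class_target_recovered(self):
        target = float(np.log(4) / np.log(3))  # 1.2619, the Koch benchmark
        p = load_preset("u2os_control", target_fd=round(target, 4))
        fds = [box_count(make_fractal_contour(p, 1024, seed=200 + s).edge).fd
               for s in range(8)]
        assert np.mean(fds) == pytest.approx(target, abs=0.05)

    def test_contour_closed_star_shaped_and_edge_valid(self):
        p = load_preset("u2os_capsaicin")
        fc = make_fractal_contour(p, 512, seed=4)
        # star-shaped: polygon radius strictly positive, single edge component
        c = 512 / 2
        r = np.hypot(fc.polygon[:, 0] - c, fc.polygon[:, 1] - c)
        assert (r > 0).all()
        from scipy import ndimage as ndi
        _, n = ndi.label(fc.edge.mask, structure=np.ones((3, 3), bool))
        assert n == 1
        # one pixel wide: no edge pixel interior to the filled region
        interior = ndi.binary_erosion(fc.filled, np.ones((3, 3), bool))
        assert not (fc.edge.mask & interior).any()

    def test_measured_fd_monotone_in_roughness(self):
        # increasing spectral roughness (decreasing β) must not decrease FD
        means = []
        for tgt in (1.05, 1.25):
            p = load_preset("u2os_control", target_fd=tgt)
            fds = [box_count(make_fractal_contour(p, 512, seed=300 + s).edge).fd
                   for s in range(6)]
            means.append(np.mean(fds))
        assert means[1] > means[0]
        assert fd_to_beta(1.05) > fd_to_beta(1.25)

    def test_out_of_range_target_raises(self):
        with pytest.raises(ValueError):
            fd_to_beta(1.6)
        with pytest.raises(ValueError):
            fd_to_beta(0.9)


class TestHeightMap:
    def _contour(self):
        p = load_preset("saos2_control")
        return make_fractal_contour(p, 256, seed=7)

    def test_zero_texture_zero_roughness(self):
        fc = self._contour()
        hm = make_height_map(fc, interior_height=400.0, peripheral_texture_sd=0.0,
                             noise_sd=0.0, seed=1)
        res = peripheral_roughness(hm, fc.filled, band_width=10)
        assert res.peripheral_rms == 0.0
        assert hm.data[~fc.filled].max() == 0.0

    def test_texture_sd_recovered_within_10pct(self):
        fc = self._contour()
        s = 30.0
        hm = make_height_map(fc, interior_height=400.0, peripheral_texture_sd=s,
                             noise_sd=0.0, seed=2)
        res = peripheral_roughness(hm, fc.filled, band_width=10)
        assert res.peripheral_rms == pytest.approx(s, rel=0.10)

    def test_seed_changes_pixels_not_summary(self):
        fc = self._contour()
        h1 = make_height_map(fc, 400.0, peripheral_texture_sd=30.0, seed=10)
        h2 = make_height_map(fc, 400.0, peripheral_texture_sd=30.0, seed=11)
        assert not np.array_equal(h1.data, h2.data)
        r1 = peripheral_roughness(h1, fc.filled, 10).peripheral_rms
        r2 = peripheral_roughness(h2, fc.filled, 10).peripheral_rms
        assert r1 == pytest.approx(r2, rel=0.15)

    def test_nonpositive_height_raises(self):
        with pytest.raises(ValueError):
            make_height_map(self._contour(), interior_height=0.0)


class TestFluorCell:
    def test_noiseless_ctcf_closed_form_exact(self):
        from cellmorph.fluor_quant import background_ring, ctcf

        p = load_preset("u2os_capsaicin", noise_sd=0.0)
        fc = make_fluor_cell(p, seed=13)
        ring = background_ring(fc.cell_mask, gap=2, width=5)
        rec = ctcf(fc.src.data, fc.nuclear_mask, ring)
        assert rec.ctcf == pytest.approx(fc.truth.expected_ctcf[0], rel=1e-12)

    def test_no_enrichment_gives_cytoplasmic_increment_times_area(self):
        from cellmorph.fluor_quant import background_ring, ctcf

        p = load_preset("u2os_control", noise_sd=0.0, nuclear_src_fold=1.0)
        fc = make_fluor_cell(p, seed=14)
        ring = background_ring(fc.cell_mask, gap=2, width=5)
        rec = ctcf(fc.src.data, fc.nuclear_mask, ring)
        assert rec.ctcf == pytest.approx(
            p.cytoplasm_level * fc.nuclear_mask.sum(), rel=1e-12)

    def test_nucleus_strictly_inside_cell(self):
        p = load_preset("u2os_capsaicin")
        fc = make_fluor_cell(p, seed=15)
        assert not (fc.nuclear_mask & ~fc.cell_mask).any()
        assert fc.nuclear_mask.sum() < fc.cell_mask.sum()

    def test_nc_ratio_calibration_recovered(self):
        from cellmorph.morphometry import nc_ratio

        p = load_preset("u2os_capsaicin")  # N/C 0.4376
        vals = [nc_ratio(fc.nuclear_mask, fc.cell_mask, p.pixel_size).nc_ratio
                for fc in (make_fluor_cell(p, seed=600 + s) for s in range(100))]
        vals = np.array(vals)
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 0.4376) <= 3 * sem + 0.01
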