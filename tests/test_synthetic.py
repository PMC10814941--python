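"""Generator determinism and planted-effect recovery through the extractors."""

import numpy as np
import pandas as pd
import pytest

from dermafuse import octtexture as oct
from dermafuse import spectra as sp
from dermafuse import synthetic as syn
from dermafuse import ultrasound as us


def params(**overrides):
    base = dict(
        melanin_slope=0.1, hemoglobin_dip_depth=0.1, nir_slope=-1e-4,
        texture_correlation_length_px=3.0, texture_contrast=20.0,
        mean_intensity=140.0, shape_eccentricity=0.3,
        boundary_roughness=0.1, size_mm=4.0,
    )
    base.update(overrides)
    return syn.ClassGeneratorParams(**base)


class TestSpectrumGenerator:
    def test_all_zero_knobs_give_flat_spectrum(self, rng):
        p = params(melanin_slope=0.0, hemoglobin_dip_depth=0.0, nir_slope=0.0,
                   noise_sd_spectrum=0.0)
        s = syn.generate_spectrum(p, "lesion", rng)
        assert np.ptp(s.reflectance) == pytest.approx(0.0, abs=1e-12)
        od = sp.to_optical_density(s)
        assert sp.melanin_index(od) == pytest.approx(0.0, abs=1e-9)
        assert sp.erythema_index(od) == pytest.approx(0.0, abs=1e-9)
        assert sp.hemoglobin_index(od) == pytest.approx(0.0, abs=1e-9)

    def test_dip_depth_orders_erythema(self, rng):
        out = {}
        for d in (0.1, 0.3):
            p = params(hemoglobin_dip_depth=d, noise_sd_spectrum=0.0)
            od = sp.to_optical_density(syn.generate_spectrum(p, "lesion", rng))
            out[d] = (sp.erythema_index(od), sp.hemoglobin_index(od))
        assert out[0.3][0] > out[0.1][0]
        assert out[0.3][1] > out[0.1][1]

    def test_melanin_slope_recovered_from_noisy_draws(self, rng):
        # other chromophore knobs at zero so only the melanin ramp and the
        # reflectance noise act (the NIR tilt shifts OD700 and would bias M)
        p = params(melanin_slope=0.02, hemoglobin_dip_depth=0.0, nir_slope=0.0)
        ms = []
        for _ in range(100):
            od = sp.to_optical_density(syn.generate_spectrum(p, "lesion", rng))
            ms.append(sp.melanin_index(od))
        # raw melanin index is 100 * melanin_slope (ramp spans 620-700 nm)
        assert np.mean(ms) == pytest.approx(2.0, rel=0.10)

    def test_nir_slope_recovered_by_linearity_fit(self, rng):
        slopes = {}
        for nir in (-3e-4, -1e-4):
            p = params(nir_slope=nir, melanin_slope=0.0, noise_sd_spectrum=0.0)
            s = syn.generate_spectrum(p, "lesion", rng)
            slopes[nir] = sp.linearity_fit(s)[0]
        assert slopes[-3e-4] == pytest.approx(-3e-4, rel=0.05)
        assert slopes[-3e-4] < slopes[-1e-4]

    def test_healthy_site_ignores_class_chromophores(self):
        # healthy spectra depend only on the fixed baseline, not the class
        a = syn.generate_spectrum(
            params(melanin_slope=0.9), "healthy", np.random.default_rng(42)
        )
        b = syn.generate_spectrum(
            params(melanin_slope=0.0), "healthy", np.random.default_rng(42)
        )
        assert np.array_equal(a.reflectance, b.reflectance)
        # and carries the baseline melanin level, clearly below a dark lesion
        lesion = syn.generate_spectrum(params(melanin_slope=0.9), "lesion",
                                       np.random.default_rng(42))
        od_h = sp.to_optical_density(a)
        od_l = sp.to_optical_density(lesion)
        assert sp.melanin_index(od_h) < sp.melanin_index(od_l)


class TestBScanGenerator:
    def test_zero_contrast_gives_constant_roi(self, rng):
        p = params(texture_contrast=0.0)
        scan, roi, bg = syn.generate_bscan(p, rng)
        out = oct.extract_oct_features(scan, roi, bg)
        assert out["energy_a0_d1"] == pytest.approx(1.0)
        assert out["contrast_a0_d1"] == pytest.approx(0.0)

    def test_same_seed_bit_identical(self):
        a = syn.generate_bscan(params(), np.random.default_rng(99))[0]
        b = syn.generate_bscan(params(), np.random.default_rng(99))[0]
        assert np.array_equal(a.pixels, b.pixels)

    def test_roi_satisfies_physical_minimum(self, rng):
        scan, roi, _ = syn.generate_bscan(params(), rng)
        assert roi.height_px * scan.axial_pitch_um >= oct.MIN_ROI_DEPTH_UM
        assert roi.width_px * scan.lateral_pitch_um >= oct.MIN_ROI_WIDTH_UM

    def test_short_correlation_length_raises_d1_contrast(self, rng):
        means = {}
        for L in (1.0, 8.0):
            vals = []
            for _ in range(20):
                scan, roi, bg = syn.generate_bscan(
                    params(texture_correlation_length_px=L), rng
                )
                out = oct.extract_oct_features(scan, roi, bg)
                vals.append(out["contrast_a0_d1"])
            means[L] = np.mean(vals)
        assert means[1.0] > means[8.0]


class TestMaskGenerator:
    def test_smooth_identical_annotators(self, rng):
        p = params(boundary_roughness=0.0, annotator_jitter=0.0)
        a, b = syn.generate_mask_pair(p, rng)
        assert np.array_equal(a.mask, b.mask)

    def test_round_lesion_high_circularity(self, rng):
        p = params(shape_eccentricity=0.0, boundary_roughness=0.0,
                   annotator_jitter=0.01)
        a, b = syn.generate_mask_pair(p, rng)
        feats = us.shape_features(us.consensus_roi(a, b))
        assert feats["Circularity"] >= 0.9

    def test_eccentricity_recovered(self, rng):
        p = params(shape_eccentricity=0.8, boundary_roughness=0.0,
                   annotator_jitter=0.01)
        measured = []
        for _ in range(50):
            a, b = syn.generate_mask_pair(p, rng)
            measured.append(
                us.shape_features(us.consensus_roi(a, b))["Eccentricity"]
            )
        assert np.mean(measured) == pytest.approx(0.8, abs=0.05)

    def test_eccentricity_monotone_in_knob(self, rng):
        means = {}
        for e in (0.2, 0.5, 0.8):
            p = params(shape_eccentricity=e, boundary_roughness=0.0,
                       annotator_jitter=0.01)
            vals = []
            for _ in range(10):
                a, b = syn.generate_mask_pair(p, rng)
                vals.append(us.shape_features(us.consensus_roi(a, b))["Eccentricity"])
            means[e] = np.mean(vals)
        assert means[0.2] < means[0.5] < means[0.8]


class TestCohort:
    def test_presets_exist_and_overlapping_is_compressed(self):
        ws = syn.preset("well-separated")
        ov = syn.preset("overlapping")
        assert set(ws) == set(syn.DIAGNOSIS_LABELS if hasattr(syn, 'DIAGNOSIS_LABELS') else ws)
        mel_ws = [p.melanin_slope for p in ws.values()]
        mel_ov = [p.melanin_slope for p in ov.values()]
        assert np.std(mel_ov) < np.std(mel_ws)
        with pytest.raises(ValueError):
            syn.preset("nonexistent")

    def test_in_memory_simulation_deterministic(self):
        spec = syn.CohortSpec(
            tumors_per_class={"benign": 1, "nodular_bcc": 1, "superficial_bcc": 1},
            observations_per_tumor=2, seed=3,
        )
        a = syn.simulate_modalities(spec, "well-separated")
        b = syn.simulate_modalities(spec, "well-separated")
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_observations_per_tumor_respected(self, tiny_cohort):
        drs, oct_, usf, labels = tiny_cohort
        for frame in (drs, oct_, usf):
            assert (frame.groupby("tumor_id").size() == 4).all()

    def test_default_cohort_inventory_on_disk(self, tmp_path):
        spec = syn.CohortSpec(observations_per_tumor=1, seed=5)
        paths = syn.generate_cohort(spec, "well-separated", tmp_path)
        labels = pd.read_csv(paths["labels"])
        assert len(labels) == 37
        counts = labels["label"].value_counts()
        assert counts["superficial_bcc"] == 15
        assert counts["benign"] == 10
        oct_manifest = pd.read_csv(paths["oct_manifest"])
        assert len(oct_manifest) == 37  # one image per tumor at 1 obs/tumor
        # every referenced file exists
        for rel in oct_manifest["path"]:
            assert (tmp_path / rel).exists()

    def test_cohort_manifests_byte_identical_across_runs(self, tmp_path):
        spec = syn.CohortSpec(
            tumors_per_class={"benign": 2, "nodular_bcc": 1, "superficial_bcc": 1,
                              "pigmented_bcc": 1, "morpheaform_bcc": 1,
                              "infiltrative_ulcerative_bcc": 1},
            observations_per_tumor=1, seed=11,
        )
        p1 = syn.generate_cohort(spec, "well-separated", tmp_path / "a")
        p2 = syn.generate_cohort(spec, "well-separated", tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
        # and the pixel data too
        m = pd.read_csv(p1["oct_manifest"])
        rel = m["path"].iloc[0]
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_file_based_extraction_roundtrip(self, tmp_path):
        spec = syn.CohortSpec(
            tumors_per_class={"benign": 1, "nodular_bcc": 1, "superficial_bcc": 1},
            observations_per_tumor=2, seed=13,
        )
        paths = syn.generate_cohort(spec, "well-separated", tmp_path)
        drs = sp.extract_drs_from_manifest(paths["drs_manifest"])
        octf = oct.extract_oct_from_manifest(paths["oct_manifest"])
        usf = us.extract_us_from_manifest(paths["us_manifest"])
        assert len(drs) == len(octf) == len(usf) == 6
        assert set(sp.DRS_FEATURES) <= set(drs.columns)
        assert len(set(oct.oct_feature_names()) & set(octf.columns)) == 65
        assert set(us.US_FEATURES) <= set(usf.columns)
        assert not octf[oct.oct_feature_names()].isna().any().any()
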