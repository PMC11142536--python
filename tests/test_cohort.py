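"""Synthetic cohort generator: structure, determinism and signal contracts."""

import numpy as np
import pytest
from scipy.stats import ttest_ind

from melafuse import (MELANOMA, NEVUS, CohortConfig, PatientEffects,
                      generate_cohort, generate_patch, generate_spectrum)
from melafuse.cohort import CohortConfigError, signal_peak_bins


def _effects(label=MELANOMA, ims=True, morph=True):
    return PatientEffects(patient_id="P0000", label=label,
                          ims_informative=ims, morph_informative=morph)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"class_prevalence": 0.0}, "class_prevalence"),
            ({"class_prevalence": 1.5}, "class_prevalence"),
            ({"n_patients": 0}, "n_patients"),
            ({"patch_px": 4}, "patch_px"),
            ({"mz_min": 650.0}, "mz"),
            ({"mz_min": 900.0, "mz_max": 800.0}, "mz"),
            ({"frac_ims_uninformative_patients": 1.2},
             "frac_ims_uninformative_patients"),
            ({"noise_sd": -1.0}, "noise_sd"),
            ({"mz_jitter_bins": -1}, "mz_jitter_bins"),
        ],
    )
    def test_invalid_field_is_named_in_error(self, kwargs, field):
        with pytest.raises(CohortConfigError, match=field):
            CohortConfig(**kwargs)

    def test_defaults_are_valid(self):
        CohortConfig()


class TestCohortStructure:
    def test_degenerate_single_spot(self):
        cfg = CohortConfig(n_patients=1, spots_per_patient_mean=1.0,
                           n_axis_bins=50, n_signal_peaks=2, patch_px=8, seed=0)
        cohort = generate_cohort(cfg)
        # Poisson(1) truncated at >= 1 can exceed 1; a single patient always
        # contributes at least one complete record triple
        assert len(cohort.records) >= 1
        assert len(cohort.spectra) == len(cohort.records)
        assert len(cohort.patches) == len(cohort.records)

    def test_total_spots_near_expected_cohort_scale(self):
        # full cohort scale: 331 patients x ~21 spots; spectra/patches kept
        # tiny so only the counting behavior is exercised
        cfg = CohortConfig(n_patients=331, spots_per_patient_mean=21.0,
                           n_axis_bins=8, n_signal_peaks=1, patch_px=8, seed=5)
        cohort = generate_cohort(cfg)
        expected = 331 * 21
        sd = np.sqrt(expected)
        assert abs(len(cohort.records) - expected) < 5 * sd

    def test_one_label_per_patient_and_unique_spot_ids(self, tiny_cohort):
        by_patient = {}
        seen = set()
        for r in tiny_cohort.records:
            assert r.spot_id not in seen
            seen.add(r.spot_id)
            by_patient.setdefault(r.patient_id, set()).add(r.label)
        assert all(len(labels) == 1 for labels in by_patient.values())

    def test_seed_reproducibility_is_bit_identical(self):
        cfg = CohortConfig(n_patients=3, spots_per_patient_mean=3.0,
                           n_axis_bins=100, n_signal_peaks=3, patch_px=16, seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert [r.spot_id for r in a.records] == [r.spot_id for r in b.records]
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensity, sb.intensity)
        for pa, pb in zip(a.patches, b.patches):
            assert np.array_equal(pa.pixels, pb.pixels)

    def test_uninformative_fractions_give_disjoint_patient_sets(self):
        cfg = CohortConfig(n_patients=20, spots_per_patient_mean=2.0,
                           n_axis_bins=50, n_signal_peaks=2, patch_px=8,
                           frac_ims_uninformative_patients=0.3,
                           frac_morph_uninformative_patients=0.3, seed=1)
        cohort = generate_cohort(cfg)
        ims_off = {e.patient_id for e in cohort.effects if not e.ims_informative}
        morph_off = {e.patient_id for e in cohort.effects if not e.morph_informative}
        assert len(ims_off) == 6 and len(morph_off) == 6
        assert not ims_off & morph_off


class TestSpectrumGeneration:
    def test_all_nuisance_off_gives_deterministic_class_template(self):
        cfg = CohortConfig(noise_sd=0.0, baseline_amplitude=0.0,
                           tic_scale_sd=0.0, mz_jitter_bins=0,
                           ims_patient_sd=0.0, n_axis_bins=200,
                           n_signal_peaks=4, seed=3)
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(99)
        s1 = generate_spectrum(MELANOMA, _effects(), cfg, rng1)
        s2 = generate_spectrum(MELANOMA, _effects(), cfg, rng2)
        assert np.array_equal(s1.intensity, s2.intensity)  # rng plays no role
        nev = generate_spectrum(NEVUS, _effects(NEVUS), cfg, rng1)
        assert not np.array_equal(s1.intensity, nev.intensity)

    def test_zero_effect_gives_null_t_statistics_at_peaks(self):
        cfg = CohortConfig(ims_effect_size=0.0, ims_patient_sd=0.0,
                           tic_scale_sd=0.0, mz_jitter_bins=0,
                           n_axis_bins=200, n_signal_peaks=4, seed=3)
        rng = np.random.default_rng(7)
        bins = signal_peak_bins(cfg)
        mel = np.array([generate_spectrum(MELANOMA, _effects(), cfg, rng).intensity[bins]
                        for _ in range(500)])
        nev = np.array([generate_spectrum(NEVUS, _effects(NEVUS), cfg, rng).intensity[bins]
                        for _ in range(500)])
        t, _ = ttest_ind(mel, nev, axis=0)
        assert np.all(np.abs(t) < 4.0)

    def test_large_effect_separates_peak_heights(self):
        # effect 5x the noise sd: per-peak class AUC must exceed 0.95,
        # measured by Mann-Whitney pair counting on the drawn apex heights
        cfg = CohortConfig(ims_effect_size=2.0, noise_sd=0.4,
                           ims_patient_sd=0.0, tic_scale_sd=0.0,
                           mz_jitter_bins=0, n_axis_bins=200,
                           n_signal_peaks=4, seed=3)
        rng = np.random.default_rng(7)
        bins = signal_peak_bins(cfg)
        mel = np.array([generate_spectrum(MELANOMA, _effects(), cfg, rng).intensity[bins]
                        for _ in range(500)])
        nev = np.array([generate_spectrum(NEVUS, _effects(NEVUS), cfg, rng).intensity[bins]
                        for _ in range(500)])
        for j, sign in enumerate([1, -1, 1, -1][: mel.shape[1]]):
            hi, lo = (mel[:, j], nev[:, j]) if sign > 0 else (nev[:, j], mel[:, j])
            greater = (hi[:, None] > lo[None, :]).sum()
            ties = (hi[:, None] == lo[None, :]).sum()
            auc = (greater + 0.5 * ties) / (len(hi) * len(lo))
            assert auc > 0.95

    def test_intensities_are_nonnegative(self, tiny_cohort):
        for s in tiny_cohort.spectra:
            assert np.all(s.intensity >= 0)


class TestPatchGeneration:
    def test_patch_shape_and_range(self):
        cfg = CohortConfig(patch_px=96, seed=0)
        p = generate_patch(MELANOMA, _effects(), cfg, np.random.default_rng(0))
        assert p.pixels.shape == (96, 96, 3)
        assert p.pixels.dtype == np.uint8

    def test_same_rng_state_gives_identical_patch(self):
        cfg = CohortConfig(patch_px=32, seed=0)
        p1 = generate_patch(MELANOMA, _effects(), cfg, np.random.default_rng(5))
        p2 = generate_patch(MELANOMA, _effects(), cfg, np.random.default_rng(5))
        assert np.array_equal(p1.pixels, p2.pixels)

    def test_zero_effect_equalizes_class_pixel_statistics(self):
        cfg = CohortConfig(morph_effect_size=0.0, morph_patient_sd=0.0,
                           patch_px=32, seed=0)
        rng = np.random.default_rng(21)
        mel = np.array([generate_patch(MELANOMA, _effects(), cfg, rng).pixels.mean()
                        for _ in range(500)])
        nev = np.array([generate_patch(NEVUS, _effects(NEVUS), cfg, rng).pixels.mean()
                        for _ in range(500)])
        t, _ = ttest_ind(mel, nev)
        assert abs(t) < 4.0

    def test_invalid_label_rejected(self):
        cfg = CohortConfig(patch_px=16)
        with pytest.raises(CohortConfigError):
            generate_patch("carcinoma", _effects(), cfg, np.random.default_rng(0))


def test_roundtrip_write_load(tmp_path, tiny_cohort):
    from melafuse import load_cohort, write_cohort

    write_cohort(tiny_cohort, tmp_path)
    records, spectra, patches = load_cohort(tmp_path)
    assert [r.spot_id for r in records] == [r.spot_id for r in tiny_cohort.records]
    assert [r.label for r in records] == [r.label for r in tiny_cohort.records]
    for a, b in zip(spectra, tiny_cohort.spectra):
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)
    for a, b in zip(patches, tiny_cohort.patches):
        assert np.array_equal(a.pixels, b.pixels)  # PNG is lossless
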