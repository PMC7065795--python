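"""Synthetic cohort, BMD-map and cross-section generator contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from osteomap import cohort
from osteomap.cohort import (
    CohortSpec,
    CohortSpecError,
    PANEL_VARIABLES,
    apply_effect_profile,
    generate_annulus_profile,
    generate_bmd_map,
    generate_cohort,
)


class TestGenerateCohort:
    def test_default_composition(self, study_cohort):
        before = study_cohort[study_cohort.timepoint == "before"]
        assert before.patient_id.nunique() == 40
        assert (before.sex == "F").sum() == 29
        assert (before.sex == "M").sum() == 11
        assert len(study_cohort) == 80
        assert set(PANEL_VARIABLES) <= set(study_cohort.columns)

    def test_empty_cohort(self):
        table = generate_cohort(CohortSpec(n_patients=0, n_female=0, n_male=0))
        assert table.empty

    def test_determinism(self):
        spec = CohortSpec(n_patients=12, n_female=8, n_male=4, seed=42)
        t1 = generate_cohort(spec)
        t2 = generate_cohort(CohortSpec(n_patients=12, n_female=8, n_male=4, seed=42))
        pd.testing.assert_frame_equal(t1, t2)

    def test_bmi_consistency_and_positivity(self, study_cohort):
        bmi = study_cohort.weight / study_cohort.height**2
        assert ((bmi > 10) & (bmi < 60)).all()
        for v in PANEL_VARIABLES:
            if v != "SHAFT_NECK_ANGLE":
                assert (study_cohort[v] >= 0).all(), v
        # SDI lands on the half-integer grid
        assert np.allclose(study_cohort.SDI * 2, np.round(study_cohort.SDI * 2))

    def test_non_psd_correlation_rejected(self):
        corr = np.array([[1.0, 2.0], [2.0, 1.0]])
        spec = CohortSpec(
            n_patients=4, n_female=2, n_male=2,
            variables=("BMD", "TBS"), correlation=corr,
        )
        with pytest.raises(CohortSpecError, match="positive semidefinite"):
            generate_cohort(spec)

    def test_negative_dispersion_rejected(self):
        spec = CohortSpec(n_patients=4, n_female=2, n_male=2)
        spec.baseline = dict(spec.baseline)
        spec.baseline["BMD"] = (0.7, -0.1)
        with pytest.raises(CohortSpecError, match="dispersion"):
            generate_cohort(spec)

    def test_sex_count_mismatch_rejected(self):
        with pytest.raises(CohortSpecError):
            generate_cohort(CohortSpec(n_patients=5, n_female=2, n_male=2))

    def test_baseline_moments_converge(self):
        spec = CohortSpec(n_patients=5000, n_female=3600, n_male=1400, seed=3)
        table = generate_cohort(spec)
        before = table[table.timepoint == "before"]
        for v in PANEL_VARIABLES:
            if v == "SDI":  # snapped to a grid and floored
                continue
            center, scale = spec.baseline[v]
            se = scale / math.sqrt(5000)
            assert abs(before[v].mean() - center) < 3 * se, v

    def test_correlated_pair_exceeds_independent_pair(self):
        hits = 0
        for seed in range(20):
            corr = np.eye(4)
            corr[0, 1] = corr[1, 0] = 0.8
            spec = CohortSpec(
                n_patients=1000, n_female=700, n_male=300,
                variables=("BMD", "TBS", "HAL", "FS_CSA"),
                correlation=corr, seed=seed,
            )
            b = generate_cohort(spec).query("timepoint == 'before'")
            r_high = np.corrcoef(b.BMD, b.TBS)[0, 1]
            r_zero = np.corrcoef(b.HAL, b.FS_CSA)[0, 1]
            hits += r_high > r_zero
        assert hits == 20


class TestApplyEffectProfile:
    def test_zero_effect_is_identity(self, study_cohort):
        before = study_cohort[study_cohort.timepoint == "before"]
        effect = {v: 0.0 for v in PANEL_VARIABLES}
        out = apply_effect_profile(before, effect, noise_sd=0.0)
        after = out[out.timepoint == "after"]
        np.testing.assert_array_equal(
            after[list(PANEL_VARIABLES)].to_numpy(),
            before[list(PANEL_VARIABLES)].to_numpy(),
        )

    def test_exact_ratio_without_noise(self, study_cohort):
        before = study_cohort[study_cohort.timepoint == "before"]
        effect = {v: 0.0 for v in PANEL_VARIABLES}
        effect["TBS"] = 5.08
        out = apply_effect_profile(before, effect, noise_sd=0.0)
        ratio = (
            out[out.timepoint == "after"].TBS.to_numpy()
            / out[out.timepoint == "before"].TBS.to_numpy()
        )
        np.testing.assert_allclose(ratio, 1.0508, rtol=1e-12)

    def test_monte_carlo_mean_ratio(self):
        spec = CohortSpec(n_patients=10000, n_female=7000, n_male=3000,
                          effect_noise_sd=0.0, seed=5)
        table = generate_cohort(spec)
        before = table[table.timepoint == "before"]
        effect = {v: 0.0 for v in PANEL_VARIABLES}
        effect["BSI"] = -13.9
        out = apply_effect_profile(before, effect, noise_sd=0.02, seed=5)
        ratio = (
            out[out.timepoint == "after"].BSI.to_numpy()
            / out[out.timepoint == "before"].BSI.to_numpy()
        )
        assert abs(ratio.mean() - 0.861) < 0.005

    def test_missing_variable_named(self, study_cohort):
        before = study_cohort[study_cohort.timepoint == "before"]
        effect = {v: 0.0 for v in PANEL_VARIABLES if v != "TBS"}
        with pytest.raises(KeyError, match="TBS"):
            apply_effect_profile(before, effect)

    def test_no_before_rows_rejected(self, study_cohort):
        after_only = study_cohort[study_cohort.timepoint == "after"]
        with pytest.raises(ValueError, match="before"):
            apply_effect_profile(after_only, {v: 0.0 for v in PANEL_VARIABLES})


class TestBMDMap:
    def test_noiseless_rect_is_constant(self):
        m = generate_bmd_map(20, 20, 0.745, noise_sd=0.0)
        assert (m.grid == 0.745).all()
        assert m.mask.all()
        assert abs(m.in_mask_mean - 0.745) < 1e-12

    def test_noisy_mean_close(self):
        m = generate_bmd_map(20, 20, 0.745, noise_sd=0.05, seed=2)
        assert abs(m.in_mask_mean - 0.745) < 3 * 0.05 / math.sqrt(400)

    def test_vertebra_mask_interior_and_contiguous(self):
        from scipy import ndimage

        m = generate_bmd_map(30, 40, 0.7, shape="vertebra", seed=0)
        assert not m.mask[0].any() and not m.mask[-1].any()
        assert not m.mask[:, 0].any() and not m.mask[:, -1].any()
        assert ndimage.label(m.mask)[1] == 1

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            generate_bmd_map(0, 5, 0.7)


class TestAnnulusProfile:
    def test_solid_disc_peak(self):
        p = generate_annulus_profile(1.5, 0.0, density=1.05, spacing=0.01)
        assert abs(p.areal_mass.max() - 2 * 1.05 * 1.5) < 1e-9
        assert p.areal_mass[np.abs(p.positions) >= 1.5].max() == 0.0

    def test_annulus_integral_matches_area(self):
        p = generate_annulus_profile(1.5, 1.2, density=1.05, spacing=0.01)
        integral = (p.areal_mass * p.spacing).sum()
        expected = 1.05 * math.pi * (1.5**2 - 1.2**2)
        assert abs(integral - expected) / expected < 0.005

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            generate_annulus_profile(1.5, 1.2, spacing=0.0)

    def test_bad_radii(self):
        with pytest.raises(ValueError):
            generate_annulus_profile(1.0, 1.2)


class TestCohortCSV:
    def test_round_trip(self, study_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cohort.write_cohort_csv(study_cohort, path)
        back = cohort.read_cohort_csv(path)
        assert list(back.columns) == list(study_cohort.columns)
        assert len(back) == len(study_cohort)
        # second write is byte-identical (fixed float format)
        path2 = tmp_path / "cohort2.csv"
        cohort.write_cohort_csv(back, path2)
        assert path.read_text() == path2.read_text()
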