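import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from captoped.errors import ConfigError, DomainError
from captoped.population import (
    PopulationSpec,
    Subject,
    compute_bsa,
    gfr_for_age,
    median_height_for_age,
    median_weight_for_age,
    sample_population,
    subject_from_row,
    subjects_to_frame,
)
from captoped.renal import STAGE_BANDS


class TestBSA:
    def test_haycock_reference_adult(self):
        # direct evaluation of 0.024265 * 70^0.5378 * 170^0.3964
        assert compute_bsa(70, 170) == pytest.approx(1.8256771, abs=1e-6)

    def test_dubois_flag(self):
        assert compute_bsa(70, 170, formula="dubois") == pytest.approx(1.8097078, abs=1e-6)

    def test_weight_power_law_scaling_is_exact(self):
        ratio = compute_bsa(140, 170) / compute_bsa(70, 170)
        assert ratio == pytest.approx(2**0.5378, rel=1e-12)

    @pytest.mark.parametrize("w,h,field", [(-1, 170, "weight"), (70, 0, "height")])
    def test_nonpositive_inputs_name_the_field(self, w, h, field):
        with pytest.raises(DomainError, match=field):
            compute_bsa(w, h)

    @settings(derandomize=True, max_examples=50)
    @given(
        w=st.floats(1, 150),
        h=st.floats(40, 210),
        dw=st.floats(0.1, 50),
        dh=st.floats(0.1, 50),
    )
    def test_monotone_in_both_arguments(self, w, h, dw, dh):
        base = compute_bsa(w, h)
        assert compute_bsa(w + dw, h) > base
        assert compute_bsa(w, h + dh) > base


class TestGrowthApproximations:
    def test_weight_is_increasing_and_plausible(self):
        ages = np.linspace(0, 25, 200)
        w = [median_weight_for_age(a) for a in ages]
        assert all(b >= a for a, b in zip(w, w[1:]))
        assert w[0] == pytest.approx(3.4)
        assert median_weight_for_age(1) == pytest.approx(10.0)
        assert max(w) == pytest.approx(70.0)

    def test_height_is_increasing(self):
        ages = np.linspace(0, 25, 200)
        h = [median_height_for_age(a) for a in ages]
        assert all(b >= a for a, b in zip(h, h[1:]))
        assert h[0] == pytest.approx(50.0)
        assert max(h) == pytest.approx(170.0)


class TestGFRMaturation:
    def test_birth_and_plateau(self):
        assert gfr_for_age(0.0) == pytest.approx(20.0)
        assert gfr_for_age(1.0) == pytest.approx(120.0)
        assert gfr_for_age(10.0) == pytest.approx(120.0)
        # linear in between
        assert gfr_for_age(0.5) == pytest.approx(70.0)

    def test_plateau_for_all_ages_above_one(self):
        for age in np.linspace(1.0, 60.0, 25):
            assert gfr_for_age(age) == 120.0

    def test_ckd_stage_draws_inside_band(self):
        rng = np.random.default_rng(3)
        lo, hi = STAGE_BANDS["severe"]
        for _ in range(50):
            g = gfr_for_age(10.0, "severe", rng)
            assert lo <= g < hi

    def test_negative_age_rejected(self):
        with pytest.raises(DomainError):
            gfr_for_age(-0.1)


class TestSubjectInvariants:
    def test_inconsistent_bsa_rejected(self):
        with pytest.raises(DomainError, match="bsa"):
            Subject(
                id="X", age=5, sex="M", weight=18, height=109, bsa=1.5,
                gfr=120, ckd_stage="healthy",
            )

    def test_inconsistent_stage_rejected(self):
        with pytest.raises(DomainError, match="ckd_stage"):
            Subject(
                id="X", age=5, sex="M", weight=18, height=109,
                bsa=compute_bsa(18, 109), gfr=120, ckd_stage="severe",
            )


class TestSamplePopulation:
    def test_seeded_determinism_bitwise(self):
        spec = PopulationSpec(n=7, seed=7)
        a = subjects_to_frame(sample_population(spec)).to_csv()
        b = subjects_to_frame(sample_population(spec)).to_csv()
        assert a == b

    def test_reference_subject_fixes_demographics(self):
        ref, _ = subject_from_row(
            {"id": "RF1", "age_years": 5.5, "sex": "M", "serum_creatinine_mg_dl": 0.61,
             "gfr": 61.0}
        )
        cohort = sample_population(
            PopulationSpec(n=100, ckd_stage="mild", reference_subject=ref, seed=1)
        )
        assert len(cohort) == 100
        assert all(s.age == 5.5 and s.sex == "M" and s.weight == ref.weight for s in cohort)
        # physiology is resampled, not copied
        assert len({round(s.gfr, 6) for s in cohort}) > 50

    def test_sex_ratio_within_binomial_bounds(self):
        cohort = sample_population(PopulationSpec(n=1000, sex_ratio=0.5, seed=3))
        males = sum(s.sex == "M" for s in cohort)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= males <= hi

    @pytest.mark.parametrize("stage", ["mild", "moderate", "severe", "esrd"])
    def test_stage_containment(self, stage):
        cohort = sample_population(PopulationSpec(n=40, ckd_stage=stage, seed=11))
        lo, hi = STAGE_BANDS[stage]
        for s in cohort:
            assert lo <= s.gfr < hi
            assert s.ckd_stage == stage

    def test_invalid_spec_is_config_error(self):
        with pytest.raises(ConfigError):
            PopulationSpec(n=0)
        with pytest.raises(ConfigError):
            PopulationSpec(n=1, sex_ratio=1.5)


class TestDemographicsIO:
    def test_missing_height_imputed_and_logged(self, tmp_path):
        csv = tmp_path / "demo.csv"
        csv.write_text(
            "id,age_years,sex,weight_kg,serum_creatinine_mg_dl\n"
            "P1,7,M,29.7,0.34\n"
        )
        from captoped.population import read_demographics_csv

        subjects, log = read_demographics_csv(csv)
        (s,) = subjects
        assert "height" in s.imputed
        assert s.height == pytest.approx(median_height_for_age(7))
        assert any("height imputed" in line for line in log)
        # BSA for the 29.7-kg 7-year-old follows from the imputed height
        assert s.bsa == pytest.approx(compute_bsa(29.7, s.height))
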