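import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from captoped.errors import AlignmentError, DomainError, InsufficientDataError
from captoped.evaluate import (
    afe,
    evaluate_parameters,
    fold_error,
    mean_ratio_ci,
    pi_coverage,
    population_summary,
    twofold_check,
)
from captoped.pbpk import ConcentrationProfile

ratios_pos = st.lists(st.floats(0.05, 20), min_size=1, max_size=12)


def profile(times, concs, sid="P"):
    return ConcentrationProfile(sid, tuple(times), tuple(concs), 10.0)


class TestFoldError:
    @pytest.mark.parametrize(
        "obs,pred,expected",
        [(221.90, 523.00, 2.36), (371, 636.97, 1.72), (5.0, 5.0, 1.0)],
    )
    def test_reference_ratios(self, obs, pred, expected):
        assert round(fold_error(obs, pred), 2) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.01, 1e4), b=st.floats(0.01, 1e4))
    def test_reciprocal_identity(self, a, b):
        assert fold_error(a, b) * fold_error(b, a) == pytest.approx(1.0, rel=1e-12)

    def test_domain(self):
        with pytest.raises(DomainError):
            fold_error(0, 1)


class TestAFE:
    def test_reciprocal_pair_and_singleton(self):
        assert afe([2.0, 0.5]) == pytest.approx(1.0)
        assert afe([1.7]) == pytest.approx(1.7)

    @settings(derandomize=True, max_examples=50)
    @given(r=ratios_pos)
    def test_geometric_mean_reciprocal_identity(self, r):
        assert afe(r) * afe([1 / x for x in r]) == pytest.approx(1.0, rel=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(r=st.lists(st.floats(0.1, 10), min_size=2, max_size=8))
    def test_permutation_invariance(self, r):
        assert afe(r) == pytest.approx(afe(list(reversed(r))), rel=1e-12)

    def test_log_additivity_under_concatenation(self):
        a, b = [0.5, 2.0, 1.3], [0.8, 1.1, 0.9]
        combined = afe(a + b)
        assert combined == pytest.approx(np.sqrt(afe(a) * afe(b)))

    def test_domain(self):
        with pytest.raises(DomainError):
            afe([])
        with pytest.raises(DomainError):
            afe([1.0, -1.0])


class TestMeanRatioCI:
    def test_zero_variance(self):
        mean, (lo, hi) = mean_ratio_ci([1, 1, 1, 1])
        assert (mean, lo, hi) == (1.0, 1.0, 1.0)

    def test_symmetric_about_mean(self):
        mean, (lo, hi) = mean_ratio_ci([0.5, 1.5])
        assert mean == pytest.approx(1.0)
        assert hi - mean == pytest.approx(mean - lo)

    def test_needs_two(self):
        with pytest.raises(InsufficientDataError):
            mean_ratio_ci([1.0])

    def test_log_scale_returns_geometric_mean(self):
        mean, _ = mean_ratio_ci([0.25, 4.0], log_scale=True)
        assert mean == pytest.approx(1.0)


class TestTwofold:
    def test_inclusive_bounds(self):
        flags, frac = twofold_check([0.5, 2.0])
        assert flags.all() and frac == 1.0

    def test_wider_band_admits_more(self):
        flags, _ = twofold_check([2.36], hi=2.4)
        assert flags.all()
        flags, _ = twofold_check([2.36])
        assert not flags.any()

    def test_coverage_monotone_in_band_width(self):
        r = [0.3, 0.6, 1.0, 1.9, 2.2, 3.5]
        fracs = [twofold_check(r, 1 / w, w)[1] for w in (1.5, 2.0, 2.4, 4.0)]
        assert fracs == sorted(fracs)


class TestPopulationSummary:
    def test_identical_profiles_collapse(self):
        p = profile([0, 1, 2], [0, 10, 5])
        s = population_summary([p, p, p])
        assert s.mean == s.minimum == s.maximum == s.p5 == s.p95

    def test_two_profile_percentile_rule(self):
        lo = profile([0, 1], [0, 10], "a")
        hi = profile([0, 1], [0, 20], "b")
        s = population_summary([lo, hi])
        # linear interpolation between order statistics: p5 is 5% up the gap
        assert s.p5[1] == pytest.approx(10 + 0.05 * 10)
        assert s.p95[1] == pytest.approx(10 + 0.95 * 10)
        assert s.minimum[1] == 10 and s.maximum[1] == 20

    def test_mismatched_grids_rejected(self):
        with pytest.raises(AlignmentError):
            population_summary([profile([0, 1], [1, 1]), profile([0, 2], [1, 1])])

    def test_seeded_simulations_reproducible(self, child, params):
        from captoped.pbpk import DoseRegimen, simulate_profile
        from captoped.population import PopulationSpec, sample_population
        from captoped.renal import apply_ckd

        def build():
            cohort = sample_population(PopulationSpec(n=10, ckd_stage="healthy", seed=4))
            rng = np.random.default_rng(9)
            cohort = [apply_ckd(s, "mild", rng=rng) for s in cohort]
            reg = DoseRegimen(amount_mg=20, sampling_times=(0.0, 0.5, 1.0, 2.0, 4.0))
            return population_summary([simulate_profile(s, params, reg) for s in cohort])

        assert build() == build()


class TestPICoverage:
    def test_median_observations_fully_covered(self):
        sims = [profile([0, 1, 2], [0, c, c / 2], str(c)) for c in (8, 10, 12)]
        s = population_summary(sims)
        obs = profile([0, 1, 2], [0, 10, 5], "obs")
        assert pi_coverage(obs, s) == 1.0

    def test_outlier_observations_zero(self):
        sims = [profile([0, 1], [0, c]) for c in (8, 10, 12)]
        s = population_summary(sims)
        obs = profile([0, 1], [100, 100], "obs")
        assert pi_coverage(obs, s) == 0.0

    def test_empty_observations_rejected(self):
        sims = [profile([0, 1], [0, c]) for c in (8, 12)]
        s = population_summary(sims)
        with pytest.raises(DomainError):
            pi_coverage(ConcentrationProfile("e", (), (), 1.0), s)


class TestEvaluateParameters:
    def test_report_aggregates(self):
        records = [("AUC", 100, 200), ("AUC", 100, 50)]
        report = evaluate_parameters(records)
        assert report.n == 2
        assert report.mean_ratio == pytest.approx((2.0 + 0.5) / 2)
        assert report.afe == pytest.approx(1.0)
        assert report.frac_within_twofold == 1.0
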