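import dataclasses

import numpy as np
import pytest

from captoped import nca
from captoped.errors import ConfigError, DomainError
from captoped.pbpk import (
    CAPTOPRIL,
    CompoundParams,
    ConcentrationProfile,
    DoseRegimen,
    scale_clearances,
    simulate_profile,
    simulate_to_steady_state,
)


class TestCompoundParams:
    def test_clearance_additivity_enforced(self):
        with pytest.raises(DomainError, match="cl_iv_adult"):
            CompoundParams(cl_iv_adult=50.0)  # 22.2 + 27.3 != 50

    def test_adult_reference_values(self):
        assert CAPTOPRIL.cl_renal_adult + CAPTOPRIL.cl_additional_adult == pytest.approx(
            CAPTOPRIL.cl_iv_adult
        )


class TestDoseRegimen:
    def test_exactly_one_dose_field(self):
        with pytest.raises(ConfigError):
            DoseRegimen(amount_mg=10, amount_mg_per_kg=1)
        with pytest.raises(ConfigError):
            DoseRegimen()

    def test_multiple_doses_need_interval(self):
        with pytest.raises(ConfigError):
            DoseRegimen(amount_mg=10, n_doses=3)

    def test_sampling_times_must_increase(self):
        with pytest.raises(ConfigError):
            DoseRegimen(amount_mg=10, sampling_times=(0.0, 1.0, 1.0))

    def test_per_kg_resolution(self):
        assert DoseRegimen(amount_mg_per_kg=1.6).resolve_dose_mg(30.0) == pytest.approx(48.0)


class TestScaleClearances:
    def test_adult_healthy_reference(self, adult, params):
        cl_r, cl_nr = scale_clearances(adult, params)
        assert cl_r == pytest.approx(22.2)
        assert cl_nr == pytest.approx(27.3)
        assert cl_r + cl_nr == pytest.approx(49.5)

    def test_severe_adult_with_low_gfr(self, adult, params, staged_child):
        from captoped.renal import DEFAULT_OVERLAYS

        severe_adult = dataclasses.replace(
            adult, gfr=20.0, ckd_stage="severe", overlay=DEFAULT_OVERLAYS["severe"]
        )
        cl_r, cl_nr = scale_clearances(severe_adult, params)
        assert cl_nr == pytest.approx(27.3 * 0.6)  # 16.38
        assert cl_r == pytest.approx(22.2 * 20 / 120)  # 3.70

    def test_child_allometry(self, params):
        from captoped.population import Subject, compute_bsa
        from captoped.renal import DEFAULT_OVERLAYS

        c = Subject(
            id="C27", age=8.0, sex="M", weight=27.0, height=128.0,
            bsa=compute_bsa(27.0, 128.0), gfr=120.0, ckd_stage="healthy",
            overlay=DEFAULT_OVERLAYS["healthy"],
        )
        _, cl_nr = scale_clearances(c, params)
        assert cl_nr == pytest.approx(27.3 * (27 / 70) ** 0.75, rel=1e-12)
        assert cl_nr == pytest.approx(13.36, abs=0.01)

    def test_per_kg_nonrenal_cl_decreases_with_weight(self, params):
        from captoped.population import Subject, compute_bsa
        from captoped.renal import DEFAULT_OVERLAYS

        per_kg = []
        for w in (10.0, 20.0, 40.0, 70.0):
            s = Subject(
                id=f"W{w}", age=10.0, sex="M", weight=w, height=140.0,
                bsa=compute_bsa(w, 140.0), gfr=120.0, ckd_stage="healthy",
                overlay=DEFAULT_OVERLAYS["healthy"],
            )
            _, cl_nr = scale_clearances(s, params)
            per_kg.append(cl_nr / w)
        assert per_kg == sorted(per_kg, reverse=True)


class TestSimulateProfile:
    def test_zero_dose_gives_zero_concentrations(self, adult, params):
        reg = DoseRegimen(amount_mg=0.0, sampling_times=(0.0, 1.0, 2.0))
        p = simulate_profile(adult, params, reg)
        assert all(c == 0 for c in p.concentrations)

    def test_dose_linearity_of_auc(self, adult, params):
        times = tuple(np.round(np.arange(0.0, 12.01, 0.25), 4))
        auc = {}
        for d in (10.0, 20.0):
            p = simulate_profile(adult, params, DoseRegimen(amount_mg=d, sampling_times=times))
            auc[d] = nca.auc_trapezoid(p)
        assert auc[20.0] / auc[10.0] == pytest.approx(2.0, abs=1e-6)

    def test_oral_clearance_identity(self, adult, params, dense_regimen):
        # for a linear model with complete AUC, CL/F = CL_iv / fa
        p = simulate_profile(adult, params, dense_regimen)
        res = nca.nca(p, use_auc_inf=True)
        assert res.cl_f == pytest.approx(49.5 / params.fa, rel=0.02)

    def test_mass_balance(self, adult, params):
        # amount eliminated = CL * AUC_0-inf -> fa * dose within 0.5%
        times = tuple(np.round(np.arange(0.0, 48.01, 0.1), 4))
        dose = 25.0
        p = simulate_profile(adult, params, DoseRegimen(amount_mg=dose, sampling_times=times))
        res = nca.nca(p, use_auc_inf=True)
        cl_total = sum(scale_clearances(adult, params))
        eliminated_mg = cl_total * res.auc_0_inf / 1e3  # ng*h/ml (= ug*h/L) * L/h -> ug -> mg
        assert eliminated_mg == pytest.approx(params.fa * dose, rel=0.005)

    def test_lsoda_cross_check(self, adult, params):
        times = tuple(np.round(np.arange(0.0, 12.01, 0.5), 4))
        reg = DoseRegimen(amount_mg=25.0, sampling_times=times)
        a = simulate_profile(adult, params, reg).c
        b = simulate_profile(adult, params, reg, integrator="lsoda").c
        assert np.allclose(a, b, rtol=1e-5, atol=1e-3)

    def test_profile_invariants(self, adult, params, dense_regimen):
        p = simulate_profile(adult, params, dense_regimen)
        assert np.all(p.c >= 0) and np.all(np.isfinite(p.c))
        with pytest.raises(DomainError):
            ConcentrationProfile("x", (0.0, 1.0), (1.0, -2.0), 10.0)


class TestSteadyState:
    def test_accumulation_matches_one_compartment_closed_form(self, child):
        # one-compartment limit: trough ratio = 1 / (1 - exp(-k tau))
        params = dataclasses.replace(CAPTOPRIL, central_fraction=1.0, ka=50.0)
        tau = 2.0
        k = 49.5 * (30 / 70) ** 0.75 / (0.8 * 30)  # CL / V
        reg = DoseRegimen(amount_mg=10.0, interval_h=tau, sampling_times=(0.0, 1.0, 1.999))
        single = simulate_profile(child, params, reg)
        ss = simulate_to_steady_state(child, params, reg, auc_rtol=1e-6)
        ratio = ss.c[-1] / single.c[-1]
        assert ratio == pytest.approx(1.0 / (1.0 - np.exp(-k * tau)), rel=0.005)

    def test_long_interval_reduces_to_single_dose(self, child, params):
        # interval >> terminal half-life: interval AUC == single-dose AUC_0-inf
        tau = 72.0
        times = tuple(np.round(np.arange(0.0, tau + 0.01, 0.25), 4))
        reg = DoseRegimen(amount_mg=20.0, interval_h=tau, sampling_times=times)
        ss = simulate_to_steady_state(child, params, reg)
        single = simulate_profile(child, params, DoseRegimen(amount_mg=20.0, sampling_times=times))
        auc_ss = nca.auc_trapezoid(ss)
        auc_inf = nca.nca(single, use_auc_inf=True).auc_0_inf
        assert auc_ss == pytest.approx(auc_inf, rel=0.01)
        assert ss.is_steady_state

    def test_ckd_increases_steady_state_exposure(self, staged_child, params):
        reg = DoseRegimen(
            amount_mg_per_kg=1.6, interval_h=8.0,
            sampling_times=tuple(np.round(np.arange(0.0, 8.01, 0.25), 4)),
        )
        auc = {
            stage: nca.auc_trapezoid(simulate_to_steady_state(staged_child(stage), params, reg))
            for stage in ("healthy", "mild", "severe")
        }
        assert auc["healthy"] < auc["mild"] < auc["severe"]

    def test_requires_interval(self, child, params):
        with pytest.raises(ConfigError):
            simulate_to_steady_state(
                child, params, DoseRegimen(amount_mg=10.0, sampling_times=(0.0, 1.0))
            )
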