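"""Polynomial temperature laws and joint/constrained fits."""

import numpy as np
import pytest

from txinit import (
    InitiationModel,
    ObservationDesign,
    RNAPProfile,
    TemperatureLaw,
    bic,
    eval_rate,
    fit_joint_temperature,
    fit_model,
    fit_rnap_constrained,
    fit_shared_shape,
    select_temperature_model,
)
from txinit.inference import ModelStructure, censored_loglik
from txinit.simulate import ConditionMeta, simulate_condition
from txinit.temperature import InvalidLawError, default_order_lattice

ST1 = ModelStructure(1, True)


def quad_coeffs(points):
    ts, vs = zip(*points)
    return tuple(np.polyfit(ts, vs, 2))


def study_law(k1_pts, kon_inv=200.0, koff_inv=200.0):
    return TemperatureLaw({
        "k1": (2, quad_coeffs(k1_pts)),
        "k_on": (0, (0, 0, kon_inv)),
        "k_off": (0, (0, 0, koff_inv)),
    })


def simulate_by_T(law, temps, n_cells, seed):
    rng = np.random.default_rng(seed)
    design = ObservationDesign(n_cells=n_cells)
    return {
        T: simulate_condition(law.model_at(T), design,
                              ConditionMeta(f"T{T}", temperature_C=T), rng)
        for T in temps
    }


class TestEvalRate:
    def test_constant_order(self):
        law = TemperatureLaw({"k1": (0, (0, 0, 500.0))})
        assert eval_rate(law, "k1", 24.0) == pytest.approx(0.002)
        assert eval_rate(law, "k1", 41.0) == pytest.approx(0.002)

    def test_linear_order(self):
        law = TemperatureLaw({"k1": (1, (0, -100.0, 4000.0))})
        assert 1 / eval_rate(law, "k1", 30.0) == pytest.approx(1000.0)

    def test_convexity_of_quadratic(self):
        law = TemperatureLaw({"k1": (2, (2.0, -100.0, 2000.0))})
        lo, mid, hi = (1 / eval_rate(law, "k1", T) for T in (24, 32.5, 41))
        assert mid <= (lo + hi) / 2

    def test_nonpositive_inverse_rate_rejected(self):
        law = TemperatureLaw({"k1": (1, (0, -100.0, 1000.0))})
        with pytest.raises(InvalidLawError):
            eval_rate(law, "k1", 30.0)


class TestJointTemperatureFit:
    def test_constant_spec_equals_pooled_likelihood(self):
        law = study_law([(24, 2000), (32.5, 2000), (41, 2000)])
        by_T = simulate_by_T(law, [24, 37], 150, seed=0)
        pooled = __import__("pandas").concat(by_T.values(), ignore_index=True)
        fit_pooled = fit_model(pooled, ST1, n_starts=4, seed=1)
        fit_joint = fit_joint_temperature(by_T, ST1, {}, n_starts=4, seed=1)
        # tying with all-constant laws is mathematically the pooled likelihood
        spec = fit_joint.extra["spec"]
        ll_at_pooled_params = sum(
            censored_loglik(spec.model_at(fit_pooled.estimates, T), recs)
            for T, recs in by_T.items()
        )
        assert ll_at_pooled_params == pytest.approx(fit_pooled.loglik, abs=1e-8)
        assert fit_joint.loglik == pytest.approx(fit_pooled.loglik, abs=1e-3)

    def test_two_temperature_linear_law_interpolates_per_T_optima(self, rng):
        # with one step and no switching, a 2-anchor linear law is saturated:
        # the joint fit reproduces the per-temperature ML rates
        law = TemperatureLaw({"k1": (1, (0.0, -40.0, 2000.0))})
        design = ObservationDesign(n_cells=250)
        by_T = {
            T: simulate_condition(law.model_at(T), design,
                                  ConditionMeta(f"T{T}", temperature_C=T), rng)
            for T in (25.0, 40.0)
        }
        st = ModelStructure(1, False)
        joint = fit_joint_temperature(by_T, st, {"k1": 1}, n_starts=4, seed=0)
        jlaw = joint.extra["law"]
        for T, recs in by_T.items():
            per = fit_model(recs, st, n_starts=3, seed=int(T))
            assert jlaw.rate("k1", T) == pytest.approx(
                float(np.exp(per.estimates[0])), rel=1e-3)

    def test_quadratic_k1_recovery_within_10pct(self):
        pts = [(24, 2590), (32.5, 1580), (41, 2200)]
        law = study_law(pts)
        temps = [24, 27.4, 30.8, 34.2, 37.6, 41]
        by_T = simulate_by_T(law, temps, 1200, seed=1)
        fit = fit_joint_temperature(by_T, ST1, {"k1": 2}, n_starts=4, seed=0)
        flaw = fit.extra["law"]
        for T in temps:
            assert flaw.inverse_rate("k1", T) == pytest.approx(
                law.inverse_rate("k1", T), rel=0.10)

    def test_single_temperature_nonconstant_rejected(self):
        law = study_law([(24, 2000), (32.5, 2000), (41, 2000)])
        by_T = simulate_by_T(law, [37], 30, seed=2)
        with pytest.raises(ValueError):
            fit_joint_temperature(by_T, ST1, {"k1": 2}, n_starts=2, seed=0)


class TestTemperatureModelSelection:
    def test_k1_quadratic_data_selects_k1(self):
        # bursty switching as in the study: the shape signature of the fast
        # within-burst component separates k1 changes from k_on changes
        law = study_law([(24, 235), (32.5, 145), (41, 200)],
                        kon_inv=500.0, koff_inv=50.0)
        temps = [24, 27.4, 30.8, 34.2, 37.6, 41]
        by_T = simulate_by_T(law, temps, 700, seed=3)
        comp = select_temperature_model(by_T, ST1, n_starts=3, seed=0)
        assert "k1:2" in comp.best_fit.model_spec or "k1:1" in comp.best_fit.model_spec

    def test_null_data_selects_all_constant(self):
        law = study_law([(24, 1500), (32.5, 1500), (41, 1500)])
        by_T = simulate_by_T(law, [24, 30, 35, 41], 500, seed=4)
        comp = select_temperature_model(by_T, ST1, n_starts=3, seed=0)
        assert "k_on:0+k_off:0+k1:0" in comp.best_fit.model_spec
        assert comp.delta_bic_second_best >= 0

    def test_lattice_shapes(self):
        assert len(default_order_lattice(ST1)) == 1 + 2 * 3
        assert len(default_order_lattice(ST1, full=True)) == 3**3
        with pytest.raises(ValueError):
            select_temperature_model({}, ST1, lattice=[])


class TestSharedShape:
    def test_scale_recovery(self):
        pts = [(24, 2590), (32.5, 1580), (41, 2200)]
        A, B, C = quad_coeffs(pts)
        scales = {"Full": 1.0, "IPTG": 2.5, "Ara": 0.8}
        cells = {"Full": 900, "IPTG": 2600, "Ara": 750}
        rng = np.random.default_rng(4)
        by_scheme = {}
        for s, c in scales.items():
            law = TemperatureLaw({"k1": (2, (c * A, c * B, c * C)),
                                  "k_on": (0, (0, 0, 200.0)),
                                  "k_off": (0, (0, 0, 200.0))})
            design = ObservationDesign(n_cells=cells[s])
            by_scheme[s] = {
                T: simulate_condition(law.model_at(T), design,
                                      ConditionMeta(f"{s}{T}", temperature_C=T), rng)
                for T in (24, 30, 35, 41)
            }
        fit = fit_shared_shape(by_scheme, ST1, n_starts=4, seed=0,
                               reference_scheme="Full")
        assert fit.converged
        est = fit.extra["scales"]
        assert est["Full"] == 1.0
        assert est["IPTG"] == pytest.approx(2.5, rel=0.15)
        assert est["Ara"] == pytest.approx(0.8, rel=0.15)
        # constrained shared shape beats unconstrained per-scheme quadratics
        ll_unc, p_unc = 0.0, 0
        for s in scales:
            f = fit_joint_temperature(by_scheme[s], ST1, {"k1": 2}, n_starts=3, seed=5)
            ll_unc += f.loglik
            p_unc += f.n_params
        n_eff = fit.n_exact + 0.5 * fit.n_censored
        bic_shared = -2 * fit.loglik + fit.n_params * np.log(n_eff)
        bic_unc = -2 * ll_unc + p_unc * np.log(n_eff)
        assert bic_shared < bic_unc

    def test_single_scheme_rejected(self):
        with pytest.raises(ValueError):
            fit_shared_shape({"Full": {}}, ST1)


class TestRnapConstrained:
    PROFILE = RNAPProfile((24.0, 37.0, 41.0), (0.415, 1.0, 0.562))

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            RNAPProfile((24.0,), (0.5,))  # no reference with R = 1
        with pytest.raises(ValueError):
            self.PROFILE.abundance(20.0)  # extrapolation refused
        assert self.PROFILE.abundance(30.5) == pytest.approx(
            0.415 + (1.0 - 0.415) * (30.5 - 24) / 13)

    def test_k1_tilde_recovery(self):
        k1t = 1 / 1800.0
        rng = np.random.default_rng(5)
        design = ObservationDesign(n_cells=800)
        by_T = {
            T: simulate_condition(
                InitiationModel((k1t * self.PROFILE.abundance(T),),
                                k_on=1 / 200, k_off=1 / 200),
                design, ConditionMeta(f"T{T}", temperature_C=T), rng)
            for T in (24.0, 37.0, 41.0)
        }
        fit = fit_rnap_constrained(by_T, self.PROFILE, ST1, n_starts=4, seed=0)
        se = fit.standard_errors()[0]
        assert abs(fit.estimates[0] - np.log(k1t)) < 3 * se

    def test_constant_profile_reduces_to_constant_k1(self):
        profile = RNAPProfile((24.0, 41.0), (1.0, 1.0))
        law = study_law([(24, 1500), (32.5, 1500), (41, 1500)])
        by_T = simulate_by_T(law, [24, 41], 200, seed=6)
        con = fit_rnap_constrained(by_T, profile, ST1, n_starts=4, seed=1)
        const = fit_joint_temperature(by_T, ST1, {}, n_starts=4, seed=1)
        assert con.loglik == pytest.approx(const.loglik, abs=1e-2)

    def test_free_quadratic_beats_constrained_on_nonproportional_data(self):
        law = study_law([(24, 2590), (32.5, 1580), (41, 2200)])
        by_T = simulate_by_T(law, [24.0, 37.0, 41.0], 700, seed=7)
        con = fit_rnap_constrained(by_T, self.PROFILE, ST1, n_starts=4, seed=2)
        free = fit_joint_temperature(by_T, ST1, {"k1": 2}, n_starts=4, seed=2)
        assert bic(free) < bic(con)
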