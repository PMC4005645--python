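"""ITC forward model, least-squares fitting and the slow-exchange estimator."""

import math

import numpy as np
import pytest

from rsmbind import (
    BindingParameters,
    ItcExperiment,
    ItcModel,
    NmrIntegralPair,
    SlowExchangeError,
    bound_fraction_forward,
    fit_itc,
    free_ligand,
    itc_isotherm,
    kd_from_integrals,
)
from rsmbind.thermo import _complex_concentrations, _enthalpy_content

ONE_SITE = BindingParameters("one_site", kd1=1e-6, dh1=-50e3)


def bisect_free_ligand(l_tot, p_tot, params, iters=200):
    """Independent bisection oracle on the mass-balance residual."""

    def bound(l):
        if params.model == "one_site":
            return p_tot * l / (params.kd1 + l)
        a1 = l / params.kd1
        a2 = a1 * l / params.kd2
        return p_tot * (a1 + 2 * a2) / (1 + a1 + a2)

    lo, hi = 0.0, l_tot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid + bound(mid) < l_tot:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestFreeLigand:
    def test_no_protein_all_free(self):
        assert free_ligand(1e-6, 0.0, ONE_SITE) == 1e-6

    def test_no_binding_limit(self):
        weak = BindingParameters("one_site", kd1=1e6, dh1=-50e3)
        assert free_ligand(1e-6, 1e-5, weak) == pytest.approx(1e-6, rel=1e-9)

    def test_golden_quadratic_root(self):
        # kd = p_tot = l_tot = 1 uM: l_free = (sqrt(5)-1)/2 uM
        l = free_ligand(1e-6, 1e-6, ONE_SITE)
        assert l == pytest.approx((math.sqrt(5) - 1) / 2 * 1e-6, rel=1e-9)

    @pytest.mark.parametrize(
        "params,l_tot,p_tot",
        [
            (ONE_SITE, 5e-6, 2e-6),
            (BindingParameters("two_site", kd1=1e-8, kd2=2e-7, dh1=-6e4, dh2=-4e4), 2e-5, 8e-6),
            (BindingParameters("two_site", kd1=1e-6, kd2=1e-4, dh1=-6e4, dh2=-4e4), 1e-6, 1e-5),
        ],
    )
    def test_agrees_with_bisection_oracle(self, params, l_tot, p_tot):
        assert free_ligand(l_tot, p_tot, params) == pytest.approx(
            bisect_free_ligand(l_tot, p_tot, params), rel=1e-10, abs=1e-18
        )

    def test_mass_balance_residual_tiny(self):
        params = BindingParameters("two_site", kd1=16e-9, kd2=185e-9, dh1=-6e4, dh2=-4e4)
        l_tot, p_tot = 1.3e-5, 8e-6
        l = free_ligand(l_tot, p_tot, params)
        pl, pl2 = _complex_concentrations(l, p_tot, params)
        assert abs(l + pl + 2 * pl2 - l_tot) / l_tot < 1e-12


def design(n=30, v=8e-6, cell=1e-5, syr=2e-4, heats=None):
    return ItcExperiment(
        cell_conc=cell,
        syringe_conc=syr,
        injection_volumes=[v] * n,
        heats=heats,
    )


class TestItcIsotherm:
    def test_zero_enthalpy_gives_dilution_heat_only(self):
        params = BindingParameters("one_site", kd1=1e-7, dh1=0.0, q_dil=-2e-6)
        heats = itc_isotherm(params, design())
        assert np.allclose(heats, -2e-6)

    def test_saturating_titration_asymptote(self):
        params = BindingParameters("one_site", kd1=1e-9, dh1=-50e3, q_dil=-1e-7)
        heats = itc_isotherm(params, design(n=40))
        assert abs(heats[-1] - params.q_dil) < 1e-2 * abs(heats[0] - params.q_dil)

    def test_first_injection_matches_brute_force_equilibrium_oracle(self):
        # same post-injection totals, but equilibrium found by long bisection
        # on the mass balance instead of the solver under test
        params = BindingParameters("one_site", kd1=1e-7, dh1=-50e3)
        exp = design(n=1)
        v0, v = exp.cell_volume, exp.injection_volumes[0]
        q_model = itc_isotherm(params, exp)[0]
        d = v0 / (v0 + v)
        p_tot = exp.cell_conc * d
        l_tot = exp.syringe_conc * (1 - d)
        l_free = bisect_free_ligand(l_tot, p_tot, params)
        pl = p_tot * l_free / (params.kd1 + l_free)
        assert q_model == pytest.approx(v0 * pl * params.dh1, rel=1e-3)

    def test_heat_is_path_independent_under_micro_mixing(self):
        # 10^4-step incremental mixing: the complex enthalpy is a state
        # function, so the fine-grained path agrees with the one-step model
        # up to the dilution-ladder discretisation bound ~v/(2 V0) (~0.3%)
        params = BindingParameters("one_site", kd1=1e-7, dh1=-50e3)
        exp = design(n=1)
        v0, v = exp.cell_volume, exp.injection_volumes[0]
        q_model = itc_isotherm(params, exp)[0]
        steps = 10_000
        p_tot, l_tot = exp.cell_conc, 0.0
        h_prev, q_total = 0.0, 0.0
        for _ in range(steps):
            d = v0 / (v0 + v / steps)
            p_tot *= d
            l_tot = l_tot * d + exp.syringe_conc * (1 - d)
            h_now = _enthalpy_content(l_tot, p_tot, params)
            q_total += v0 * (h_now - h_prev)  # pure state difference
            h_prev = h_now
        assert q_model == pytest.approx(q_total, rel=v / (2 * v0) + 1e-4)

    def test_heat_conservation_bookkeeping(self):
        # sum of (q_i - q_dil) equals final complex enthalpy content plus the
        # enthalpy displaced by the perfusion dilution, tracked independently
        params = BindingParameters(
            "two_site", kd1=1e-8, kd2=3e-7, dh1=-6e4, dh2=-4e4, q_dil=-5e-7
        )
        exp = design(n=25)
        heats = itc_isotherm(params, exp)
        v0 = exp.cell_volume
        p_tot, l_tot = exp.cell_conc, 0.0
        h_states = []
        for v in exp.injection_volumes:
            d = v0 / (v0 + v)
            p_tot *= d
            l_tot = l_tot * d + exp.syringe_conc * (1 - d)
            h_states.append(_enthalpy_content(l_tot, p_tot, params))
        displaced = sum(
            h_states[i] * (1 - v0 / (v0 + exp.injection_volumes[i + 1]))
            for i in range(len(h_states) - 1)
        )
        expected = v0 * (h_states[-1] + displaced)
        total = float(np.sum(heats - params.q_dil))
        assert total == pytest.approx(expected, rel=1e-9)

    def test_two_site_collapses_to_one_site_when_kd2_huge(self):
        # kd2 >= 1e4 * kd1 and titration kept below one-site saturation
        one = BindingParameters("one_site", kd1=5e-8, dh1=-55e3)
        two = BindingParameters("two_site", kd1=5e-8, kd2=5e-4, dh1=-55e3, dh2=-40e3)
        exp = design(n=12, v=4e-6, cell=1e-5, syr=1e-4)  # ends ~0.34 eq per dimer
        h1 = itc_isotherm(one, exp)
        h2 = itc_isotherm(two, exp)
        assert np.all(np.abs(h2 - h1) <= 5e-3 * np.abs(h1))


class TestFitItc:
    def test_noise_free_one_site_recovery(self):
        truth = BindingParameters("one_site", kd1=2e-7, dh1=-48e3, q_dil=-3e-7)
        exp = design(n=30)
        exp.heats = itc_isotherm(truth, exp)
        res = fit_itc(exp, model="one_site")
        assert res.converged
        assert res.params.kd1 == pytest.approx(truth.kd1, rel=1e-3)
        assert res.params.dh1 == pytest.approx(truth.dh1, rel=1e-3)
        assert res.params.q_dil == pytest.approx(truth.q_dil, abs=1e-9)

    def test_noise_free_two_site_recovery(self):
        truth = BindingParameters(
            "two_site", kd1=16e-9, kd2=185e-9, dh1=-60e3, dh2=-45e3, q_dil=-2e-7
        )
        exp = design(n=35, cell=1e-5, syr=3e-4)
        exp.heats = itc_isotherm(truth, exp)
        res = fit_itc(exp, model="two_site")
        assert res.converged
        assert res.params.kd1 == pytest.approx(truth.kd1, rel=1e-3)
        assert res.params.kd2 == pytest.approx(truth.kd2, rel=1e-3)
        assert res.params.dh1 == pytest.approx(truth.dh1, rel=1e-3)
        assert res.params.dh2 == pytest.approx(truth.dh2, rel=1e-3)

    def test_one_site_model_on_two_site_data_has_larger_rss(self):
        truth = BindingParameters(
            "two_site", kd1=1e-8, kd2=1e-6, dh1=-60e3, dh2=-20e3
        )
        exp = design(n=35, cell=1e-5, syr=3e-4)
        exp.heats = itc_isotherm(truth, exp)
        rss_one = fit_itc(exp, model="one_site").rss
        rss_two = fit_itc(exp, model="two_site").rss
        assert rss_two < rss_one

    def test_thermodynamic_decomposition_consistent(self):
        truth = BindingParameters("one_site", kd1=1e-7, dh1=-50e3)
        exp = design(n=30)
        exp.heats = itc_isotherm(truth, exp)
        res = fit_itc(exp, model="one_site")
        T = exp.temperature
        assert res.dg1 == pytest.approx(8.314 * T * math.log(res.params.kd1), rel=1e-9)
        assert res.tds1 == pytest.approx(res.params.dh1 - res.dg1, rel=1e-9)
        # exothermic binding tighter than its enthalpy alone would allow:
        # negative dG with entropic penalty reported on the same scale
        assert res.dg1 < 0

    def test_too_few_injections_rejected(self):
        exp = design(n=5, heats=[1e-6] * 5)
        with pytest.raises(ValueError, match="10 injections"):
            ItcModel(exp, model="one_site")

    def test_summary_mentions_both_sites(self):
        truth = BindingParameters(
            "two_site", kd1=1e-8, kd2=2e-7, dh1=-60e3, dh2=-45e3
        )
        exp = design(n=35, cell=1e-5, syr=3e-4)
        exp.heats = itc_isotherm(truth, exp)
        s = fit_itc(exp, model="two_site").summary()
        assert "Kd1" in s and "Kd2" in s and "TdS" in s


class TestSlowExchangeEstimator:
    def test_equal_integrals_give_half_total(self):
        # f = 1/2 at equal totals C: kd = C(1-f)^2/f = C/2
        C = 5.4e-4
        est = kd_from_integrals([NmrIntegralPair("g", 1.0, 1.0)], C, C)
        assert est.kd_mean == pytest.approx(C / 2, rel=1e-12)

    def test_round_trip_identity_over_kd_grid(self):
        C = 5.4e-4
        for kd in np.logspace(-9, -2, 30):
            f = bound_fraction_forward(kd, C, C)
            est = kd_from_integrals([NmrIntegralPair("r", 1 - f, f)], C, C)
            assert est.kd_mean == pytest.approx(kd, rel=1e-9)

    def test_round_trip_with_unequal_totals(self):
        p, r = 4e-4, 7e-4
        for kd in (1e-6, 3e-4, 2.7e-3):
            f = bound_fraction_forward(kd, p, r)
            est = kd_from_integrals([NmrIntegralPair("r", 1 - f, f)], p, r)
            assert est.kd_mean == pytest.approx(kd, rel=1e-9)

    def test_hcn_gga2_like_fraction(self):
        # kd = 2.7 mM at 0.54 mM totals: bound fraction ~0.146
        f = bound_fraction_forward(2.7e-3, 5.4e-4, 5.4e-4)
        assert f == pytest.approx(0.1459, abs=5e-4)

    def test_forward_limits(self):
        C = 5.4e-4
        assert bound_fraction_forward(1e3, C, C) < 1e-6
        assert bound_fraction_forward(1e-15, C, C) == pytest.approx(1.0, abs=1e-5)

    def test_noisy_pairs_have_positive_sd(self):
        rng = np.random.default_rng(5)
        f = bound_fraction_forward(3e-4, 5.4e-4, 5.4e-4)
        pairs = [
            NmrIntegralPair(f"r{i}", (1 - f) * rng.lognormal(0, 0.05), f * rng.lognormal(0, 0.05))
            for i in range(4)
        ]
        est = kd_from_integrals(pairs, 5.4e-4, 5.4e-4)
        assert est.kd_sd > 0
        assert est.kd_mean == pytest.approx(3e-4, rel=0.3)

    def test_single_pair_flagged(self):
        est = kd_from_integrals([NmrIntegralPair("g", 1.0, 1.0)], 1e-4, 1e-4)
        assert est.single_pair and est.kd_sd == 0.0

    @pytest.mark.parametrize("i_free,i_bound", [(0.0, 1.0), (1.0, 0.0)])
    def test_fraction_at_boundary_rejected(self, i_free, i_bound):
        with pytest.raises(SlowExchangeError):
            kd_from_integrals([NmrIntegralPair("g", i_free, i_bound)], 1e-4, 1e-4)
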