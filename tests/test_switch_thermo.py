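"""Unit and property tests for the five-state switch equilibrium model."""

import math
from dataclasses import replace

import numpy as np
import pytest

from lockrkit.switch_thermo import (
    DoseResponse,
    MutationEffect,
    ReadoutModel,
    SwitchParams,
    Totals,
    apply_mutations,
    dose_response,
    dynamic_range,
    ec50,
    ratio,
    signal,
    solve_equilibrium,
    state_weights,
    tune,
)

from _oracles import oracle_equilibrium, oracle_tune
from conftest import random_param_sets

RT = 0.593  # kcal/mol at 298.15 K


class TestStateWeights:
    def test_symmetric_reference_case(self):
        """dG=0 with nothing free: closed and open/empty weigh equally."""
        p = SwitchParams(dG_close=0.0, Kd_key=1e-6, Kd_target=1e-7)
        w = state_weights(p, 0.0, 0.0)
        assert np.allclose(w, [1, 1, 0, 0, 0])
        assert w[0] / w.sum() == pytest.approx(0.5)

    def test_target_at_its_kd_matches_open_empty(self):
        p = SwitchParams(dG_close=-1.0, Kd_key=1e-6, Kd_target=1e-7)
        w = state_weights(p, 0.0, 1e-7)
        assert w[2] == pytest.approx(w[1])

    def test_closed_weight_is_boltzmann_factor(self):
        """Hand-evaluated exponential for dG_close = -2 kcal/mol at 298.15 K."""
        p = SwitchParams(dG_close=-2.0, Kd_key=1e-6, Kd_target=1e-7)
        w = state_weights(p, 0.0, 0.0)
        expected = math.exp(2.0 / (1.987204259e-3 * 298.15))  # 29.168...
        assert w[0] == pytest.approx(expected, rel=1e-12)
        assert w[0] / (w[0] + 1.0) == pytest.approx(expected / (expected + 1))

    def test_negative_concentration_rejected(self):
        p = SwitchParams(dG_close=0.0, Kd_key=1e-6, Kd_target=1e-7)
        with pytest.raises(ValueError):
            state_weights(p, -1e-9, 0.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SwitchParams(dG_close=0.0, Kd_key=0.0, Kd_target=1e-7)
        with pytest.raises(ValueError):
            SwitchParams(dG_close=0.0, Kd_key=1e-6, Kd_target=1e-7, temperature_K=0)


class TestSolveEquilibrium:
    def test_dilute_limit_matches_closed_form(self, base_params):
        """At vanishing cage concentration nothing is depleted."""
        totals = Totals(C_tot=1e-15, K_tot=1e-6, T_tot=1e-7)
        eq = solve_equilibrium(base_params, totals)
        assert eq.K_free == pytest.approx(totals.K_tot, rel=1e-6)
        assert eq.T_free == pytest.approx(totals.T_tot, rel=1e-6)
        w = state_weights(base_params, totals.K_tot, totals.T_tot)
        assert np.allclose(eq.populations, w / w.sum(), rtol=1e-6)

    def test_mass_balance_residual_contract(self, base_params):
        rng = np.random.default_rng(7)
        for params, totals in random_param_sets(rng, 50):
            eq = solve_equilibrium(params, totals)
            assert eq.residual < 1e-9

    def test_agrees_with_nested_bisection_oracle(self):
        """Populations match an independently coded grid/bisection solver."""
        rng = np.random.default_rng(11)
        for params, totals in random_param_sets(rng, 100):
            eq = solve_equilibrium(params, totals)
            _, _, p_oracle = oracle_equilibrium(
                params.dG_close,
                params.Kd_key,
                params.Kd_target,
                totals.C_tot,
                totals.K_tot,
                totals.T_tot,
            )
            np.testing.assert_allclose(
                eq.populations, p_oracle, rtol=1e-6, atol=1e-12
            )

    def test_strong_depletion_regime(self, base_params):
        """Cage far in excess of key and target still satisfies balance."""
        totals = Totals(C_tot=1e-4, K_tot=1e-7, T_tot=1e-8)
        eq = solve_equilibrium(base_params, totals)
        assert eq.residual < 1e-9
        assert 0 <= eq.K_free <= totals.K_tot
        assert 0 <= eq.T_free <= totals.T_tot


class TestSignalAndRatio:
    def test_no_key_no_signal(self, base_params, readout):
        totals = Totals(C_tot=1e-6, K_tot=0.0, T_tot=1e-6)
        assert signal(base_params, totals) == 0.0
        assert ratio(base_params, totals, readout) == readout.R_min

    def test_open_latch_dilute_limit_is_binary_binding(self):
        """With the latch never closing and no target, key binding is a
        simple bimolecular occupancy K/(K + Kd)."""
        p = SwitchParams(dG_close=50.0, Kd_key=1e-6, Kd_target=1e-7)
        totals = Totals(C_tot=1e-15, K_tot=5e-7, T_tot=0.0)
        expected = (totals.K_tot / p.Kd_key) / (1 + totals.K_tot / p.Kd_key)
        assert signal(p, totals) == pytest.approx(expected, rel=1e-6)

    def test_signal_strictly_increasing_in_target(self, base_params, base_totals):
        doses = np.logspace(-9, -5, 9)
        sig = [
            signal(base_params, replace(base_totals, T_tot=d)) for d in doses
        ]
        assert np.all(np.diff(sig) > 0)

    def test_monotone_in_key_and_kd_key(self, base_params):
        t = Totals(C_tot=1e-6, K_tot=1e-6, T_tot=1e-7)
        more_key = signal(base_params, replace(t, K_tot=2e-6))
        assert more_key > signal(base_params, t)
        weaker_key = replace(base_params, Kd_key=base_params.Kd_key * 10)
        assert signal(weaker_key, t) < signal(base_params, t)


class TestDoseResponse:
    def test_single_basal_point(self, base_params, base_totals):
        dr = dose_response(base_params, base_totals, [0.0])
        assert dr.signal[0] == pytest.approx(signal(base_params, base_totals))

    def test_sigmoid_spans_most_of_the_gap(self, base_params, base_totals):
        """A grid from 1e-3 to 1e3 times Kd_target covers >=90% of the
        basal-to-plateau range."""
        kd = base_params.Kd_target
        grid = np.r_[0.0, np.logspace(np.log10(kd) - 3, np.log10(kd) + 3, 25)]
        dr = dose_response(base_params, base_totals, grid)
        basal, plateau = dr.signal[0], dr.signal[-1]
        inner = dr.signal[1:]  # positive-dose portion
        covered = (inner.max() - inner.min()) / (plateau - basal)
        assert covered >= 0.90
        assert np.all(np.diff(dr.signal) >= 0)

    def test_non_ascending_grid_rejected(self, base_params, base_totals):
        with pytest.raises(ValueError):
            dose_response(base_params, base_totals, [0.0, 1e-7, 1e-7])


class TestDynamicRangeAndEc50:
    def test_flat_response_has_zero_dynamic_range(self):
        dr = DoseResponse(np.array([0.0, 1e-7]), np.array([0.2, 0.2]))
        assert dynamic_range(dr) == 0.0

    def test_dynamic_range_is_plateau_minus_basal(self):
        dr = DoseResponse(
            np.array([0.0, 1e-8, 1e-6]), np.array([0.1, 0.3, 0.6])
        )
        assert dynamic_range(dr) == pytest.approx(0.5)

    def test_dynamic_range_requires_basal(self):
        dr = DoseResponse(np.array([1e-8, 1e-6]), np.array([0.3, 0.6]))
        with pytest.raises(ValueError):
            dynamic_range(dr)

    def test_dynamic_range_nonnegative_on_model_output(
        self, base_params, base_totals
    ):
        grid = np.r_[0.0, np.logspace(-9, -5, 9)]
        dr = dose_response(base_params, base_totals, grid)
        assert dynamic_range(dr) >= 0.0

    def test_ec50_of_constructed_symmetric_sigmoid(self):
        """Hill curve centred at 1e-7 M recovered within one grid step."""
        doses = np.logspace(-9, -5, 41)
        sig = doses / (doses + 1e-7)
        dr = DoseResponse(doses, sig)
        est = ec50(dr)
        step = 10 ** (np.diff(np.log10(doses))[0])
        assert 1e-7 / step <= est <= 1e-7 * step

    def test_latch_weakening_shifts_ec50_to_lower_dose(
        self, base_params, base_totals
    ):
        """A weaker latch responds at lower target concentrations."""
        grid = np.r_[0.0, np.logspace(-10, -4, 25)]
        weak = replace(base_params, dG_close=base_params.dG_close + 2.0)
        e_base = ec50(dose_response(base_params, base_totals, grid))
        e_weak = ec50(dose_response(weak, base_totals, grid))
        assert e_weak < e_base

    def test_flat_curve_flagged_undefined(self):
        dr = DoseResponse(np.array([0.0, 1e-8, 1e-7]), np.array([0.2, 0.2, 0.2]))
        with pytest.warns(UserWarning):
            assert math.isnan(ec50(dr))


class TestMutations:
    def test_empty_effect_list_is_identity(self, base_params):
        assert apply_mutations(base_params, []) == base_params

    def test_key_effect_scales_kd_by_construction(self, base_params):
        e = MutationEffect("k1", "key", base_params.RT * math.log(10))
        out = apply_mutations(base_params, [e])
        assert out.Kd_key == pytest.approx(base_params.Kd_key * 10, rel=1e-12)
        assert out.dG_close == base_params.dG_close

    def test_latch_effect_adds_to_dG(self, base_params):
        out = apply_mutations(
            base_params, [MutationEffect("l1", "latch", 1.5)]
        )
        assert out.dG_close == pytest.approx(base_params.dG_close + 1.5)

    def test_effects_are_additive(self, base_params):
        effects = [
            MutationEffect("l1", "latch", 1.0),
            MutationEffect("l2", "latch", 0.5),
            MutationEffect("k1", "key", 1.0),
            MutationEffect("k2", "key", 0.7),
        ]
        out = apply_mutations(base_params, effects)
        assert out.dG_close == pytest.approx(base_params.dG_close + 1.5)
        assert out.Kd_key == pytest.approx(
            base_params.Kd_key * math.exp(1.7 / base_params.RT)
        )

    def test_unknown_interface_rejected(self):
        with pytest.raises(ValueError):
            MutationEffect("x", "cage", 1.0)

    def test_tuning_directions_match_observed_laws(self, base_params):
        """Latch weakening raises background; key weakening lowers both
        background and saturating signal."""
        totals0 = Totals(C_tot=1e-6, K_tot=1e-6, T_tot=0.0)
        totals_sat = Totals(C_tot=1e-6, K_tot=1e-6, T_tot=1e-4)
        bg = signal(base_params, totals0)
        sat = signal(base_params, totals_sat)
        latch_weak = apply_mutations(
            base_params, [MutationEffect("l", "latch", 1.0)]
        )
        assert signal(latch_weak, totals0) > bg
        key_weak = apply_mutations(base_params, [MutationEffect("k", "key", 1.0)])
        assert signal(key_weak, totals0) < bg
        assert signal(key_weak, totals_sat) < sat


class TestTune:
    LIB = [
        MutationEffect("k_weak1", "key", 0.8),
        MutationEffect("k_weak2", "key", 1.5),
        MutationEffect("l_weak1", "latch", 0.7),
        MutationEffect("l_weak2", "latch", 1.2),
    ]

    def test_empty_library_selects_empty_subset(self, base_params, base_totals):
        rep = tune(base_params, [], (1e-8, 1e-6), 1.0, base_totals)
        assert rep.selected == ()
        assert rep.feasible

    def test_tight_cap_forces_key_weakening(self, base_totals):
        """When the unmutated sensor exceeds the background cap, the single
        helpful key-weakening mutation is selected."""
        leaky = SwitchParams(dG_close=0.0, Kd_key=1e-7, Kd_target=1e-7)
        lib = [MutationEffect("k_fix", "key", 2.0)]
        bg_unmutated = signal(leaky, replace(base_totals, T_tot=0.0))
        cap = bg_unmutated * 0.5
        rep = tune(leaky, lib, (1e-8, 1e-6), cap, base_totals)
        assert rep.feasible
        assert [e.name for e in rep.selected] == ["k_fix"]

    def test_matches_brute_force_enumeration_oracle(
        self, base_params, base_totals
    ):
        window, cap = (1e-8, 1e-6), 0.10
        rep = tune(base_params, self.LIB, window, cap, base_totals)
        expected = oracle_tune(
            base_params, self.LIB, window, cap, base_totals, signal, apply_mutations
        )
        assert sorted(e.name for e in rep.selected) == sorted(
            e.name for e in expected
        )
        assert rep.feasible
        assert rep.background <= cap

    def test_infeasible_cap_flagged(self, base_params, base_totals):
        with pytest.warns(UserWarning):
            rep = tune(base_params, self.LIB, (1e-8, 1e-6), -1.0, base_totals)
        assert not rep.feasible

    def test_oversized_library_rejected(self, base_params, base_totals):
        lib = [MutationEffect(f"m{i}", "key", 0.1) for i in range(21)]
        with pytest.raises(ValueError):
            tune(base_params, lib, (1e-8, 1e-6), 1.0, base_totals)
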