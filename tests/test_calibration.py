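import numpy as np
import pytest

from baskex import (
    DecisionRule,
    ModelConfig,
    ResponseScenario,
    SamplerSettings,
    calibrate_cbhm_ab,
    calibrate_delta_alpha,
    select_cutoff_c,
)
from baskex.calibrate import solve_cbhm_ab


class TestDecisionRule:
    def test_strict_threshold(self):
        rule = DecisionRule("independent", 0.9, 0.0, 0.1, "basketwise")
        probs = np.array([0.89, 0.9, 0.91])
        assert rule.decide(probs).tolist() == [False, False, True]

    def test_tie_break_probability(self):
        rule = DecisionRule("independent", 0.9, 0.5, 0.1, "basketwise")
        rng = np.random.default_rng(0)
        ties = np.full(20_000, 0.9)
        frac = rule.decide(ties, rng).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_method_binding(self):
        rule = DecisionRule("bhm", 0.9, 0.0, 0.1, "basketwise")
        with pytest.raises(ValueError, match="calibrated for"):
            rule.check_method("bma")

    def test_json_round_trip(self, tmp_path):
        rule = DecisionRule("exnex", 0.8721, 0.3, 0.1, "fwer", {"n": [13] * 5})
        path = tmp_path / "rule.json"
        rule.to_json(path)
        assert DecisionRule.from_json(path) == rule

    def test_validation(self):
        with pytest.raises(ValueError):
            DecisionRule("x", 1.2, 0.0, 0.1, "basketwise")
        with pytest.raises(ValueError):
            DecisionRule("x", 0.5, 0.0, 0.1, "perbasket")


class TestDeltaAlphaCalibration:
    def test_alpha_one_rejects_everything(self):
        rule = calibrate_delta_alpha("independent", [13] * 5, 0.15, alpha=1.0, replicates=200, seed=1)
        probs = np.array([0.0, 0.004, 0.5, 1.0])
        assert rule.decide(probs, np.random.default_rng(0)).all()

    def test_achieved_null_rate_is_exact_on_calibration_sample(self):
        """The randomized tie-break makes the null rejection rate = alpha."""
        from baskex.simulate import posterior_probs_batch

        n = np.array([13] * 5)
        rule = calibrate_delta_alpha("independent", n, 0.15, alpha=0.10, replicates=4000, seed=3)
        rng = np.random.default_rng(9)
        Y = rng.binomial(n, 0.15, size=(4000, 5))
        probs, _ = posterior_probs_batch("independent", Y, n, 0.15)
        rate = rule.decide(probs, rng).mean()
        assert rate == pytest.approx(0.10, abs=0.012)

    def test_monotone_in_alpha(self):
        deltas = []
        effective = []
        for alpha in (0.05, 0.10, 0.20, 0.40):
            rule = calibrate_delta_alpha(
                "independent", [13] * 5, 0.15, alpha=alpha, replicates=3000, seed=11
            )
            deltas.append(rule.delta_alpha)
            # effective threshold: delta minus the tie mass already granted
            effective.append((rule.delta_alpha, -rule.tie_prob))
        assert all(b <= a for a, b in zip(deltas, deltas[1:]))
        assert all(b <= a for a, b in zip(effective, effective[1:]))

    def test_fwer_control_realized(self):
        from baskex.simulate import run_operating_characteristics
        from baskex.data import ResponseScenario

        n = [13] * 5
        rule = calibrate_delta_alpha(
            "independent", n, 0.15, alpha=0.25, replicates=8000, seed=21, control="fwer"
        )
        null = ResponseScenario(p=(0.15,) * 5, name="null")
        oc = run_operating_characteristics("independent", null, n, rule, 8000, seed=22)
        assert oc.fwer_pct == pytest.approx(25.0, abs=1.5)

    def test_degenerate_distribution_errors(self):
        # a 1-patient basket at q0 tiny still has 2 outcomes; force
        # degeneracy through constant probabilities instead
        from baskex.calibrate import _pooled_threshold

        with pytest.raises(ValueError, match="degenerate"):
            _pooled_threshold(np.full(100, 0.5), 0.1)


class TestCBHMCalibration:
    def test_solver_algebra_identity(self):
        a, b = solve_cbhm_ab(1.0, 80.0)
        assert (a, b) == pytest.approx((0.0, 1.0), abs=1e-14)

    def test_defining_equations_hold(self):
        cal = calibrate_cbhm_ab([13] * 5, 0.15, 0.45, replicates=500, seed=5)
        assert np.exp(cal.a + cal.b * np.log(cal.HB)) == pytest.approx(1.0, rel=1e-12)
        assert np.exp(cal.a + cal.b * np.log(cal.HB_bar)) == pytest.approx(80.0, rel=1e-12)

    def test_equal_mode_scenario_count(self):
        cal = calibrate_cbhm_ab([13] * 5, 0.15, 0.45, replicates=300, seed=5)
        assert cal.mode == "equal"
        assert cal.n_heterogeneity_configs == 4  # first-j, j = 1..K-1

    def test_unequal_permutation_count(self):
        cal = calibrate_cbhm_ab(
            [20, 10, 8, 18, 7], 0.15, 0.45, replicates=300, seed=5, mode="permutations"
        )
        assert cal.n_heterogeneity_configs == 2**5 - 2

    def test_auto_mode_uses_rounded_mean_size(self):
        cal = calibrate_cbhm_ab([20, 10, 8, 18, 7], 0.15, 0.45, replicates=300, seed=5)
        assert cal.n_calibration == (13,) * 5  # mean 12.6 rounds to 13
        assert cal.mode == "equal"

    def test_non_separated_medians_error(self):
        with pytest.raises(ValueError, match="not separated"):
            solve_cbhm_ab(5.0, 5.0)


class TestCutoffSelection:
    light = SamplerSettings(chains=2, iterations=2_000, burn_in=1_000)

    def test_singleton_grid_identity(self):
        sel = select_cutoff_c(
            [0.1], x=0.4, n=[13] * 5, q0=0.15, q1=0.45,
            replicates=100, cal_replicates=200, seed=5, settings=self.light,
        )
        assert sel.chosen_c == 0.1

    def test_power_only_objective_prefers_larger_cutoff(self):
        """x = 1 under an all-sensitive truth rewards maximal borrowing."""
        sel = select_cutoff_c(
            [0.0, 2 / 13], x=1.0, n=[13] * 5, q0=0.15, q1=0.45,
            scenarios=[ResponseScenario(p=(0.45,) * 5, name="all-sensitive")],
            replicates=150, cal_replicates=300, seed=5, settings=self.light,
        )
        assert sel.chosen_c == pytest.approx(2 / 13)
        assert sel.power[1] > sel.power[0]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff_c([], 0.4, [13] * 5, 0.15, 0.45)
        with pytest.raises(ValueError):
            select_cutoff_c([0.1], 0.4, [13] * 5, 0.15, 0.45, scenarios=[])
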