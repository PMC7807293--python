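import numpy as np
import pytest

from prtcea.engine import (
    HealthState,
    cohort_expectation,
    cost_for_cycle,
    discount_factor,
    hr_adjust_probability,
    resolve_arm,
    simulate_cohort,
    simulate_patient,
    utility_for_cycle,
)

S, P1, P2, D = (HealthState.STABLE, HealthState.PROGRESSION1,
                HealthState.PROGRESSION2, HealthState.DEAD)


def zero_transitions(params):
    """Disable every disease transition and toxicity process."""
    for name in ("p_progress_adt", "p_death_stable", "p_death_progression",
                 "p_prog1_to_prog2", "p_tox_gu", "p_tox_gi"):
        params.set_value(name, 0.0)
    params.set_value("hr_progression_prt", 1.0)
    return params


class TestHazardRatioAdjustment:
    @pytest.mark.parametrize("p,hr,expected", [
        (0.035, 0.59, 1 - 0.965**0.59),  # rounds to the printed 0.020
        (0.2, 1.0, 0.2),
        (0.0, 0.7, 0.0),
    ])
    def test_values(self, p, hr, expected):
        assert hr_adjust_probability(p, hr) == pytest.approx(expected)

    def test_printed_anchor(self):
        # 0.035 under an HR of 0.59 reproduces the printed PRT value 0.020
        assert round(hr_adjust_probability(0.035, 0.59), 2) == 0.02

    def test_errors(self):
        with pytest.raises(ValueError):
            hr_adjust_probability(1.0, 0.5)
        with pytest.raises(ValueError):
            hr_adjust_probability(0.5, 0.0)


class TestDiscounting:
    def test_values(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(12, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(24, 0.03) == pytest.approx(1 / 1.03**2)

    def test_negative_cycle(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


class TestPerCycleAccrual:
    def test_utilities(self, params, settings):
        adt = resolve_arm("adt", params, settings)
        prt = resolve_arm("prt", params, settings)
        assert utility_for_cycle(S, adt, 5) == 0.90
        assert utility_for_cycle(S, prt, 0) == 0.83
        # both toxicity trackers set: the elicited joint weight applies
        assert utility_for_cycle(S, prt, 10, tox_gu=True, tox_gi=True) == 0.76
        assert utility_for_cycle(P2, adt, 3) == 0.11
        # single-site GU toxicity (0.90) cannot raise a lower state utility
        assert utility_for_cycle(P1, prt, 4, tox_gu=True) == 0.70
        with pytest.raises(ValueError):
            utility_for_cycle(D, adt, 1)

    def test_treatment_only_utility_mode(self, params, settings):
        s = settings.copy(prt_utility_mode="treatment_only", prt_treatment_cycles=2)
        prt = resolve_arm("prt", params, s)
        assert utility_for_cycle(S, prt, 0) == 0.83
        assert utility_for_cycle(S, prt, 1) == 0.83
        assert utility_for_cycle(S, prt, 2) == 0.90

    def test_costs(self, params, settings):
        adt = resolve_arm("adt", params, settings)
        prt = resolve_arm("prt", params, settings)
        assert cost_for_cycle(S, prt, 0) == 16860 + 63
        assert cost_for_cycle(S, adt, 0) == 63
        assert cost_for_cycle(P2, adt, 7) == 17365 + 63
        # cycle in which the death transition fires: state cost + death cost
        assert cost_for_cycle(P1, adt, 7, death_this_cycle=True) == 5738 + 63 + 5772
        assert cost_for_cycle(S, adt, 3, upfront_abi_cost=5738.0) == 63 + 5738


class TestDegenerateClosedForms:
    def test_zero_transition_qalys_and_costs(self, params, settings):
        zero_transitions(params)
        dfs = (1.03) ** (-np.arange(37) / 12)
        for arm, u, once in (("adt", 0.90, 0.0), ("prt", 0.83, 16860.0)):
            expected_q = u * dfs.sum() / 12
            expected_c = 63 * dfs.sum() + once
            res = simulate_cohort(arm, params, settings, rng=0, n_trials=50)
            assert res.qaly_trials == pytest.approx(expected_q, abs=1e-9)
            assert res.cost_trials == pytest.approx(expected_c, abs=1e-9)
            exp = cohort_expectation(arm, params, settings)
            assert exp.qalys == pytest.approx(expected_q, abs=1e-9)
            assert exp.cost == pytest.approx(expected_c, abs=1e-9)
            # a deterministic cohort has zero-width confidence intervals
            lo, hi = res.ci_qalys
            assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_forced_death(self, params, settings):
        zero_transitions(params)
        params.set_value("p_death_stable", 1.0)
        traj = simulate_patient("adt", params, settings, np.random.default_rng(0))
        assert traj.death_cycle == 1
        assert traj.state_path[0] == S and traj.state_path[1] == D
        assert traj.discounted_cost == pytest.approx(63 + 5772)
        assert traj.discounted_qalys == pytest.approx(0.90 / 12)

    def test_hr_one_and_no_toxicity_parameter_symmetry(self, params, settings):
        params.set_value("hr_progression_prt", 1.0)
        params.set_value("p_tox_gu", 0.0)
        params.set_value("p_tox_gi", 0.0)
        params.set_value("u_stable_prt", params["u_stable_adt"])
        a = cohort_expectation("adt", params, settings)
        b = cohort_expectation("prt", params, settings)
        assert b.qalys == pytest.approx(a.qalys, abs=1e-12)
        assert b.cost - a.cost == pytest.approx(16860.0, abs=1e-9)


def enumerate_expectation(arm, params, settings, horizon):
    """Independent oracle: exhaustive enumeration over every outcome path.

    Walks the full tree of (disease transition x toxicity onset) outcomes,
    weighting each path by its probability, and accrues cost/QALYs with the
    same cycle conventions the engine documents.
    """
    inputs = resolve_arm(arm, params, settings)
    out = {"cost": 0.0, "qalys": 0.0}

    def recurse(t, state, gu, gi, prob, cost, qalys):
        if t == horizon or state == D:
            out["cost"] += prob * cost
            out["qalys"] += prob * qalys
            return
        df = (1 + settings.annual_discount_rate) ** (-t / 12)
        tox_branches = [(gu, gi, 1.0, 0)]
        if inputs.p_tox_gu > 0 or inputs.p_tox_gi > 0:
            # explicit enumeration of the two independent tracker draws
            gu_opts = [(gu, 1.0, 0)] if gu else [
                (True, inputs.p_tox_gu, 1), (False, 1 - inputs.p_tox_gu, 0)]
            gi_opts = [(gi, 1.0, 0)] if gi else [
                (True, inputs.p_tox_gi, 1), (False, 1 - inputs.p_tox_gi, 0)]
            tox_branches = [
                (g1, g2, p1 * p2, n1 + n2)
                for g1, p1, n1 in gu_opts for g2, p2, n2 in gi_opts
            ]
        for new_gu, new_gi, p_tox, n_onsets in tox_branches:
            u = utility_for_cycle(state, inputs, t, new_gu, new_gi)
            q_inc = u / 12 * df
            if t < horizon - 1:
                if state == S:
                    moves = [(P1, inputs.p_progress), (D, inputs.p_death_stable)]
                elif state == P1:
                    moves = [(P2, inputs.p_p1_to_p2), (D, inputs.p_death_p1)]
                else:
                    moves = [(D, inputs.p_death_p2)]
                stay_p = 1.0 - sum(p for _, p in moves)
                moves.append((state, stay_p))
                for new_state, p_move in moves:
                    if p_move == 0.0:
                        continue
                    died = new_state == D
                    c_inc = df * cost_for_cycle(
                        state, inputs, t, n_tox_onsets=n_onsets,
                        death_this_cycle=died)
                    recurse(t + 1, new_state, new_gu, new_gi,
                            prob * p_tox * p_move, cost + c_inc, qalys + q_inc)
            else:
                c_inc = df * cost_for_cycle(state, inputs, t, n_tox_onsets=n_onsets)
                recurse(t + 1, state, new_gu, new_gi,
                        prob * p_tox, cost + c_inc, qalys + q_inc)

    recurse(0, S, False, False, 1.0, 0.0, 0.0)
    return out["cost"], out["qalys"]


class TestEnumerationOracle:
    """3-cycle exhaustive enumeration vs closed form and Monte Carlo."""

    @pytest.fixture
    def loud_params(self, params):
        # large probabilities so every path carries real weight
        params.set_value("p_progress_adt", 0.3)
        params.set_value("p_death_stable", 0.1)
        params.set_value("p_prog1_to_prog2", 0.25)
        params.set_value("p_death_progression", 0.2)
        params.set_value("p_tox_gu", 0.10)
        params.set_value("p_tox_gi", 0.15)
        params.set_value("hr_progression_prt", 0.5)
        return params

    @pytest.mark.parametrize("arm", ["adt", "prt"])
    def test_against_closed_form(self, loud_params, settings, arm):
        cost, qalys = enumerate_expectation(arm, loud_params, settings, 3)
        exp = cohort_expectation(arm, loud_params, settings, horizon=3)
        assert exp.cost == pytest.approx(cost, rel=1e-12)
        assert exp.qalys == pytest.approx(qalys, rel=1e-12)

    @pytest.mark.parametrize("arm", ["adt", "prt"])
    def test_against_monte_carlo(self, loud_params, settings, arm):
        cost, qalys = enumerate_expectation(arm, loud_params, settings, 3)
        res = simulate_cohort(arm, loud_params, settings, rng=42,
                              n_trials=40_000, horizon=3)
        assert res.mean_cost == pytest.approx(cost, abs=3 * res.se_cost)
        assert res.mean_qalys == pytest.approx(qalys, abs=3 * res.se_qalys)


class TestCohortSimulation:
    def test_reproducibility(self, params, settings):
        a = simulate_cohort("prt", params, settings, rng=123, n_trials=500)
        b = simulate_cohort("prt", params, settings, rng=123, n_trials=500)
        assert np.array_equal(a.cost_trials, b.cost_trials)
        assert np.array_equal(a.qaly_trials, b.qaly_trials)

    @pytest.mark.parametrize("arm", ["adt", "prt"])
    def test_alive_curve_monotone(self, params, settings, arm):
        res = simulate_cohort(arm, params, settings, rng=3, n_trials=2000)
        assert np.all(np.diff(res.alive_curve) <= 0)
        assert np.all(np.diff(res.ffs_curve) <= 0)
        assert np.all(res.ffs_curve <= res.alive_curve + 1e-12)
        assert res.alive_curve[0] == 1.0

    @pytest.mark.parametrize("arm", ["adt", "prt"])
    def test_mc_matches_expectation(self, params, settings, arm):
        res = simulate_cohort(arm, params, settings, rng=11, n_trials=20_000)
        exp = cohort_expectation(arm, params, settings)
        assert res.mean_cost == pytest.approx(exp.cost, abs=3 * res.se_cost)
        assert res.mean_qalys == pytest.approx(exp.qalys, abs=3 * res.se_qalys)
        # survival curves agree within 3 binomial SEs pointwise
        se = np.sqrt(exp.os_curve * (1 - exp.os_curve) / 20_000)
        assert np.all(np.abs(res.alive_curve - exp.os_curve) <= 3 * se + 1e-9)

    def test_se_scaling_with_trials(self, params, settings):
        small = simulate_cohort("adt", params, settings, rng=5, n_trials=2000)
        big = simulate_cohort("adt", params, settings, rng=6, n_trials=8000)
        assert big.se_qalys == pytest.approx(small.se_qalys / 2, rel=0.15)

    def test_toxicity_only_in_prt_arm(self, params, settings):
        adt = simulate_cohort("adt", params, settings, rng=1, n_trials=2000)
        prt = simulate_cohort("prt", params, settings, rng=1, n_trials=2000)
        assert adt.tox_gu_incidence == 0.0 and adt.tox_gi_incidence == 0.0
        assert prt.tox_gu_incidence > 0.0 and prt.tox_gi_incidence > 0.0

    def test_schedule_override_matches_scalar(self, params, settings):
        ov = {"p_progress": np.full(37, params["p_progress_adt"])}
        a = cohort_expectation("adt", params, settings)
        b = cohort_expectation("adt", params, settings, overrides=ov)
        assert b.cost == pytest.approx(a.cost, rel=1e-12)
        assert b.qalys == pytest.approx(a.qalys, rel=1e-12)

    def test_piecewise_schedule_changes_hazard_when_it_should(self, params, settings):
        sched = np.concatenate([np.full(12, 0.01), np.full(25, 0.08)])
        exp = cohort_expectation("adt", params, settings,
                                 overrides={"p_progress": sched})
        flat = cohort_expectation("adt", params, settings,
                                  overrides={"p_progress": 0.01})
        # identical failure-free survival for the first 13 cycles, lower after
        assert exp.ffs_curve[:13] == pytest.approx(flat.ffs_curve[:13], rel=1e-12)
        assert np.all(exp.ffs_curve[14:] < flat.ffs_curve[14:])


class TestOutcomeMonotonicity:
    def test_qalys_decrease_with_any_utility(self, params, settings):
        ref = cohort_expectation("prt", params, settings).qalys
        for name in ("u_stable_prt", "u_progression1", "u_progression2", "u_tox_both"):
            p = params.copy()
            p.set_value(name, max(0.0, p[name] - 0.05))
            assert cohort_expectation("prt", p, settings).qalys <= ref + 1e-12, name

    def test_cost_increases_with_any_cost_parameter(self, params, settings):
        ref = cohort_expectation("prt", params, settings).cost
        for name in ("c_prt_once", "c_adt_monthly", "c_progression1_monthly",
                     "c_progression2_monthly", "c_death_once", "c_tox_once"):
            p = params.copy()
            p.set_value(name, p[name] * 1.1)
            assert cohort_expectation("prt", p, settings).cost > ref, name
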