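import numpy as np
import pandas as pd
import pytest
from lifelines import AalenJohansenFitter, KaplanMeierFitter

from hedscape.outcomes import (
    CENSORED,
    DEATH,
    RELAPSE,
    CoxConvergenceError,
    SubjectOutcome,
    build_design,
    cif_aalen_johansen,
    cox_cause_specific,
    km_estimate,
    logrank_test,
    outcomes_to_frame,
)


def mk(times_states, group=None):
    out = []
    for i, (t, s) in enumerate(times_states):
        cov = {} if group is None else {"g": group[i]}
        out.append(SubjectOutcome(f"S{i}", float(t), s, cov))
    return out


def random_outcomes(rng, n, p_death=0.3, p_censor=0.3, tie_scale=None):
    times = rng.exponential(10, n)
    if tie_scale:
        times = np.ceil(times / tie_scale) * tie_scale  # monthly-style ties
    states = rng.choice(
        [RELAPSE, DEATH, CENSORED],
        size=n,
        p=[1 - p_death - p_censor, p_death, p_censor],
    )
    return mk(list(zip(times, states)))


class TestSubjectOutcome:
    @pytest.mark.parametrize("t", [0.0, -1.0, np.inf, np.nan])
    def test_bad_time_rejected(self, t):
        with pytest.raises(ValueError):
            SubjectOutcome("S", t, RELAPSE)

    def test_bad_state_rejected(self):
        with pytest.raises(ValueError, match="event state"):
            SubjectOutcome("S", 1.0, "relapsed")


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = km_estimate(mk([(1, CENSORED), (2, CENSORED), (3, CENSORED)]))
        assert (curve.values == 1.0).all()

    def test_hand_product_limit(self):
        # events at 1 and 3, censor at 2: S(1) = 2/3; at t=3 the single
        # remaining subject fails, so S(3) = (2/3)*(1 - 1/1) = 0
        curve = km_estimate(mk([(1, RELAPSE), (2, CENSORED), (3, RELAPSE)]))
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(2 / 3)
        assert curve.at(3) == 0.0
        kmf = KaplanMeierFitter().fit([1, 2, 3], [1, 0, 1])
        assert float(kmf.survival_function_at_times(3).iloc[0]) == 0.0

    def test_single_subject_event_drops_to_zero(self):
        curve = km_estimate(mk([(5, DEATH)]))
        assert curve.at(4.9) == 1.0 and curve.at(5) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        outcomes = random_outcomes(rng, 80, p_death=0.5, p_censor=0.0, tie_scale=1.0)
        times = np.array([o.time for o in outcomes])
        curve = km_estimate(outcomes)
        for t in curve.times:
            assert curve.at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(5)
        outcomes = random_outcomes(rng, 150, tie_scale=2.0)
        curve = km_estimate(outcomes, event_def={RELAPSE, DEATH})
        kmf = KaplanMeierFitter().fit(
            [o.time for o in outcomes],
            [o.event != CENSORED for o in outcomes],
        )
        for t, v in zip(curve.times, curve.values):
            assert v == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_greenwood_variance_hand_value(self):
        # single event among 3 at t=1: Var = S^2 * d/(n(n-d)) = (2/3)^2 * 1/6
        curve = km_estimate(mk([(1, RELAPSE), (2, CENSORED), (3, CENSORED)]))
        assert curve.variance[0] == pytest.approx((2 / 3) ** 2 / 6)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogrank:
    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(mk([(1, RELAPSE), (2, RELAPSE)], group=["a", "a"]), "g")

    def test_identical_event_patterns_give_zero_statistic(self):
        pattern = [(1, RELAPSE), (2, CENSORED), (3, DEATH), (4, RELAPSE)]
        outcomes = mk(pattern + pattern, group=["a"] * 4 + ["b"] * 4)
        stat, p = logrank_test(outcomes, "g")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_sample_statistic_matches_hand_summation(self):
        """Observed-minus-expected summation over risk sets, no ties."""
        data = [(1, RELAPSE, "a"), (2, RELAPSE, "b"), (3, CENSORED, "a"),
                (4, RELAPSE, "a"), (5, RELAPSE, "b"), (6, CENSORED, "b")]
        outcomes = mk([(t, s) for t, s, _ in data], group=[g for _, _, g in data])
        o_minus_e = 0.0
        var = 0.0
        for t, s, g in data:
            if s == CENSORED:
                continue
            at_risk = [(tt, gg) for tt, ss, gg in data if tt >= t]
            n = len(at_risk)
            n_a = sum(1 for _, gg in at_risk if gg == "a")
            o_minus_e += (1 if g == "a" else 0) - n_a / n
            var += (n_a / n) * (1 - n_a / n)
        expected = o_minus_e**2 / var
        stat, _ = logrank_test(outcomes, "g")
        assert stat == pytest.approx(expected, rel=1e-10)

    def test_relabeling_groups_leaves_statistic_unchanged(self):
        rng = np.random.default_rng(3)
        outcomes = random_outcomes(rng, 60, tie_scale=1.0)
        groups = list(rng.choice(["x", "y"], 60))
        a = logrank_test(mk([(o.time, o.event) for o in outcomes], group=groups), "g")
        swapped = ["y" if g == "x" else "x" for g in groups]
        b = logrank_test(mk([(o.time, o.event) for o in outcomes], group=swapped), "g")
        assert a[0] == pytest.approx(b[0], rel=1e-12)


class TestAalenJohansen:
    def test_no_competing_events_equals_one_minus_km(self):
        rng = np.random.default_rng(9)
        outcomes = random_outcomes(rng, 100, p_death=0.0, tie_scale=1.0)
        cif = cif_aalen_johansen(outcomes, RELAPSE)
        km = km_estimate(outcomes, event_def={RELAPSE})
        assert np.allclose(cif.values, 1.0 - km.values, atol=1e-12)

    def test_all_deaths_first_keeps_relapse_cif_zero(self):
        outcomes = mk([(1, DEATH), (2, DEATH), (3, CENSORED)])
        cif = cif_aalen_johansen(outcomes, RELAPSE)
        assert (cif.values == 0.0).all()

    def test_six_subject_hand_computation(self):
        outcomes = mk([
            (1, RELAPSE), (2, DEATH), (3, CENSORED),
            (4, RELAPSE), (5, DEATH), (6, CENSORED),
        ])
        cif_r = cif_aalen_johansen(outcomes, RELAPSE)
        cif_d = cif_aalen_johansen(outcomes, DEATH)
        # hand risk-set computation: S(1-)=1, S(2-)=5/6, S(4-)=2/3, S(5-)=4/9
        assert cif_r.at(1) == pytest.approx(1 / 6)
        assert cif_r.at(3.9) == pytest.approx(1 / 6)
        assert cif_r.at(4) == pytest.approx(1 / 6 + (2 / 3) * (1 / 3))
        assert cif_d.at(2) == pytest.approx((5 / 6) * (1 / 5))
        assert cif_d.at(5) == pytest.approx(1 / 6 + (4 / 9) * (1 / 2))

    def test_conservation_sum_of_cifs_plus_event_free_is_one(self):
        rng = np.random.default_rng(21)
        outcomes = random_outcomes(rng, 200, tie_scale=1.0)
        cif_r = cif_aalen_johansen(outcomes, RELAPSE)
        cif_d = cif_aalen_johansen(outcomes, DEATH)
        ef = km_estimate(outcomes, event_def={RELAPSE, DEATH})
        total = cif_r.values + cif_d.values + ef.values
        assert np.abs(total - 1.0).max() < 1e-12

    def test_matches_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(13)
        outcomes = random_outcomes(rng, 120)  # continuous times, no ties
        cif = cif_aalen_johansen(outcomes, RELAPSE)
        codes = {CENSORED: 0, RELAPSE: 1, DEATH: 2}
        aj = AalenJohansenFitter(calculate_variance=False).fit(
            [o.time for o in outcomes],
            [codes[o.event] for o in outcomes],
            event_of_interest=1,
        )
        ours = {float(t): v for t, v in zip(cif.times, cif.values)}
        theirs = aj.cumulative_density_
        for t in [o.time for o in outcomes if o.event == RELAPSE]:
            assert ours[t] == pytest.approx(
                float(theirs.loc[t].iloc[0]), abs=1e-10
            )

    def test_unknown_cause_rejected(self):
        with pytest.raises(ValueError, match="cause"):
            cif_aalen_johansen(mk([(1, RELAPSE)]), "censored")


def breslow_partial_loglik(beta, rows):
    """Brute-force partial log-likelihood, binary covariate, no ties."""
    ll = 0.0
    for t, event, x in rows:
        if not event:
            continue
        risk = [xx for tt, _, xx in rows if tt >= t]
        ll += beta * x - np.log(sum(np.exp(beta * xx) for xx in risk))
    return ll


class TestCox:
    def test_matches_grid_maximization_single_binary_covariate(self):
        rng = np.random.default_rng(17)
        n = 60
        x = rng.integers(0, 2, n)
        t = rng.exponential(10 * np.exp(-0.7 * x))  # true log HR 0.7, no ties
        state = np.where(rng.random(n) < 0.75, RELAPSE, CENSORED)
        outcomes = [
            SubjectOutcome(f"S{i}", float(t[i]), str(state[i]), {"x": float(x[i])})
            for i in range(n)
        ]
        fit = cox_cause_specific(outcomes, RELAPSE, ["x"])
        rows = [(t[i], state[i] == RELAPSE, x[i]) for i in range(n)]
        grid = np.arange(-3, 3, 1e-4)
        lls = [breslow_partial_loglik(b, rows) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.terms["x"].coef == pytest.approx(best, abs=1e-4)
        assert fit.log_likelihood == pytest.approx(
            breslow_partial_loglik(fit.terms["x"].coef, rows), rel=1e-9
        )

    def test_null_covariate_hr_near_one_large_n(self):
        rng = np.random.default_rng(23)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(10, n)
        outcomes = [
            SubjectOutcome(f"S{i}", float(t[i]), RELAPSE, {"x": float(x[i])})
            for i in range(n)
        ]
        fit = cox_cause_specific(outcomes, RELAPSE, ["x"])
        assert abs(fit.terms["x"].coef) < 0.15
        lo, hi = fit.terms["x"].ci_low, fit.terms["x"].ci_high
        assert lo < fit.terms["x"].hr < hi

    def test_ci_and_hr_consistent_with_coef(self):
        rng = np.random.default_rng(29)
        outcomes = [
            SubjectOutcome(
                f"S{i}", float(rng.exponential(8)), RELAPSE if rng.random() < 0.7 else CENSORED,
                {"x": float(rng.normal())},
            )
            for i in range(150)
        ]
        term = cox_cause_specific(outcomes, RELAPSE, ["x"]).terms["x"]
        assert term.hr == pytest.approx(np.exp(term.coef))
        assert term.ci_low == pytest.approx(np.exp(term.coef - 1.96 * term.se))
        assert term.ci_high == pytest.approx(np.exp(term.coef + 1.96 * term.se))

    def test_competing_events_censored_at_their_time(self):
        """Cause-specific convention: recoding competing deaths as censorings
        must not change the relapse fit."""
        rng = np.random.default_rng(31)
        outcomes = random_outcomes(rng, 200, tie_scale=1.0)
        outcomes = [
            SubjectOutcome(o.subject_id, o.time, o.event, {"x": float(i % 2)})
            for i, o in enumerate(outcomes)
        ]
        recoded = [
            SubjectOutcome(
                o.subject_id, o.time, CENSORED if o.event == DEATH else o.event, o.covariates
            )
            for o in outcomes
        ]
        f1 = cox_cause_specific(outcomes, RELAPSE, ["x"])
        f2 = cox_cause_specific(recoded, RELAPSE, ["x"])
        assert f1.terms["x"].coef == pytest.approx(f2.terms["x"].coef, abs=1e-12)

    def test_monotone_likelihood_raises(self):
        # one event, binary covariate: partial likelihood maximized at infinity
        outcomes = [
            SubjectOutcome("S1", 1.0, RELAPSE, {"x": 1.0}),
            SubjectOutcome("S2", 2.0, CENSORED, {"x": 0.0}),
        ]
        with pytest.raises(CoxConvergenceError):
            cox_cause_specific(outcomes, RELAPSE, ["x"])

    def test_invalid_cause_and_ties(self):
        outcomes = mk([(1, RELAPSE), (2, DEATH)])
        with pytest.raises(ValueError, match="cause"):
            cox_cause_specific(outcomes, CENSORED, [])
        with pytest.raises(NotImplementedError):
            cox_cause_specific(outcomes, RELAPSE, [], ties="breslow")


class TestDesign:
    def test_reference_coding(self):
        df = pd.DataFrame(
            {"donor": ["MRD", "MUD", "Haplo"], "age": [1.0, 2.0, 3.0]}
        )
        design = build_design(df, ["donor", "age"], {"donor": ["MRD", "MUD", "Haplo"]})
        assert list(design.columns) == ["donor=MUD", "donor=Haplo", "age"]
        assert design["donor=MUD"].tolist() == [0.0, 1.0, 0.0]

    def test_undeclared_level_raises(self):
        df = pd.DataFrame({"donor": ["MRD", "MMUD"]})
        with pytest.raises(ValueError, match="MMUD"):
            build_design(df, ["donor"], {"donor": ["MRD", "MUD"]})

    def test_outcomes_frame_round_trip(self):
        outcomes = mk([(1, RELAPSE), (2, CENSORED)], group=["a", "b"])
        frame = outcomes_to_frame(outcomes)
        assert frame.loc["S0", "g"] == "a"
        assert frame.loc["S1", "event"] == CENSORED
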