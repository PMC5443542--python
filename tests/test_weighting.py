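import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oceanhealth.synthetic import GeneratorConfig, gen_survey
from oceanhealth.weighting import (
    ChoiceTask,
    SurveyResponse,
    UtilityVector,
    bw_rank_weights,
    compare_groups,
    dce_weights,
    equal_weights,
    fit_maxdiff_logit,
    likert_weights,
    normalize_weights,
    subgoal_weight_table,
)

GOALS10 = [f"g{i}" for i in range(10)]


class TestNormalizeWeights:
    def test_equal_raw_fixed_point(self):
        out = normalize_weights({g: 3.7 for g in GOALS10})
        assert all(w == pytest.approx(1.0) for w in out.values())

    def test_two_goal_hand_computation(self):
        out = normalize_weights({"a": 0.0, "b": 1.0})
        assert out["a"] == pytest.approx(2 / 3)
        assert out["b"] == pytest.approx(4 / 3)

    @given(
        raw=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=15,
        )
    )
    @settings(max_examples=200)
    def test_sum_equals_goal_count(self, raw):
        mapping = {f"g{i}": v for i, v in enumerate(raw)}
        out = normalize_weights(mapping)
        assert sum(out.values()) == pytest.approx(len(mapping))

    def test_order_of_steps_matters(self):
        # scale-then-shift would give a different answer than shift-then-scale
        out = normalize_weights({"a": 0.0, "b": 1.0})
        assert min(out.values()) < 1.0

    def test_empty(self):
        with pytest.raises(ValueError):
            normalize_weights({})

    def test_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            normalize_weights({"a": float("nan"), "b": 1.0})


class TestEqualWeights:
    def test_ten_goals(self):
        out = equal_weights(GOALS10)
        assert all(w == 1.0 for w in out.values())
        assert sum(out.values()) == 10

    def test_three_goals(self):
        assert equal_weights(["a", "b", "c"]) == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_zero_goals(self):
        with pytest.raises(ValueError):
            equal_weights([])


def respondent(rid, likert=None, tasks=()):
    return SurveyResponse(
        respondent_id=rid, likert=likert or {}, tasks=tuple(tasks)
    )


class TestLikertWeights:
    def test_constant_ratings(self):
        resp = [respondent(f"r{i}", {g: 5 for g in GOALS10}) for i in range(3)]
        out = likert_weights(resp)
        assert all(w == pytest.approx(1.0) for w in out.values())

    def test_two_goal_means(self):
        resp = [
            respondent("r0", {"a": 1, "b": 5}),
            respondent("r1", {"a": 3, "b": 3}),
        ]
        # means 2 and 4 -> shift to (1, 3) -> scale by 2/4 -> (0.5, 1.5)
        out = likert_weights(resp)
        assert out["a"] == pytest.approx(0.5)
        assert out["b"] == pytest.approx(1.5)

    def test_single_respondent(self):
        out = likert_weights([respondent("r0", {"a": 2, "b": 4})])
        assert out["a"] == pytest.approx(0.5)
        assert out["b"] == pytest.approx(1.5)

    def test_unrated_goal_error(self):
        resp = [respondent("r0", {"a": 3})]
        with pytest.raises(ValueError, match="without any"):
            likert_weights(resp, goals=["a", "b"])

    def test_invalid_rating(self):
        with pytest.raises(ValueError, match="1..5"):
            respondent("r0", {"a": 6})


class TestBwRankWeights:
    def test_dominant_goal_gets_largest_weight(self):
        tasks = [ChoiceTask(("a", "b", "c"), best="a", worst="c") for _ in range(4)]
        out = bw_rank_weights([respondent("r0", tasks=tasks)])
        assert out["a"] == max(out.values())
        assert out["c"] == min(out.values())

    def test_identical_counts_all_ones(self):
        tasks = [
            ChoiceTask(("a", "b", "c"), best="a", worst="b"),
            ChoiceTask(("a", "b", "c"), best="b", worst="a"),
        ]
        out = bw_rank_weights([respondent("r0", tasks=tasks)])
        assert all(w == pytest.approx(1.0) for w in out.values())

    def test_hand_computed_three_goal_case(self):
        # net counts (5, 0, -5) -> raw inverse ranks (3, 2, 1)
        tasks = [ChoiceTask(("a", "b", "c"), best="a", worst="c") for _ in range(5)]
        out = bw_rank_weights([respondent("r0", tasks=tasks)])
        # shift: min raw is 1 already -> scale 3/6
        assert out["a"] == pytest.approx(1.5)
        assert out["b"] == pytest.approx(1.0)
        assert out["c"] == pytest.approx(0.5)

    def test_no_tasks(self):
        with pytest.raises(ValueError, match="tasks"):
            bw_rank_weights([respondent("r0")])


def oracle_sequential_nll(utilities, tasks):
    """Independent plain-loop likelihood of best-then-worst choices."""
    total = 0.0
    for t in tasks:
        num = math.exp(utilities[t.best])
        den = sum(math.exp(utilities[g]) for g in t.shown)
        total -= math.log(num / den)
        rest = [g for g in t.shown if g != t.best]
        num_w = math.exp(-utilities[t.worst])
        den_w = sum(math.exp(-utilities[g]) for g in rest)
        total -= math.log(num_w / den_w)
    return total


class TestFitMaxdiffLogit:
    def test_uniform_choices_give_zero_utilities(self):
        config = GeneratorConfig(
            seed=3,
            n_respondents=300,
            true_utilities={g: 0.0 for g in GOALS10},
        )
        fit = fit_maxdiff_logit(gen_survey(config))
        for g in GOALS10:
            assert abs(fit.utilities[g]) < 3 * fit.std_errors[g] + 1e-9
            assert abs(fit.utilities[g]) < 0.2

    def test_parameter_recovery_within_three_se(self, recovery_fit):
        config, fit = recovery_fit
        truth = config.true_utilities
        center = np.mean(list(truth.values()))
        for g, u_hat in fit.utilities.items():
            assert abs(u_hat - (truth[g] - center)) < 3 * fit.std_errors[g]

    def test_sum_to_zero(self, recovery_fit):
        _, fit = recovery_fit
        assert sum(fit.utilities.values()) == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_grid_on_tiny_data(self):
        tasks = [
            ChoiceTask(("a", "b", "c"), "a", "c"),
            ChoiceTask(("a", "b", "c"), "a", "b"),
            ChoiceTask(("a", "b", "c"), "b", "c"),
            ChoiceTask(("a", "b", "c"), "a", "c"),
            ChoiceTask(("a", "b", "c"), "c", "b"),
            ChoiceTask(("a", "b", "c"), "a", "c"),
        ]
        fit = fit_maxdiff_logit(tasks)
        # coarse independent grid search over the sum-zero plane
        best_nll, best_u = math.inf, None
        grid = np.arange(-2.0, 2.0001, 0.01)
        for ua in grid:
            for ub in grid:
                u = {"a": ua, "b": ub, "c": -ua - ub}
                nll = oracle_sequential_nll(u, tasks)
                if nll < best_nll:
                    best_nll, best_u = nll, u
        for g in "abc":
            assert fit.utilities[g] == pytest.approx(best_u[g], abs=0.02)
        assert -fit.log_likelihood == pytest.approx(best_nll, abs=1e-3)

    def test_objective_history_non_increasing(self, recovery_fit):
        _, fit = recovery_fit
        history = np.asarray(fit.history)
        assert (np.diff(history) <= 1e-9).all()
        assert fit.grad_norm < 1e-6

    def test_goal_never_shown(self):
        tasks = [ChoiceTask(("a", "b", "c"), "a", "b")]
        resp = respondent("r0", likert={"d": 3}, tasks=tasks)
        # 'd' appears nowhere in tasks; the fit only sees shown goals
        fit = fit_maxdiff_logit([resp])
        assert set(fit.utilities) == {"a", "b", "c"}

    def test_shift_invariance_of_generated_choices(self):
        base = {g: u for g, u in zip(GOALS10, np.linspace(-1, 1, 10))}
        shifted = {g: u + 5.0 for g, u in base.items()}
        r1 = gen_survey(GeneratorConfig(seed=11, n_respondents=50, true_utilities=base))
        r2 = gen_survey(
            GeneratorConfig(seed=11, n_respondents=50, true_utilities=shifted)
        )
        assert [r.tasks for r in r1] == [r.tasks for r in r2]
        f1 = fit_maxdiff_logit(r1)
        f2 = fit_maxdiff_logit(r2)
        for g in GOALS10:
            assert f1.utilities[g] == pytest.approx(f2.utilities[g], abs=1e-6)

    def test_paired_model_runs(self):
        config = GeneratorConfig(seed=5, n_respondents=100)
        fit = fit_maxdiff_logit(gen_survey(config), model="paired")
        truth = config.true_utilities
        # same ordering of goals as the truth
        order_hat = sorted(truth, key=lambda g: fit.utilities[g])
        order_true = sorted(truth, key=lambda g: truth[g])
        top3 = set(order_true[-3:])
        assert len(top3 & set(order_hat[-3:])) >= 2

    def test_unknown_model(self):
        tasks = [ChoiceTask(("a", "b", "c"), "a", "b")]
        with pytest.raises(ValueError, match="model"):
            fit_maxdiff_logit(tasks, model="nested")


class TestDceWeights:
    def test_zero_utilities(self):
        fit = UtilityVector(
            utilities={g: 0.0 for g in GOALS10},
            std_errors={g: 0.1 for g in GOALS10},
            log_likelihood=0.0,
            n_iter=0,
            grad_norm=0.0,
        )
        out = dce_weights(fit)
        assert all(w == pytest.approx(1.0) for w in out.values())

    def test_dominant_goal_max_weight(self):
        utilities = {g: 0.0 for g in GOALS10}
        utilities["g3"] = 2.0
        utilities = {g: u - np.mean(list(utilities.values())) for g, u in utilities.items()}
        fit = UtilityVector(
            utilities=utilities, std_errors={g: 0.1 for g in GOALS10},
            log_likelihood=0.0, n_iter=0, grad_norm=0.0,
        )
        out = dce_weights(fit)
        assert max(out, key=out.get) == "g3"

    def test_spread_exceeds_likert_on_heterogeneous_population(self):
        # strongly heterogeneous preferences: the bounded 1-5 likert scale
        # saturates at the extremes while the logit utilities do not
        utilities = {g: u for g, u in zip(GOALS10, np.linspace(-2.5, 2.5, 10))}
        config = GeneratorConfig(
            seed=21, n_respondents=400, true_utilities=utilities
        )
        responses = gen_survey(config)
        dce = dce_weights(fit_maxdiff_logit(responses))
        lik = likert_weights(responses)
        spread = lambda w: max(w.values()) - min(w.values())
        assert spread(dce) >= spread(lik)


class TestSubgoalWeightTable:
    STRUCTURE = {"FP": ("FIS", "MAR"), "BD": ("HAB", "SPP"), "CW": ()}

    def test_equal_split_default(self):
        out = subgoal_weight_table(self.STRUCTURE, {"FIS": 1, "MAR": 1})
        assert out["BD"] == {"HAB": 0.5, "SPP": 0.5}

    def test_fp_yield_proportions(self):
        out = subgoal_weight_table(self.STRUCTURE, {"FIS": 85.0, "MAR": 15.0})
        assert out["FP"]["FIS"] == pytest.approx(0.85)
        assert out["FP"]["MAR"] == pytest.approx(0.15)

    def test_missing_yields(self):
        with pytest.raises(ValueError, match="yield"):
            subgoal_weight_table(self.STRUCTURE, None)

    def test_invalid_yields(self):
        with pytest.raises(ValueError):
            subgoal_weight_table(self.STRUCTURE, {"FIS": -1.0, "MAR": 2.0})

    def test_goals_without_subgoals_omitted(self):
        out = subgoal_weight_table(self.STRUCTURE, {"FIS": 1, "MAR": 1})
        assert "CW" not in out


GOALS3 = ("x", "y", "z")
SCORES3 = {"x": 90.0, "y": 50.0, "z": 10.0}


def grouped_survey(group_utilities, n=30, seed=0):
    responses = []
    for g_i, (label, utilities) in enumerate(sorted(group_utilities.items())):
        config = GeneratorConfig(
            seed=seed + 1000 * g_i,
            n_respondents=n,
            tasks_per_respondent=4,
            set_size=3,
            true_utilities=utilities,
        )
        for r in gen_survey(config, demographics={"region": label}):
            responses.append(
                SurveyResponse(
                    respondent_id=f"{label}-{r.respondent_id}",
                    demographics=r.demographics,
                    likert=r.likert,
                    tasks=r.tasks,
                )
            )
    return responses


class TestCompareGroups:
    def test_identical_groups_share_letter(self):
        utilities = {"x": 0.3, "y": 0.0, "z": -0.3}
        responses = grouped_survey({"A": utilities, "B": utilities}, n=25, seed=2)
        out = compare_groups(
            responses, "region", SCORES3, n_sims=120, seed=9
        )
        assert set(out.letters["A"]) & set(out.letters["B"])
        assert not out.different.loc["A", "B"]

    def test_engineered_separation_gets_distinct_letters(self):
        responses = grouped_survey(
            {
                "A": {"x": 1.5, "y": 0.0, "z": -1.5},
                "B": {"x": -1.5, "y": 0.0, "z": 1.5},
            },
            n=30,
            seed=4,
        )
        out = compare_groups(responses, "region", SCORES3, n_sims=500, seed=10)
        assert out.indices["A"] - out.indices["B"] > 5.0
        assert not (set(out.letters["A"]) & set(out.letters["B"]))
        assert out.different.loc["A", "B"]

    def test_proportion_method_runs(self):
        responses = grouped_survey(
            {
                "A": {"x": 1.5, "y": 0.0, "z": -1.5},
                "B": {"x": -1.5, "y": 0.0, "z": 1.5},
            },
            n=25,
            seed=6,
        )
        out = compare_groups(
            responses, "region", SCORES3, n_sims=120, seed=3, method="proportion"
        )
        assert out.different.loc["A", "B"]

    def test_deterministic_given_seed(self):
        utilities = {"x": 0.5, "y": 0.0, "z": -0.5}
        responses = grouped_survey({"A": utilities, "B": utilities}, n=20, seed=8)
        a = compare_groups(responses, "region", SCORES3, n_sims=50, seed=77)
        b = compare_groups(responses, "region", SCORES3, n_sims=50, seed=77)
        for g in ("A", "B"):
            assert np.array_equal(a.bootstrap[g], b.bootstrap[g])
        assert a.letters == b.letters

    def test_zero_sims_error(self):
        responses = grouped_survey(
            {"A": {"x": 0.1, "y": 0.0, "z": -0.1}, "B": {"x": 0.1, "y": 0.0, "z": -0.1}},
            n=5,
        )
        with pytest.raises(ValueError, match="n_sims"):
            compare_groups(responses, "region", SCORES3, n_sims=0)

    def test_small_group_error(self):
        responses = grouped_survey(
            {"A": {"x": 0.1, "y": 0.0, "z": -0.1}, "B": {"x": 0.1, "y": 0.0, "z": -0.1}},
            n=5,
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(responses[:6], "region", SCORES3, n_sims=10)

    def test_missing_demographic(self):
        responses = grouped_survey(
            {"A": {"x": 0.1, "y": 0.0, "z": -0.1}, "B": {"x": 0.1, "y": 0.0, "z": -0.1}},
            n=5,
        )
        with pytest.raises(ValueError, match="lacks demographic"):
            compare_groups(responses, "party", SCORES3, n_sims=10)


class TestChoiceTaskValidation:
    def test_best_equals_worst(self):
        with pytest.raises(ValueError, match="differ"):
            ChoiceTask(("a", "b", "c"), "a", "a")

    def test_best_not_shown(self):
        with pytest.raises(ValueError, match="shown"):
            ChoiceTask(("a", "b", "c"), "d", "a")

    def test_too_small_set(self):
        with pytest.raises(ValueError, match="at least 3"):
            ChoiceTask(("a", "b"), "a", "b")
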