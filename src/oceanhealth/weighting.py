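"""Survey-derived goal weights and group comparison.

Four schemes turn survey responses into goal weights:

* ``equal``   — every goal weighted 1;
* ``likert``  — mean importance rating per goal, normalized;
* ``bw-rank`` — inverse ranks of net best-minus-worst counts, normalized;
* ``bw-dce``  — coefficients of a best-worst (maxdiff) conditional logit,
  normalized.

Normalization is shift-then-scale: add a constant so the minimum raw value is
1, then scale so the weights sum to the number of goals.  The Monte-Carlo
group comparison bootstraps respondents within groups, refits bw-dce weights,
recomputes the overall index, and assigns compact letters: groups sharing a
letter are not distinguishable at the 5 % level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .core import GoalParameters, aggregate_index

__all__ = [
    "ChoiceTask",
    "SurveyResponse",
    "UtilityVector",
    "GroupComparison",
    "equal_weights",
    "likert_weights",
    "bw_rank_weights",
    "fit_maxdiff_logit",
    "dce_weights",
    "normalize_weights",
    "subgoal_weight_table",
    "compare_groups",
]


@dataclass(frozen=True)
class ChoiceTask:
    """One best-worst task: the shown set plus the best and worst picks."""

    shown: tuple[str, ...]
    best: str
    worst: str

    def __post_init__(self) -> None:
        if len(set(self.shown)) < 3:
            raise ValueError("a task must show at least 3 distinct goals")
        if self.best not in self.shown or self.worst not in self.shown:
            raise ValueError("best and worst must be among the shown goals")
        if self.best == self.worst:
            raise ValueError("best and worst must differ")


@dataclass(frozen=True)
class SurveyResponse:
    """One respondent: demographics, Likert ratings and best-worst tasks."""

    respondent_id: str
    demographics: Mapping[str, str] = field(default_factory=dict)
    likert: Mapping[str, int] = field(default_factory=dict)
    tasks: tuple[ChoiceTask, ...] = ()

    def __post_init__(self) -> None:
        for goal, rating in self.likert.items():
            if rating not in (1, 2, 3, 4, 5):
                raise ValueError(
                    f"likert rating for {goal!r} must be in 1..5, got {rating!r}"
                )


@dataclass(frozen=True)
class UtilityVector:
    """Fitted maxdiff utilities (sum-to-zero identified) and diagnostics."""

    utilities: dict[str, float]
    std_errors: dict[str, float]
    log_likelihood: float
    n_iter: int
    grad_norm: float
    history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.utilities.values())
        if abs(total) > 1e-6:
            raise ValueError(f"utilities must sum to 0, got {total!r}")


def _collect_tasks(
    responses: Iterable[SurveyResponse | ChoiceTask],
) -> list[ChoiceTask]:
    tasks: list[ChoiceTask] = []
    for item in responses:
        if isinstance(item, ChoiceTask):
            tasks.append(item)
        else:
            tasks.extend(item.tasks)
    return tasks


def normalize_weights(raw: Mapping[str, float]) -> dict[str, float]:
    """Shift so the minimum is 1, then scale so the sum equals the goal count.

    The steps do not commute; shift happens first.  The post-scale minimum is
    generally below 1 — only equal raw values map to all-ones.
    """
    if not raw:
        raise ValueError("need at least one goal")
    values = np.asarray(list(raw.values()), dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("raw weight values must be finite")
    shifted = values + (1.0 - values.min())
    scaled = shifted * (len(values) / shifted.sum())
    return {g: float(w) for g, w in zip(raw.keys(), scaled)}


def equal_weights(goals: Sequence[str]) -> dict[str, float]:
    """Every goal weighted exactly 1."""
    if len(goals) == 0:
        raise ValueError("need at least one goal")
    return {g: 1.0 for g in goals}


def likert_weights(
    responses: Sequence[SurveyResponse], goals: Sequence[str] | None = None
) -> dict[str, float]:
    """Mean Likert rating per goal across respondents, normalized.

    If ``goals`` is given, every listed goal must carry at least one rating.
    """
    ratings: dict[str, list[int]] = {}
    for resp in responses:
        for goal, rating in resp.likert.items():
            ratings.setdefault(goal, []).append(rating)
    if not ratings:
        raise ValueError("no Likert ratings in responses")
    if goals is not None:
        unrated = sorted(set(goals) - set(ratings))
        if unrated:
            raise ValueError(f"goals without any Likert rating: {unrated}")
        ratings = {g: ratings[g] for g in goals}
    means = {g: float(np.mean(v)) for g, v in sorted(ratings.items())}
    return normalize_weights(means)


def bw_rank_weights(responses: Sequence[SurveyResponse | ChoiceTask]) -> dict[str, float]:
    """Inverse-rank weights from pooled net best-minus-worst counts.

    Ties share their average rank, so goals with identical counts receive
    identical weights (and all-identical counts normalize to all ones).
    """
    tasks = _collect_tasks(responses)
    if not tasks:
        raise ValueError("no choice tasks in responses")
    net: dict[str, int] = {}
    for task in tasks:
        for goal in task.shown:
            net.setdefault(goal, 0)
        net[task.best] += 1
        net[task.worst] -= 1
    goals = sorted(net)
    counts = np.asarray([net[g] for g in goals], dtype=float)
    ranks = rankdata(-counts, method="average")  # rank 1 = largest net count
    raw = len(goals) + 1.0 - ranks
    return normalize_weights({g: float(r) for g, r in zip(goals, raw)})


def _index_tasks(
    tasks: Sequence[ChoiceTask], goals: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad tasks into (shown_idx, shown_mask, best_idx, worst_idx) arrays."""
    gidx = {g: i for i, g in enumerate(goals)}
    m = max(len(t.shown) for t in tasks)
    shown = np.zeros((len(tasks), m), dtype=np.int64)
    mask = np.zeros((len(tasks), m), dtype=bool)
    best = np.empty(len(tasks), dtype=np.int64)
    worst = np.empty(len(tasks), dtype=np.int64)
    for i, t in enumerate(tasks):
        idx = [gidx[g] for g in t.shown]
        shown[i, : len(idx)] = idx
        mask[i, : len(idx)] = True
        best[i] = gidx[t.best]
        worst[i] = gidx[t.worst]
    return shown, mask, best, worst


def _sequential_nll_grad(
    u: np.ndarray,
    shown: np.ndarray,
    mask: np.ndarray,
    best: np.ndarray,
    worst: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood of best-then-worst choices and its u-gradient."""
    neg_inf = -np.inf
    U = np.where(mask, u[shown], neg_inf)
    lse_best = logsumexp(U, axis=1)
    # worst stage: -u over the shown set with the best item removed
    is_best = shown == best[:, None]
    V = np.where(mask & ~is_best, -u[shown], neg_inf)
    lse_worst = logsumexp(V, axis=1)
    nll = float((-u[best] + lse_best + u[worst] + lse_worst).sum())

    grad = np.zeros_like(u)
    p_best = np.exp(U - lse_best[:, None])  # masked entries -> exp(-inf) = 0
    p_worst = np.exp(V - lse_worst[:, None])
    np.add.at(grad, shown, p_best - p_worst)
    np.add.at(grad, best, -1.0)
    np.add.at(grad, worst, 1.0)
    return nll, grad


def _paired_nll_grad(
    u: np.ndarray,
    shown: np.ndarray,
    mask: np.ndarray,
    best: np.ndarray,
    worst: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Paired variant: P(b, w | S) proportional to exp(u_b - u_w) over ordered pairs."""
    nll = 0.0
    grad = np.zeros_like(u)
    for i in range(shown.shape[0]):
        idx = shown[i, mask[i]]
        diffs = u[idx][:, None] - u[idx][None, :]
        np.fill_diagonal(diffs, -np.inf)
        lse = logsumexp(diffs)
        nll += -(u[best[i]] - u[worst[i]]) + lse
        p = np.exp(diffs - lse)
        grad[idx] += p.sum(axis=1) - p.sum(axis=0)
        grad[best[i]] -= 1.0
        grad[worst[i]] += 1.0
    return float(nll), grad


def fit_maxdiff_logit(
    responses: Sequence[SurveyResponse | ChoiceTask],
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    model: str = "sequential",
) -> UtilityVector:
    """Maximum-likelihood utilities from best-worst tasks.

    The likelihood is convex and the fit deterministic (``seed`` is accepted
    for interface parity only).  Utilities are identified by a sum-to-zero
    constraint; standard errors come from the observed information.
    """
    tasks = _collect_tasks(responses)
    if not tasks:
        raise ValueError("no choice tasks in responses")
    goals = sorted({g for t in tasks for g in t.shown})
    n = len(goals)
    shown, mask, best, worst = _index_tasks(tasks, goals)
    seen = np.zeros(n, dtype=bool)
    seen[np.unique(shown[mask])] = True
    if not seen.all():
        missing = [goals[i] for i in np.flatnonzero(~seen)]
        raise ValueError(f"goals never shown in any task: {missing}")
    nll_grad = {"sequential": _sequential_nll_grad, "paired": _paired_nll_grad}.get(model)
    if nll_grad is None:
        raise ValueError(f"unknown model {model!r}; use 'sequential' or 'paired'")

    # sum-to-zero reduction: u = A @ theta with theta in R^(n-1)
    A = np.vstack([np.eye(n - 1), -np.ones((1, n - 1))])

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        nll, g = nll_grad(A @ theta, shown, mask, best, worst)
        return nll, A.T @ g

    history: list[float] = []

    def callback(theta: np.ndarray) -> None:
        history.append(objective(theta)[0])

    theta0 = np.zeros(n - 1)
    history.append(objective(theta0)[0])
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="BFGS",
        callback=callback,
        options={"gtol": tol, "maxiter": max_iter},
    )
    theta = res.x
    # Newton polish: BFGS stalls above very tight gradient tolerances, and
    # near the optimum the NLL changes by less than an ulp, so acceptance is
    # judged on the gradient norm.
    for _ in range(20):
        nll, g = objective(theta)
        gnorm = np.linalg.norm(g, np.inf)
        if gnorm < tol:
            break
        H = _fd_hessian(lambda t: objective(t)[1], theta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        candidate = theta - step
        nll_c, g_c = objective(candidate)
        if nll_c <= nll or np.linalg.norm(g_c, np.inf) < gnorm:
            theta = candidate
            history.append(min(nll_c, nll))
        else:
            break
    nll, g = objective(theta)
    grad_norm = float(np.linalg.norm(g, np.inf))
    if grad_norm >= max(tol, 1e-6):
        raise RuntimeError(
            f"maxdiff fit did not converge: |grad| = {grad_norm:.3g} after "
            f"{res.nit} BFGS iterations (message: {res.message})"
        )
    H = _fd_hessian(lambda t: objective(t)[1], theta)
    cov_theta = np.linalg.pinv(H)
    cov_u = A @ cov_theta @ A.T
    se = np.sqrt(np.clip(np.diag(cov_u), 0.0, None))
    u = A @ theta
    return UtilityVector(
        utilities={g_: float(v) for g_, v in zip(goals, u)},
        std_errors={g_: float(s) for g_, s in zip(goals, se)},
        log_likelihood=float(-nll),
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        history=tuple(history),
    )


def _fd_hessian(grad_fn, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = step
        H[:, j] = (grad_fn(theta + e) - grad_fn(theta - e)) / (2.0 * step)
    return (H + H.T) / 2.0


def dce_weights(utilities: UtilityVector) -> dict[str, float]:
    """Normalized weights from fitted maxdiff coefficients."""
    return normalize_weights(utilities.utilities)


def subgoal_weight_table(
    goal_structure: Mapping[str, Sequence[str]],
    fp_yield_weights: Mapping[str, float] | None = None,
    fp_goal: str = "FP",
) -> dict[str, dict[str, float]]:
    """Per-subgoal weights: equal shares everywhere, yield shares for FP."""
    table: dict[str, dict[str, float]] = {}
    for goal, subgoals in goal_structure.items():
        if not subgoals:
            continue
        if goal == fp_goal and len(subgoals) > 1:
            if fp_yield_weights is None:
                raise ValueError(f"{fp_goal} requires yield weights for its subgoals")
            yields = np.asarray(
                [fp_yield_weights.get(s, -1.0) for s in subgoals], dtype=float
            )
            if (yields < 0).any() or yields.sum() <= 0:
                raise ValueError(
                    f"yield weights must be nonnegative with positive sum and "
                    f"cover all of {list(subgoals)}"
                )
            table[goal] = {
                s: float(y / yields.sum()) for s, y in zip(subgoals, yields)
            }
        else:
            table[goal] = {s: 1.0 / len(subgoals) for s in subgoals}
    return table


@dataclass(frozen=True)
class GroupComparison:
    """Per-group index estimates, bootstrap draws, and letter assignment."""

    indices: dict[str, float]
    letters: dict[str, str]
    different: pd.DataFrame  # boolean, groups x groups
    bootstrap: dict[str, np.ndarray]


def _letters_from_graph(groups: Sequence[str], different: pd.DataFrame) -> dict[str, str]:
    """Compact letter display: letters are maximal cliques of the
    not-different graph, so two groups share a letter iff not different."""
    remaining_edges = {
        frozenset((a, b))
        for i, a in enumerate(groups)
        for b in groups[i + 1 :]
        if not different.loc[a, b]
    }
    cliques: list[set[str]] = []
    # greedy maximal-clique cover of the not-different graph (small n)
    covered: set[frozenset] = set()
    for a in groups:
        clique = {a}
        for b in groups:
            if b in clique:
                continue
            if all(frozenset((b, c)) in remaining_edges for c in clique):
                clique.add(b)
        if not any(clique <= c for c in cliques):
            cliques.append(clique)
            covered |= {
                frozenset((x, y)) for x in clique for y in clique if x != y
            }
    for edge in remaining_edges - covered:
        cliques.append(set(edge))
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    labels: dict[str, list[str]] = {g: [] for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            labels[g].append(letter)
    return {g: "".join(sorted(v)) for g, v in labels.items()}


def compare_groups(
    responses: Sequence[SurveyResponse],
    grouping_key: str,
    goal_scores: Mapping[str, float],
    n_sims: int = 500,
    seed: int | None = None,
    method: str = "interval",
    precision: float = 0.005,
    params: GoalParameters = GoalParameters(),
) -> GroupComparison:
    """Bootstrap comparison of the overall index across respondent groups.

    Within each group, respondents are resampled with replacement, bw-dce
    weights refit, and the index recomputed, ``n_sims`` times.  With
    ``method="interval"`` two groups differ when the 95 % percentile interval
    of their index difference excludes 0; ``method="proportion"`` flags a
    difference when the indices differ beyond ``precision`` in at least 95 %
    of simulations.
    """
    if n_sims <= 0:
        raise ValueError(f"n_sims must be > 0, got {n_sims!r}")
    if method not in ("interval", "proportion"):
        raise ValueError(f"unknown method {method!r}")
    by_group: dict[str, list[SurveyResponse]] = {}
    for resp in responses:
        try:
            group = resp.demographics[grouping_key]
        except KeyError:
            raise ValueError(
                f"respondent {resp.respondent_id!r} lacks demographic "
                f"{grouping_key!r}"
            ) from None
        by_group.setdefault(group, []).append(resp)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups to compare")
    for group, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 respondents")

    rng = np.random.default_rng(seed)
    groups = sorted(by_group)

    def group_index(members: Sequence[SurveyResponse]) -> float:
        weights = dce_weights(fit_maxdiff_logit(members))
        return aggregate_index(goal_scores, weights, params)

    indices = {g: group_index(by_group[g]) for g in groups}
    boot: dict[str, np.ndarray] = {}
    for g in groups:
        members = by_group[g]
        draws = np.empty(n_sims)
        for s in range(n_sims):
            sample = [members[i] for i in rng.integers(0, len(members), len(members))]
            draws[s] = group_index(sample)
        boot[g] = draws

    different = pd.DataFrame(False, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            diff = boot[a] - boot[b]
            if method == "interval":
                lo, hi = np.percentile(diff, [2.5, 97.5])
                flag = not (lo <= 0.0 <= hi)
            else:
                flag = float(np.mean(np.abs(diff) > precision)) >= 0.95
            different.loc[a, b] = different.loc[b, a] = flag
    letters = _letters_from_graph(groups, different)
    return GroupComparison(
        indices=indices, letters=letters, different=different, bootstrap=boot
    )
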