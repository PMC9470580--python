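"""Target-centric analyses of a fitted tree network.

Covers tornado sensitivity (single-evidence posterior deltas), dynamic
profiling (greedy hard-evidence accumulation with Bayes factors),
optimization-tree enumeration of evidence paths, segment profiles
(normalized conditional means with frequentist and Bayesian two-group
tests) and the target-evaluation performance report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.metrics import roc_auc_score

from .bayesnet import (TreeNetwork, evidence_probability, model_marginal, posterior)
from .discretize import DiscreteTable

__all__ = [
    "tornado",
    "DynamicProfileStep",
    "dynamic_profile",
    "bayes_rule_posterior",
    "bayes_factor",
    "generalized_bayes_factor",
    "optimization_tree",
    "EvidencePath",
    "segment_profile",
    "best_two_group",
    "evaluate_target",
    "classification_report",
    "PerformanceReport",
]


# ---------------------------------------------------------------------------
# tornado sensitivity
# ---------------------------------------------------------------------------

def tornado(network: TreeNetwork, target: str, target_state: int) -> pd.DataFrame:
    """Single-evidence sensitivity of one target state.

    For every other node and each of its states, hard evidence is placed
    on that state and the posterior of ``target_state`` recorded along
    with its delta against the prior.  Sorted by |delta| descending
    (strongest influences first).  Evidence with zero model probability
    is skipped with a warning.
    """
    prior = model_marginal(network, target)[target_state]
    rows = []
    for v in network.nodes:
        if v == target:
            continue
        for s in range(network.n_states(v)):
            try:
                post = posterior(network, {v: s}, target)[target_state]
            except ValueError:
                warnings.warn(f"impossible evidence skipped: {v}={s}", stacklevel=2)
                continue
            rows.append({"node": v, "state": network.states[v][s],
                         "posterior": float(post), "delta": float(post - prior)})
    out = pd.DataFrame(rows, columns=["node", "state", "posterior", "delta"])
    out["abs_delta"] = out["delta"].abs()
    out = out.sort_values(["abs_delta", "node", "state"],
                          ascending=[False, True, True],
                          kind="mergesort").drop(columns="abs_delta")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# dynamic profiling
# ---------------------------------------------------------------------------

def bayes_rule_posterior(likelihood: float, prior: float, marginal: float) -> float:
    """P(s|H) = P(H|s) * P(s) / P(H); all arguments on the same scale."""
    if marginal <= 0:
        raise ValueError("marginal likelihood must be positive")
    return likelihood * prior / marginal


def bayes_factor(posterior_prob: float, prior_prob: float) -> float:
    """BF(s, H) = P(s|H) / P(s)."""
    if prior_prob <= 0:
        raise ValueError("prior probability must be positive")
    return posterior_prob / prior_prob


def generalized_bayes_factor(posterior_prob: float, prior_prob: float) -> float:
    """Posterior odds over prior odds of the target state."""
    if not (0 < prior_prob < 1):
        raise ValueError("prior probability must be in (0, 1)")
    if posterior_prob >= 1.0:
        return np.inf
    post_odds = posterior_prob / (1.0 - posterior_prob)
    prior_odds = prior_prob / (1.0 - prior_prob)
    return post_odds / prior_odds


@dataclass(frozen=True)
class DynamicProfileStep:
    """One step of the greedy evidence search.

    Probabilities satisfy Bayes' rule P(s|H) P(H) = P(H|s) P(s); the
    prior/posterior means are state-probability-weighted conditional
    means of each continuous node, in feature units.
    """

    evidence: dict[str, int]
    node: str | None
    state_label: str | None
    posterior_prob: float        # P(s | H)
    marginal_likelihood: float   # P(H)
    likelihood: float            # P(H | s)
    bayes_factor: float
    generalized_bayes_factor: float
    means: dict[str, float] = field(default_factory=dict)


def _posterior_means(network: TreeNetwork, evidence: dict[str, int],
                     discrete: DiscreteTable | None) -> dict[str, float]:
    if discrete is None or not discrete.conditional_means:
        return {}
    means = {}
    for v in network.nodes:
        cm = discrete.conditional_means.get(v)
        if cm is None:
            continue
        if v in evidence:
            means[v] = float(cm[evidence[v]])
        else:
            dist = posterior(network, {k: s for k, s in evidence.items() if k != v}, v) \
                if evidence else model_marginal(network, v)
            means[v] = float((dist * cm).sum())
    return means


def dynamic_profile(network: TreeNetwork, target: str, target_state: int,
                    discrete: DiscreteTable | None = None,
                    max_steps: int | None = None) -> list[DynamicProfileStep]:
    """Greedy hard-evidence search maximizing P(target_state | evidence).

    Step 0 is the a-priori row (no evidence, BF = 1).  Each subsequent
    step adds the single (node, state) hard evidence that maximizes the
    target state's posterior, stopping when no strict improvement remains
    or after ``max_steps`` additions.  The greedy posterior sequence is
    non-decreasing by construction.
    """
    prior = float(model_marginal(network, target)[target_state])
    steps = [DynamicProfileStep(
        evidence={}, node=None, state_label=None, posterior_prob=prior,
        marginal_likelihood=1.0, likelihood=1.0, bayes_factor=1.0,
        generalized_bayes_factor=1.0,
        means=_posterior_means(network, {}, discrete))]
    evidence: dict[str, int] = {}
    current = prior
    limit = max_steps if max_steps is not None else len(network.nodes) - 1
    for _ in range(limit):
        best = None
        for v in sorted(network.nodes):
            if v == target or v in evidence:
                continue
            for s in range(network.n_states(v)):
                trial = {**evidence, v: s}
                p_h = evidence_probability(network, trial)
                if p_h <= 0:
                    continue
                post = float(posterior(network, trial, target)[target_state])
                if best is None or post > best[0] + 1e-15:
                    best = (post, v, s, p_h)
        if best is None or best[0] <= current + 1e-12:
            break
        post, v, s, p_h = best
        evidence = {**evidence, v: s}
        current = post
        likelihood = p_h * post / prior
        steps.append(DynamicProfileStep(
            evidence=dict(evidence), node=v, state_label=network.states[v][s],
            posterior_prob=post, marginal_likelihood=p_h, likelihood=likelihood,
            bayes_factor=bayes_factor(post, prior),
            generalized_bayes_factor=generalized_bayes_factor(post, prior),
            means=_posterior_means(network, evidence, discrete)))
    return steps


# ---------------------------------------------------------------------------
# optimization tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvidencePath:
    """A hard-evidence sequence reaching the target-state threshold."""

    evidence: tuple[tuple[str, int], ...]
    posterior_prob: float


def optimization_tree(network: TreeNetwork, target: str, target_state: int,
                      threshold: float, max_depth: int = 3) -> list[EvidencePath]:
    """Enumerate evidence combinations driving the target state past a
    threshold.

    Depth-first search over hard-evidence assignments on non-target nodes
    (bounded by ``max_depth`` pieces of evidence, nodes taken in
    lexicographic order so each combination appears once); a path is
    reported when P(target_state | evidence) >= threshold.  The empty
    path qualifies when the prior already meets the threshold.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    nodes = sorted(v for v in network.nodes if v != target)
    paths: list[EvidencePath] = []

    def post_of(evidence: dict[str, int]) -> float | None:
        if evidence and evidence_probability(network, evidence) <= 0:
            return None
        return float(posterior(network, evidence, target)[target_state])

    prior = post_of({})
    if prior is not None and prior >= threshold:
        paths.append(EvidencePath(evidence=(), posterior_prob=prior))

    def dfs(start: int, evidence: dict[str, int]):
        if len(evidence) >= max_depth:
            return
        for i in range(start, len(nodes)):
            v = nodes[i]
            for s in range(network.n_states(v)):
                trial = {**evidence, v: s}
                post = post_of(trial)
                if post is None:
                    continue
                if post >= threshold:
                    paths.append(EvidencePath(
                        evidence=tuple(sorted(trial.items())), posterior_prob=post))
                dfs(i + 1, trial)

    dfs(0, {})
    paths.sort(key=lambda p: (-p.posterior_prob, p.evidence))
    return paths


# ---------------------------------------------------------------------------
# segment profiles
# ---------------------------------------------------------------------------

def _log_t(y: np.ndarray, mu: float, sigma: float, nu: float) -> float:
    z = (y - mu) / sigma
    return float((gammaln((nu + 1) / 2) - gammaln(nu / 2)
                  - 0.5 * np.log(nu * np.pi) - np.log(sigma)
                  - (nu + 1) / 2 * np.log1p(z * z / nu)).sum())


def _hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    draws = np.sort(draws)
    n = draws.size
    m = max(int(np.floor(mass * n)), 1)
    widths = draws[m:] - draws[:n - m]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + m])


def best_two_group(y1, y2, seed: int = 0, n_samples: int = 20_000,
                   hdi_mass: float = 0.95) -> dict:
    """Bayesian two-group comparison with Student-t likelihoods.

    The Kruschke-style model: each group has its own mean and scale with
    a shared normality parameter; means have very broad normal priors
    (pooled mean, 1000x pooled sd), scales uniform priors over
    (pooled sd/1000, pooled sd*1000) and normality a shifted
    exponential(29)+1.  Sampled with a seeded random-walk Metropolis
    chain (50% burn-in).  The difference of means is judged credibly
    non-zero when its HDI excludes 0.

    Returns dict with keys ``mean_diff``, ``hdi``, ``significant``,
    ``acceptance_rate``.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    pooled = np.concatenate([y1, y2])
    m0, s0 = float(pooled.mean()), float(pooled.std(ddof=1))
    if s0 == 0:
        s0 = 1e-9
    lo_s, hi_s = s0 / 1000.0, s0 * 1000.0
    rng = np.random.default_rng(seed)

    def log_post(theta) -> float:
        mu1, mu2, s1, s2, nu = theta
        if not (lo_s < s1 < hi_s and lo_s < s2 < hi_s and nu > 1.0):
            return -np.inf
        lp = (-0.5 * ((mu1 - m0) / (1000 * s0)) ** 2
              - 0.5 * ((mu2 - m0) / (1000 * s0)) ** 2
              - (nu - 1.0) / 29.0)
        return lp + _log_t(y1, mu1, s1, nu) + _log_t(y2, mu2, s2, nu)

    theta = np.array([float(y1.mean()), float(y2.mean()),
                      max(float(y1.std(ddof=1)), lo_s * 2),
                      max(float(y2.std(ddof=1)), lo_s * 2), 10.0])
    scales = np.array([s0 / np.sqrt(max(y1.size, 2)), s0 / np.sqrt(max(y2.size, 2)),
                       s0 * 0.1, s0 * 0.1, 4.0])
    lp = log_post(theta)
    draws = np.empty((n_samples, 5))
    accepted = 0
    for i in range(n_samples):
        prop = theta + scales * rng.standard_normal(5)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
        draws[i] = theta
    kept = draws[n_samples // 2:]
    diff = kept[:, 0] - kept[:, 1]
    lo, hi = _hdi(diff, hdi_mass)
    return {"mean_diff": float(diff.mean()), "hdi": (lo, hi),
            "significant": bool(lo > 0 or hi < 0),
            "acceptance_rate": accepted / n_samples}


def segment_profile(features: pd.DataFrame, target_states: np.ndarray,
                    state_labels: list[str], target: str | None = None,
                    label_col: str = "class", seed: int = 0,
                    best_samples: int = 20_000, alpha: float = 0.05) -> pd.DataFrame:
    """Per-state radar-chart data with two-group significance tests.

    For each target state and feature: the normalized conditional mean
    (mean within the state, min-max scaled by the feature's global range),
    a two-tailed Welch t test of state-vs-rest, and the Bayesian
    two-group test (significant when the 95% HDI of the mean difference
    excludes 0).  States with fewer than 2 rows have their tests skipped
    and flagged.
    """
    target_states = np.asarray(target_states)
    feats = [c for c in features.columns
             if c != label_col and c != target and features[c].dtype.kind in "fiu"]
    rows = []
    for s, label in enumerate(state_labels):
        sel = target_states == s
        for fi, feat in enumerate(feats):
            vals = features[feat].to_numpy(dtype=float)
            lo, hi = vals.min(), vals.max()
            span = hi - lo if hi > lo else 1.0
            inside, outside = vals[sel], vals[~sel]
            row = {"state": label, "feature": feat,
                   "normalized_mean": float((inside.mean() - lo) / span) if sel.any() else np.nan,
                   "t_test_significant": False, "best_significant": False,
                   "hdi_low": np.nan, "hdi_high": np.nan, "tested": False}
            if inside.size >= 2 and outside.size >= 2:
                t = stats.ttest_ind(inside, outside, equal_var=False)
                best = best_two_group(inside, outside,
                                      seed=(seed * 1_000_003 + s * 131 + fi) % (2 ** 31),
                                      n_samples=best_samples)
                row.update({"t_test_significant": bool(t.pvalue < alpha),
                            "best_significant": best["significant"],
                            "hdi_low": best["hdi"][0], "hdi_high": best["hdi"][1],
                            "tested": True})
            else:
                warnings.warn(f"state {label!r} has <2 rows; tests skipped", stacklevel=2)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target evaluation
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    """Per-state classification metrics plus global numeric fit."""

    per_state: pd.DataFrame
    r: float
    r2: float
    rmse: float
    nrmse: float
    confusion: np.ndarray


def classification_report(actual: np.ndarray, predicted: np.ndarray,
                          state_labels: list[str],
                          scores: np.ndarray | None = None) -> pd.DataFrame:
    """Per-state occurrence, reliability, precision, purity, neighborhood.

    Reliability (= purity) is per-state recall, 100*correct/actual;
    precision is 100*correct/predicted.  Neighborhood lists the states
    that received a state's misclassified rows, most frequent first.
    When per-state posterior ``scores`` are given, one-vs-rest ROC index
    (AUC %) and Gini (2*AUC - 100) are included.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    k = len(state_labels)
    conf = np.zeros((k, k))
    np.add.at(conf, (actual, predicted), 1.0)
    rows = []
    for s in range(k):
        occ = conf[s].sum()
        correct = conf[s, s]
        pred_total = conf[:, s].sum()
        errs = [(conf[s, t], t) for t in range(k) if t != s and conf[s, t] > 0]
        errs.sort(key=lambda e: (-e[0], e[1]))
        reliability = 100.0 * correct / occ if occ else np.nan
        row = {"state": state_labels[s], "occurrence": int(occ),
               "reliability_pct": reliability,
               "precision_pct": 100.0 * correct / pred_total if pred_total else np.nan,
               "purity_pct": reliability,
               "neighborhood": [state_labels[t] for _, t in errs]}
        if scores is not None:
            onevs = (actual == s).astype(int)
            if 0 < onevs.sum() < onevs.size:
                auc = roc_auc_score(onevs, scores[:, s])
                row["roc_index_pct"] = 100.0 * auc
                row["gini_pct"] = 200.0 * auc - 100.0
            else:
                row["roc_index_pct"] = np.nan
                row["gini_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_target(results, target: str) -> PerformanceReport:
    """Predict the target state per row from all other nodes' states.

    The predictor is the exact posterior given full evidence on the other
    nodes; the predicted state is its argmax (ties to the lowest state
    index).  The numeric fit converts posteriors to a predicted
    continuous value via the per-state conditional means and reports
    Pearson R, R2 = R^2, RMSE and NRMSE (RMSE over the target's range).
    """
    network = results.network
    discrete = results.model.discrete
    if isinstance(discrete, DiscreteTable):
        frame = discrete.states[discrete.feature_names]
        labels = discrete.labels[target]
        cond_means = discrete.conditional_means.get(target)
    else:
        frame = pd.DataFrame(discrete)[list(network.nodes)]
        labels = network.states[target]
        cond_means = None
    k = len(labels)
    others = [v for v in network.nodes if v != target]
    actual = frame[target].to_numpy()
    scores = np.empty((len(frame), k))
    for i, (_, row) in enumerate(frame.iterrows()):
        evidence = {v: int(row[v]) for v in others}
        scores[i] = posterior(network, evidence, target)
    predicted = scores.argmax(axis=1)

    per_state = classification_report(actual, predicted, labels, scores=scores)
    conf = np.zeros((k, k))
    np.add.at(conf, (actual, predicted), 1.0)

    r = r2 = np.nan
    feats = results.model.features
    if feats is not None and target in feats and cond_means is not None:
        cm = np.asarray(cond_means, dtype=float)
        y = feats[target].to_numpy(dtype=float)
    else:
        # no continuous table: numeric fit on state indices
        cm = np.arange(k, dtype=float)
        y = actual.astype(float)
    y_hat = scores @ cm
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    span = y.max() - y.min()
    nrmse = float(rmse / span) if span > 0 else np.nan
    if np.std(y_hat) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(y, y_hat)[0, 1])
        r2 = r * r
    elif rmse == 0:
        r, r2 = 1.0, 1.0
    return PerformanceReport(per_state=per_state, r=r, r2=r2, rmse=rmse,
                             nrmse=nrmse, confusion=conf)
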