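"""Arc strengths, node forces, independence tests, target associations.

The strength of an arc is its Kullback-Leibler force: the divergence
between the fitted joint and the joint of the same tree with that arc
deleted and the child refit without the parent (the information lost by
assuming the pair independent).  Because only the child's factor changes
and the refit child distribution is the model's own child marginal, the
divergence reduces exactly to the mutual information of the arc's
endpoints under the fitted joint — which is why KL-force and MI columns
of a tree-network arc report nearly coincide.  Node force sums the KL
forces of a node's incident arcs (outgoing, incoming, total).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bayesnet import TreeNetwork, model_marginal, pair_joint
from .discretize import DiscreteTable
from .information import entropy, joint_counts, mutual_information_from_joint

__all__ = [
    "arc_kl_force",
    "model_pair_mi",
    "pearson_r",
    "gkl_independence_test",
    "node_force_table",
    "strength_table",
    "target_table",
    "relative_weights_and_contributions",
]


def model_pair_mi(network: TreeNetwork, a: str, b: str) -> float:
    """Mutual information of two nodes under the fitted joint, in bits."""
    return mutual_information_from_joint(pair_joint(network, a, b))


def arc_kl_force(network: TreeNetwork, parent: str, child: str) -> float:
    """KL force of one arc, in bits.

    KL( P_full || P_without_arc ) where the arc-deleted network refits the
    child against the full model (M-projection), i.e. the child's CPT is
    replaced by the model's child marginal.  Only the child factor
    differs between the two joints, so the divergence collapses to

        sum_{p,c} P(p,c) log2[ P(c|p) / P(c) ]  =  MI(parent, child)

    under the fitted pair joint; computed exactly on the tree.
    """
    if network.parent.get(child) != parent:
        raise ValueError(f"no arc {parent!r} -> {child!r} in the network")
    return model_pair_mi(network, parent, child)


def pearson_r(x, y) -> float:
    """Product-moment correlation of two continuous columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 rows for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant column")
    return float(stats.pearsonr(x, y).statistic)


def gkl_independence_test(x, y) -> tuple[float, int, float]:
    """Likelihood-ratio G test of independence on two state columns.

    Returns (G, dof, p).  G = 2 * sum O * ln(O/E) over non-zero cells,
    referred to a chi-square with (r-1)(c-1) degrees of freedom.
    """
    counts = joint_counts(x, y)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0:
        raise ValueError("empty contingency table")
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    mask = counts > 0
    g = 2.0 * float((counts[mask] * np.log(counts[mask] / expected[mask])).sum())
    dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if dof == 0:
        return g, 0, 1.0
    p = float(stats.chi2.sf(g, dof))
    return g, dof, p


def relative_weights_and_contributions(kl_values) -> tuple[np.ndarray, np.ndarray]:
    """Relative weight (KL / max KL) and contribution % (100 KL / sum KL)."""
    kl = np.asarray(kl_values, dtype=float)
    if kl.size == 0:
        return kl, kl
    return kl / kl.max(), 100.0 * kl / kl.sum()


def strength_table(network: TreeNetwork, discrete, features: pd.DataFrame | None = None
                   ) -> pd.DataFrame:
    """Per-arc report: KL force, relative weight, contribution %, MI,
    Pearson r of the continuous columns, G-test p-value.

    MI is computed from the fitted (smoothed) joint, matching inference;
    Pearson r uses the continuous pre-discretization features when
    available (NaN otherwise); the p-value is the G test on the raw
    discrete counts.  Rows are sorted by KL force descending.
    """
    frame = discrete.states if isinstance(discrete, DiscreteTable) else pd.DataFrame(discrete)
    rows = []
    for parent, child in network.arcs:
        kl = arc_kl_force(network, parent, child)
        mi = model_pair_mi(network, parent, child)
        if features is not None and parent in features and child in features:
            r = pearson_r(features[parent], features[child])
        else:
            r = np.nan
        _, _, p = gkl_independence_test(frame[parent], frame[child])
        rows.append({"parent": parent, "child": child, "kl_force": kl,
                     "mutual_information": mi, "pearson_r": r, "p_value": p})
    out = pd.DataFrame(rows, columns=["parent", "child", "kl_force",
                                      "mutual_information", "pearson_r", "p_value"])
    if len(out):
        w, c = relative_weights_and_contributions(out["kl_force"].to_numpy())
        out["relative_weight"] = w
        out["contribution_pct"] = c
        out = out.sort_values(["kl_force", "parent", "child"],
                              ascending=[False, True, True],
                              kind="mergesort").reset_index(drop=True)
        out = out[["parent", "child", "kl_force", "relative_weight",
                   "contribution_pct", "mutual_information", "pearson_r", "p_value"]]
    return out


def node_force_table(network: TreeNetwork, kl_forces: dict[tuple[str, str], float] | None = None
                     ) -> pd.DataFrame:
    """Outgoing / incoming / total KL force per node.

    Outgoing sums the forces of arcs with the node as parent, incoming
    those with it as child; total is their sum.  Isolated nodes report
    zeros.  Sorted by total force descending.
    """
    if kl_forces is None:
        kl_forces = {(p, c): arc_kl_force(network, p, c) for p, c in network.arcs}
    rows = []
    for v in network.nodes:
        outgoing = sum(f for (p, _), f in kl_forces.items() if p == v)
        incoming = sum(f for (_, c), f in kl_forces.items() if c == v)
        rows.append({"node": v, "outgoing": outgoing, "incoming": incoming,
                     "total": outgoing + incoming})
    out = pd.DataFrame(rows)
    return out.sort_values(["total", "node"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def target_table(network: TreeNetwork, discrete, target: str,
                 features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Association of every other node with the target.

    Per node: MI with the target under the fitted joint, normalized MI
    (% of the target's marginal entropy), relative significance
    (MI / max MI), the node's unconditional continuous mean, and the
    G-test p-value against the target.  Sorted by MI descending.
    """
    if target not in network.nodes:
        raise ValueError(f"target {target!r} not in network")
    frame = discrete.states if isinstance(discrete, DiscreteTable) else pd.DataFrame(discrete)
    h_target = entropy(model_marginal(network, target))
    rows = []
    for v in network.nodes:
        if v == target:
            continue
        mi = model_pair_mi(network, v, target)
        prior_mean = (float(np.mean(features[v])) if features is not None and v in features
                      else np.nan)
        _, _, p = gkl_independence_test(frame[v], frame[target])
        rows.append({"node": v, "mutual_information": mi,
                     "normalized_mi_pct": 100.0 * mi / h_target if h_target > 0 else 0.0,
                     "prior_mean": prior_mean, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        max_mi = out["mutual_information"].max()
        out["relative_significance"] = (out["mutual_information"] / max_mi
                                        if max_mi > 0 else 0.0)
        out = out.sort_values(["mutual_information", "node"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
        out = out[["node", "mutual_information", "normalized_mi_pct",
                   "relative_significance", "prior_mean", "p_value"]]
    return out
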