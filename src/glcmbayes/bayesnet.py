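"""Tree-structured discrete Bayesian networks: learning, fitting, inference.

The model is the classic Chow-Liu construction: pairwise mutual
information between all discrete variables, a maximum-weight spanning
tree over those weights, arcs oriented away from a chosen root (by
convention the analysis target), and conditional probability tables
(CPTs) estimated with uniform Dirichlet smoothing.  Inference is exact
message passing on the tree, so every posterior and marginal-likelihood
below is the exact quantity under the fitted joint

    P(X_1..X_n) = prod_i P(X_i | Pa(X_i)).

`TreeBayesNet` / `TreeBayesNetResults` follow the model/results split:
the model holds the data and structural choices, ``fit()`` estimates the
structure and CPTs, and the results object exposes inference, the
arc-strength/node-force/target reports, sensitivity and profiling
analyses, and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from networkx.utils import UnionFind

from .discretize import DiscreteTable
from .information import entropy, mutual_information

__all__ = [
    "TreeNetwork",
    "learn_chow_liu",
    "fit_cpts",
    "posterior",
    "evidence_probability",
    "model_marginal",
    "pair_joint",
    "mdl_score",
    "sample",
    "TreeBayesNet",
    "TreeBayesNetResults",
]


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNetwork:
    """Directed tree (or forest) over discrete nodes with CPTs.

    ``parent[v]`` is ``None`` for roots.  ``cpts[v]`` has shape
    (parent_states, own_states); root CPTs have a single row holding the
    marginal.  Every CPT row sums to 1.
    """

    nodes: tuple[str, ...]
    states: dict[str, list[str]]
    parent: dict[str, str | None]
    cpts: dict[str, np.ndarray] = field(default_factory=dict)
    root: str | None = None

    def __post_init__(self):
        for v in self.nodes:
            p = self.parent.get(v)
            if p is not None and p not in self.nodes:
                raise ValueError(f"parent {p!r} of {v!r} is not a node")
        # acyclicity: walking up from any node must terminate
        for v in self.nodes:
            seen = set()
            cur = v
            while cur is not None:
                if cur in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(cur)
                cur = self.parent.get(cur)
        for v, cpt in self.cpts.items():
            k = len(self.states[v])
            if cpt.shape[1] != k:
                raise ValueError(f"CPT of {v!r} has {cpt.shape[1]} columns, expected {k}")
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {v!r} do not sum to 1")

    @property
    def arcs(self) -> list[tuple[str, str]]:
        return [(p, v) for v, p in self.parent.items() if p is not None]

    def children(self, v: str) -> list[str]:
        return [c for c in self.nodes if self.parent.get(c) == v]

    def roots(self) -> list[str]:
        return [v for v in self.nodes if self.parent.get(v) is None]

    def n_states(self, v: str) -> int:
        return len(self.states[v])

    def n_free_parameters(self) -> int:
        total = 0
        for v in self.nodes:
            rows = self.n_states(self.parent[v]) if self.parent.get(v) else 1
            total += rows * (self.n_states(v) - 1)
        return total


# ---------------------------------------------------------------------------
# structure learning and CPT fitting
# ---------------------------------------------------------------------------

def _as_state_frame(data) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    if isinstance(data, DiscreteTable):
        frame = data.states[data.feature_names]
        labels = {f: list(data.labels[f]) for f in data.feature_names}
        return frame, labels
    frame = pd.DataFrame(data)
    labels = {c: [str(s) for s in range(int(frame[c].max()) + 1)] for c in frame.columns}
    return frame, labels


def learn_chow_liu(data, root: str | None = None, pseudo_count: float = 0.0,
                   mi_tol: float = 1e-12) -> TreeNetwork:
    """Chow-Liu structure: maximum-weight spanning tree on pairwise MI.

    Edges are selected by Kruskal's algorithm with a deterministic
    tie-break (higher MI first, then lexicographic node-name pairs), and
    arcs are oriented away from ``root`` (default: lexicographically
    first node).  If every pairwise MI is (numerically) zero the result
    is a forest of isolated nodes, with a warning.
    """
    frame, labels = _as_state_frame(data)
    nodes = sorted(frame.columns)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to learn a structure")
    if len(frame) < 1:
        raise ValueError("need at least 1 row")
    if root is None:
        root = nodes[0]
    if root not in nodes:
        raise ValueError(f"root {root!r} is not a column of the data")

    edges = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            mi = mutual_information(frame[u], frame[v], pseudo_count=pseudo_count)
            edges.append((mi, u, v))

    parent: dict[str, str | None] = {v: None for v in nodes}
    if max(e[0] for e in edges) <= mi_tol:
        warnings.warn("all pairwise MI are zero: returning a forest of isolated nodes",
                      stacklevel=2)
        return TreeNetwork(tuple(nodes), labels, parent, root=root)

    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    uf = UnionFind(nodes)
    chosen = []
    for mi, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            chosen.append((u, v))
            if len(chosen) == len(nodes) - 1:
                break

    # orient away from the root (and from the lexicographically first node
    # of any other component, should the tree be a forest)
    adj: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in chosen:
        adj[u].append(v)
        adj[v].append(u)
    visited = set()
    for start in [root] + nodes:
        if start in visited:
            continue
        stack = [start]
        visited.add(start)
        while stack:
            u = stack.pop()
            for v in sorted(adj[u]):
                if v not in visited:
                    parent[v] = u
                    visited.add(v)
                    stack.append(v)
    return TreeNetwork(tuple(nodes), labels, parent, root=root)


def fit_cpts(network: TreeNetwork, data, prior_count: float = 1.0) -> TreeNetwork:
    """Estimate CPTs by smoothed relative frequencies.

    Each CPT entry is (count + prior_count) / (row_total + prior_count*k)
    — maximum likelihood at prior_count=0, uniform Dirichlet smoothing
    otherwise (an unseen parent configuration yields a uniform row).
    """
    frame, _ = _as_state_frame(data)
    cpts = {}
    for v in network.nodes:
        k = network.n_states(v)
        p = network.parent.get(v)
        if p is None:
            counts = np.zeros((1, k))
            np.add.at(counts[0], frame[v].to_numpy(), 1.0)
        else:
            kp = network.n_states(p)
            counts = np.zeros((kp, k))
            np.add.at(counts, (frame[p].to_numpy(), frame[v].to_numpy()), 1.0)
        counts += prior_count
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError(f"node {v!r}: empty parent configuration with prior_count=0")
        cpts[v] = counts / totals
    return replace(network, cpts=cpts)


# ---------------------------------------------------------------------------
# exact inference
# ---------------------------------------------------------------------------

def _check_evidence(network: TreeNetwork, evidence: dict[str, int]) -> None:
    for v, s in evidence.items():
        if v not in network.nodes:
            raise ValueError(f"evidence node {v!r} not in network")
        if not (0 <= int(s) < network.n_states(v)):
            raise ValueError(f"evidence state {s!r} invalid for node {v!r}")


def evidence_probability(network: TreeNetwork, evidence: dict[str, int]) -> float:
    """Exact marginal probability P(H) of a hard-evidence assignment.

    Computed by a single leaves-to-root message pass per tree of the
    forest; the empty evidence set has probability 1.
    """
    if not network.cpts:
        raise ValueError("CPTs not fitted")
    _check_evidence(network, evidence)

    def message(v: str) -> np.ndarray:
        """P(evidence in v's subtree | state of v's parent) as a vector
        over parent states (roots: scalar wrapped in length-1 vector)."""
        cpt = network.cpts[v]                  # (parent_states, k)
        beta = np.ones(network.n_states(v))
        for c in network.children(v):
            beta *= message(c)
        if v in evidence:
            mask = np.zeros_like(beta)
            mask[int(evidence[v])] = 1.0
            beta = beta * mask
        return cpt @ beta                      # vector over parent states

    prob = 1.0
    for r in network.roots():
        prob *= float(message(r)[0])
    return prob


def posterior(network: TreeNetwork, evidence: dict[str, int], query: str) -> np.ndarray:
    """Exact posterior P(query | evidence) over the query's states."""
    if query in evidence:
        raise ValueError("query node cannot carry evidence")
    if query not in network.nodes:
        raise ValueError(f"query node {query!r} not in network")
    p_h = evidence_probability(network, evidence)
    if p_h <= 0:
        raise ValueError(f"evidence has zero probability under the model: {evidence}")
    k = network.n_states(query)
    joint = np.array([
        evidence_probability(network, {**evidence, query: s}) for s in range(k)
    ])
    return joint / p_h


def model_marginal(network: TreeNetwork, node: str) -> np.ndarray:
    """Marginal distribution of one node under the fitted joint."""
    return posterior(network, {}, node)


def pair_joint(network: TreeNetwork, a: str, b: str) -> np.ndarray:
    """Exact joint P(a, b) under the fitted model, shape (k_a, k_b)."""
    ka, kb = network.n_states(a), network.n_states(b)
    out = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            out[i, j] = evidence_probability(network, {a: i, b: j})
    return out


# ---------------------------------------------------------------------------
# scoring and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MdlScore:
    """Two-part description length in bits; lower is better."""

    data_bits: float
    structure_bits: float

    @property
    def total(self) -> float:
        return self.data_bits + self.structure_bits


def mdl_score(network: TreeNetwork, data) -> MdlScore:
    """MDL = -sum_rows log2 P(row) + (1/2) log2(n) * free parameters."""
    frame, _ = _as_state_frame(data)
    n = len(frame)
    loglik = 0.0
    for v in network.nodes:
        cpt = network.cpts[v]
        p = network.parent.get(v)
        rows = frame[p].to_numpy() if p is not None else np.zeros(n, dtype=int)
        probs = cpt[rows, frame[v].to_numpy()]
        if np.any(probs <= 0):
            raise ValueError("zero-probability row under the model; fit CPTs with "
                             "prior_count > 0")
        loglik += np.log2(probs).sum()
    structure = 0.5 * np.log2(n) * network.n_free_parameters()
    return MdlScore(data_bits=float(-loglik), structure_bits=float(structure))


def sample(network: TreeNetwork, n: int, rng) -> pd.DataFrame:
    """Ancestral sampling of n rows from the fitted network."""
    rng = np.random.default_rng(rng)
    order: list[str] = []
    todo = network.roots()
    while todo:
        v = todo.pop(0)
        order.append(v)
        todo.extend(network.children(v))
    out: dict[str, np.ndarray] = {}
    for v in order:
        cpt = network.cpts[v]
        p = network.parent.get(v)
        k = network.n_states(v)
        if p is None:
            out[v] = rng.choice(k, size=n, p=cpt[0])
        else:
            draws = np.empty(n, dtype=int)
            u = rng.random(n)
            cum = cpt.cumsum(axis=1)
            draws = (u[:, None] > cum[out[p]]).sum(axis=1)
            out[v] = draws
    return pd.DataFrame(out)[list(network.nodes)]


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class TreeBayesNet:
    """Chow-Liu tree Bayesian network over a discretized feature table.

    Parameters
    ----------
    discrete : DiscreteTable or DataFrame of integer state columns
        The variables of the network.
    features : DataFrame, optional
        The continuous feature table the states were derived from; enables
        the Pearson-correlation column, prior/posterior means and the
        numeric network-performance report.
    root : str, optional
        Node from which arcs are oriented away (display convention);
        defaults to the analysis target when given, else the first node.
    target : str, optional
        The analysis target feature (used as default for the target and
        profiling reports).
    """

    def __init__(self, discrete, features: pd.DataFrame | None = None,
                 root: str | None = None, target: str | None = None):
        self.discrete = discrete
        self.features = features
        self.target = target
        self.root = root if root is not None else target
        self._frame, self._labels = _as_state_frame(discrete)

    @classmethod
    def from_features(cls, features: pd.DataFrame, n_states: int = 4,
                      method: str = "equal-frequency", target: str | None = None,
                      label_col: str = "class") -> "TreeBayesNet":
        """Discretize a continuous feature table and build the model."""
        from .discretize import apply_scheme, fit_equal_frequency, fit_equal_width
        fit = {"equal-frequency": fit_equal_frequency,
               "equal-width": fit_equal_width}[method]
        scheme = fit(features, n_states=n_states, label_col=label_col)
        disc = apply_scheme(features, scheme, label_col=label_col)
        return cls(disc, features=features, target=target)

    def fit(self, prior_count: float = 1.0, pseudo_count: float = 0.0) -> "TreeBayesNetResults":
        """Learn the tree, fit smoothed CPTs and return the results."""
        network = learn_chow_liu(self.discrete, root=self.root,
                                 pseudo_count=pseudo_count)
        network = fit_cpts(network, self.discrete, prior_count=prior_count)
        return TreeBayesNetResults(self, network, prior_count=prior_count)


class TreeBayesNetResults:
    """Fitted tree network plus the reporting surface.

    Carries the learned :class:`TreeNetwork` with its CPTs, exposes exact
    inference (``posterior``, ``evidence_probability``), the arc-strength,
    node-force and target-association tables, tornado sensitivity, greedy
    dynamic profiling, the optimization tree, segment profiles and the
    target-evaluation performance report.
    """

    def __init__(self, model: TreeBayesNet, network: TreeNetwork, prior_count: float = 1.0):
        self.model = model
        self.network = network
        self.prior_count = prior_count

    # -- inference -----------------------------------------------------
    def posterior(self, evidence: dict[str, int], query: str) -> np.ndarray:
        return posterior(self.network, evidence, query)

    def evidence_probability(self, evidence: dict[str, int]) -> float:
        return evidence_probability(self.network, evidence)

    def marginal(self, node: str) -> np.ndarray:
        return model_marginal(self.network, node)

    @property
    def mdl(self) -> MdlScore:
        return mdl_score(self.network, self.model.discrete)

    def _target(self, target: str | None) -> str:
        t = target or self.model.target
        if t is None:
            raise ValueError("no target feature set on the model")
        return t

    # -- reports (delegating to the metric/profiling modules) ----------
    def arc_strengths(self) -> pd.DataFrame:
        from .arc_metrics import strength_table
        return strength_table(self.network, self.model.discrete, self.model.features)

    def node_forces(self) -> pd.DataFrame:
        from .arc_metrics import node_force_table
        return node_force_table(self.network)

    def target_table(self, target: str | None = None) -> pd.DataFrame:
        from .arc_metrics import target_table
        return target_table(self.network, self.model.discrete, self._target(target),
                            features=self.model.features)

    def tornado(self, target_state: int, target: str | None = None) -> pd.DataFrame:
        from .profiling import tornado
        return tornado(self.network, self._target(target), target_state)

    def dynamic_profile(self, target_state: int, target: str | None = None,
                        max_steps: int | None = None):
        from .profiling import dynamic_profile
        return dynamic_profile(self.network, self._target(target), target_state,
                               discrete=self.model.discrete, max_steps=max_steps)

    def optimization_tree(self, target_state: int, threshold: float,
                          target: str | None = None, max_depth: int = 3):
        from .profiling import optimization_tree
        return optimization_tree(self.network, self._target(target), target_state,
                                 threshold, max_depth=max_depth)

    def segment_profile(self, target: str | None = None, seed: int = 0,
                        best_samples: int = 20_000):
        from .profiling import segment_profile
        t = self._target(target)
        disc = self.model.discrete
        if self.model.features is None:
            raise ValueError("segment profiles need the continuous feature table")
        return segment_profile(self.model.features, disc.states[t].to_numpy(),
                               disc.labels[t], target=t, seed=seed,
                               best_samples=best_samples)

    def evaluate_target(self, target: str | None = None):
        from .profiling import evaluate_target
        return evaluate_target(self, self._target(target))

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        """Plain-text overview: structure, MDL, arc strengths, node forces."""
        lines = ["Tree Bayesian network (Chow-Liu / maximum-weight spanning tree)"]
        lines.append(f"  nodes: {len(self.network.nodes)}   arcs: {len(self.network.arcs)}"
                     f"   rows: {len(self.model._frame)}")
        score = self.mdl
        lines.append(f"  MDL: {score.total:.2f} bits "
                     f"(data {score.data_bits:.2f} + structure {score.structure_bits:.2f})")
        lines.append("")
        lines.append("Arc strengths (KL force, bits):")
        lines.append(self.arc_strengths().to_string(index=False,
                                                    float_format=lambda x: f"{x:.4f}"))
        lines.append("")
        lines.append("Node forces (bits):")
        lines.append(self.node_forces().to_string(index=False,
                                                  float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)
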