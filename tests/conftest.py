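"""Shared fixtures and independent oracles for the test suite.

The oracles here (full joint enumeration, literal double-loop feature
sums, hand pair counting) deliberately avoid the package's own fast
paths so they can serve as independent references.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from glcmbayes.bayesnet import TreeNetwork


# ---------------------------------------------------------------------------
# joint-enumeration oracle for tree networks
# ---------------------------------------------------------------------------

def enumerate_joint(network: TreeNetwork) -> tuple[list[str], dict[tuple, float]]:
    """Full joint distribution by brute-force product over all assignments."""
    nodes = list(network.nodes)
    table = {}
    for combo in itertools.product(*[range(network.n_states(v)) for v in nodes]):
        assignment = dict(zip(nodes, combo))
        p = 1.0
        for v in nodes:
            par = network.parent.get(v)
            row = 0 if par is None else assignment[par]
            p *= network.cpts[v][row, assignment[v]]
        table[combo] = p
    return nodes, table


def oracle_evidence_probability(network: TreeNetwork, evidence: dict) -> float:
    nodes, table = enumerate_joint(network)
    total = 0.0
    for combo, p in table.items():
        a = dict(zip(nodes, combo))
        if all(a[v] == s for v, s in evidence.items()):
            total += p
    return total


def oracle_posterior(network: TreeNetwork, evidence: dict, query: str) -> np.ndarray:
    k = network.n_states(query)
    joint = np.array([
        oracle_evidence_probability(network, {**evidence, query: s}) for s in range(k)
    ])
    return joint / joint.sum()


def random_tree_network(rng, n_nodes: int, min_states: int = 2, max_states: int = 4,
                        concentration: float = 1.0) -> TreeNetwork:
    """Random structure (random attachment) with Dirichlet CPT rows."""
    rng = np.random.default_rng(rng)
    names = [f"n{i}" for i in range(n_nodes)]
    parent: dict[str, str | None] = {names[0]: None}
    for i in range(1, n_nodes):
        parent[names[i]] = names[int(rng.integers(0, i))]
    states = {v: [str(s) for s in range(int(rng.integers(min_states, max_states + 1)))]
              for v in names}
    cpts = {}
    for v in names:
        k = len(states[v])
        rows = len(states[parent[v]]) if parent[v] is not None else 1
        cpts[v] = rng.dirichlet(np.full(k, concentration), size=rows)
    return TreeNetwork(tuple(names), states, parent, cpts=cpts, root=names[0])


# ---------------------------------------------------------------------------
# shared image fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def texture_study():
    """A small two-class texture study with its extracted feature table."""
    from glcmbayes import OffsetSpec, extract_features, generate_textures
    from glcmbayes.synthetic import TextureSpec
    specs = [TextureSpec("rough", blur_radius=0.0, size=(32, 32), count=25),
             TextureSpec("smooth", blur_radius=2.0, size=(32, 32), count=25)]
    images, labels = generate_textures(specs, seed=42)
    offsets = [OffsetSpec(1, a) for a in (0, 45, 90, 135)]
    table = extract_features(images, labels, offsets=offsets, n_levels=8)
    return images, labels, table


@pytest.fixture(scope="session")
def fitted_tree_study():
    """A fitted model on samples from a known strong 5-node chain."""
    from glcmbayes import TreeBayesNet
    from glcmbayes.synthetic import TreeSpec, sample_tree
    spec = TreeSpec.chain(5, strength=0.85, n_states=3)
    data = sample_tree(spec, 3000, seed=7)
    model = TreeBayesNet(data, target="X0")
    return spec, data, model.fit(prior_count=1.0)
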