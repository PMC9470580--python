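"""Synthetic inputs for every pipeline stage.

Three generators stand in for data the full study would require:

* Gaussian-smoothed noise textures — two classes differing only in blur
  radius.  Smoothing concentrates the co-occurrence distribution, so the
  smoother class provably has higher GLCM energy/homogeneity and lower
  entropy, giving a monotone, testable ground truth for the feature
  extractor and the ranking stage.
* Discrete samples from a known tree-structured joint — ground truth for
  structure-recovery tests of the Chow-Liu learner.
* Correlated Gaussian feature tables with an exactly duplicated column
  pair — emulating the duplicated correlation variants and strong
  negative dissimilarity/homogeneity association characteristic of
  Haralick feature sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .glcm import GrayImage

__all__ = [
    "TextureSpec",
    "TreeSpec",
    "generate_textures",
    "default_texture_specs",
    "sample_tree",
    "generate_feature_table",
]


@dataclass(frozen=True)
class TextureSpec:
    """One texture class: blur radius controls smoothness."""

    label: str
    blur_radius: float
    mean: float = 120.0
    sd: float = 40.0
    size: tuple[int, int] = (64, 64)
    count: int = 100

    def __post_init__(self):
        if self.size[0] < 16 or self.size[1] < 16:
            raise ValueError("image size must be at least 16x16")
        if self.count < 1:
            raise ValueError("count must be at least 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def default_texture_specs(count: int = 100, size: int = 64) -> list[TextureSpec]:
    """The two standard study classes: rough (no blur) vs smooth (blur 2)."""
    return [TextureSpec("rough", blur_radius=0.0, size=(size, size), count=count),
            TextureSpec("smooth", blur_radius=2.0, size=(size, size), count=count)]


def generate_textures(specs: list[TextureSpec], seed: int = 0
                      ) -> tuple[list[GrayImage], list[str]]:
    """Gaussian-smoothed white-noise textures, one class per spec.

    Per image: a standard-normal field, Gaussian smoothing at the class's
    blur radius, then an affine rescale to the class mean/sd clipped to
    8-bit.  Byte-identical under the same seed.  A blur radius at or
    beyond the image size produces a near-constant field and is flagged.
    """
    rng = np.random.default_rng(seed)
    images: list[GrayImage] = []
    labels: list[str] = []
    for spec in specs:
        if spec.blur_radius >= min(spec.size):
            warnings.warn(f"class {spec.label!r}: blur radius >= image size yields "
                          "degenerate near-constant textures", stacklevel=2)
        for _ in range(spec.count):
            field_ = rng.standard_normal(spec.size)
            if spec.blur_radius > 0:
                field_ = gaussian_filter(field_, spec.blur_radius, mode="reflect")
            sd = field_.std()
            if sd < 1e-12:
                z = np.zeros_like(field_)
            else:
                z = (field_ - field_.mean()) / sd
            px = np.clip(np.rint(spec.mean + spec.sd * z), 0, 255).astype(np.int64)
            images.append(GrayImage(px, bit_depth=8))
            labels.append(spec.label)
    return images, labels


@dataclass(frozen=True)
class TreeSpec:
    """Ground-truth tree: child copies parent with a given probability."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    strength: float = 0.9
    n_states: int = 3
    root_marginal: np.ndarray | None = None

    def __post_init__(self):
        if not (0 < self.strength < 1) and self.strength != 1.0:
            raise ValueError("strength must be in (0, 1]")
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("edges must form a spanning tree")
        seen = {self.nodes[0]}
        remaining = list(self.edges)
        while remaining:
            progress = False
            for e in list(remaining):
                if e[0] in seen or e[1] in seen:
                    seen.update(e)
                    remaining.remove(e)
                    progress = True
            if not progress:
                raise ValueError("edges do not form a connected tree")

    @classmethod
    def chain(cls, n: int = 8, strength: float = 0.9, n_states: int = 3) -> "TreeSpec":
        nodes = tuple(f"X{i}" for i in range(n))
        edges = tuple((nodes[i], nodes[i + 1]) for i in range(n - 1))
        return cls(nodes, edges, strength=strength, n_states=n_states)

    @classmethod
    def random_tree(cls, n: int, rng, strength: float = 0.9, n_states: int = 3) -> "TreeSpec":
        """Uniform random labelled tree via a random attachment process."""
        rng = np.random.default_rng(rng)
        nodes = tuple(f"X{i}" for i in range(n))
        edges = []
        for i in range(1, n):
            j = int(rng.integers(0, i))
            edges.append((nodes[j], nodes[i]))
        return cls(nodes, tuple(edges), strength=strength, n_states=n_states)


def sample_tree(spec: TreeSpec, n: int, seed: int = 0) -> pd.DataFrame:
    """Ancestral samples from the spec's tree.

    The root follows its marginal (uniform by default); every child
    equals its parent's state with probability ``strength`` and is
    otherwise uniform over the remaining states.  A strength of 1/k makes
    children independent of parents; a strength of 1 copies them exactly.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    k = spec.n_states
    root = spec.nodes[0]
    children: dict[str, list[str]] = {v: [] for v in spec.nodes}
    parent: dict[str, str] = {}
    # orient the undirected edges away from the first node
    adj: dict[str, list[str]] = {v: [] for v in spec.nodes}
    for u, v in spec.edges:
        adj[u].append(v)
        adj[v].append(u)
    stack, visited = [root], {root}
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v not in visited:
                visited.add(v)
                parent[v] = u
                children[u].append(v)
                stack.append(v)

    data: dict[str, np.ndarray] = {}
    marg = (np.full(k, 1.0 / k) if spec.root_marginal is None
            else np.asarray(spec.root_marginal, dtype=float))
    data[root] = rng.choice(k, size=n, p=marg)
    for v in order[1:]:
        p = data[parent[v]]
        copy = rng.random(n) < spec.strength
        other = rng.integers(0, k - 1, size=n)
        # map a uniform draw over k-1 values onto the states != parent state
        shifted = other + (other >= p)
        data[v] = np.where(copy, p, shifted)
    return pd.DataFrame(data)[list(spec.nodes)]


def generate_feature_table(n: int, correlation: np.ndarray,
                           feature_names: list[str],
                           duplicate_pair: tuple[str, str] | None = None,
                           class_shift: dict[str, float] | None = None,
                           seed: int = 0, label_col: str = "class",
                           class_labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Two-class Gaussian feature table with a requested correlation
    structure.

    Rows are drawn from a multivariate normal with the given correlation
    matrix (must be positive semi-definite), split evenly into two
    classes; ``class_shift`` adds a mean offset (in s.d. units) to the
    named features of the second class, and ``duplicate_pair`` copies one
    column onto another exactly (Pearson r = 1 by construction).
    """
    correlation = np.asarray(correlation, dtype=float)
    m = len(feature_names)
    if correlation.shape != (m, m):
        raise ValueError("correlation matrix shape does not match feature names")
    eigvals = np.linalg.eigvalsh((correlation + correlation.T) / 2)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    # eigendecomposition handles the PSD (rank-deficient) case exactly
    w, v = np.linalg.eigh((correlation + correlation.T) / 2)
    w = np.clip(w, 0, None)
    draws = rng.standard_normal((n, m)) @ (v * np.sqrt(w)).T
    table = pd.DataFrame(draws, columns=feature_names)
    half = n // 2
    labels = np.array([class_labels[0]] * half + [class_labels[1]] * (n - half))
    if class_shift:
        for feat, shift in class_shift.items():
            table.loc[half:, feat] += shift
    if duplicate_pair is not None:
        src, dst = duplicate_pair
        table[dst] = table[src].to_numpy()
    table[label_col] = labels
    return table
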