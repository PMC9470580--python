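"""Discretization of continuous features into labelled states.

States are labelled ``<=c1, <=c2, ..., >c_{k-1}`` after their upper cut
points, with the upper boundary closed (a value exactly equal to a cut
belongs to that cut's ``<=`` state).  Besides the state indices, the
discrete table keeps the per-state conditional means of the underlying
continuous values, which the profiling reports use as prior/posterior
means in feature units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DiscretizationScheme", "DiscreteTable", "fit_equal_frequency",
           "fit_equal_width", "apply_scheme"]


def _fmt(c: float) -> str:
    return f"{c:.6g}"


def state_labels(cuts: np.ndarray) -> list[str]:
    """Labels of the form '<=c1', ..., '>c_{k-1}' for a cut vector."""
    if len(cuts) == 0:
        return ["all"]
    labels = [f"<={_fmt(c)}" for c in cuts]
    labels.append(f">{_fmt(cuts[-1])}")
    return labels


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-feature ascending cut points defining k = cuts+1 states."""

    cuts: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for feat, c in self.cuts.items():
            c = np.asarray(c, dtype=float)
            if c.size and np.any(np.diff(c) <= 0):
                raise ValueError(f"cut points for {feat!r} must be strictly ascending")
            clean[feat] = c
        object.__setattr__(self, "cuts", clean)

    def n_states(self, feature: str) -> int:
        return len(self.cuts[feature]) + 1

    def labels(self, feature: str) -> list[str]:
        return state_labels(self.cuts[feature])

    def to_json(self) -> str:
        return json.dumps({f: list(c) for f, c in self.cuts.items()}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        return cls({f: np.asarray(c, dtype=float) for f, c in json.loads(text).items()})


@dataclass
class DiscreteTable:
    """State indices per feature plus per-state conditional means."""

    states: pd.DataFrame
    labels: dict[str, list[str]]
    conditional_means: dict[str, np.ndarray] = field(default_factory=dict)
    label_col: str | None = None

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.states.columns if c != self.label_col]

    def n_states(self, feature: str) -> int:
        return len(self.labels[feature])


def _feature_columns(table: pd.DataFrame, label_col: str) -> list[str]:
    return [c for c in table.columns if c != label_col]


def fit_equal_frequency(table: pd.DataFrame, n_states: int = 4,
                        label_col: str = "class") -> DiscretizationScheme:
    """Equal-frequency cuts at the empirical k/n_states quantiles.

    Quantiles are taken as order statistics (inverted CDF), so every cut
    is an observed value and the closed-upper-boundary rule assigns it to
    its own state.  Duplicate quantiles are collapsed (fewer states) with
    a warning; a constant feature yields a single state, flagged.
    """
    if n_states < 2:
        raise ValueError("n_states must be at least 2")
    if len(table) < n_states:
        raise ValueError("need at least n_states rows to fit quantile cuts")
    cuts = {}
    for feat in _feature_columns(table, label_col):
        vals = table[feat].to_numpy(dtype=float)
        qs = np.arange(1, n_states) / n_states
        c = np.quantile(vals, qs, method="inverted_cdf")
        c = np.unique(c)
        # a cut equal to the maximum would leave the last state empty
        c = c[c < vals.max()]
        if len(c) == 0:
            warnings.warn(f"feature {feat!r} is constant or near-constant: single state",
                          stacklevel=2)
        elif len(c) < n_states - 1:
            warnings.warn(f"feature {feat!r}: duplicate quantiles collapsed to "
                          f"{len(c) + 1} states", stacklevel=2)
        cuts[feat] = c
    return DiscretizationScheme(cuts)


def fit_equal_width(table: pd.DataFrame, n_states: int = 4,
                    label_col: str = "class") -> DiscretizationScheme:
    """Equal-width cuts spanning each feature's observed range."""
    if n_states < 2:
        raise ValueError("n_states must be at least 2")
    cuts = {}
    for feat in _feature_columns(table, label_col):
        vals = table[feat].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi <= lo:
            warnings.warn(f"feature {feat!r} is constant: single state", stacklevel=2)
            cuts[feat] = np.asarray([])
        else:
            cuts[feat] = np.linspace(lo, hi, n_states + 1)[1:-1]
    return DiscretizationScheme(cuts)


def apply_scheme(table: pd.DataFrame, scheme: DiscretizationScheme,
                 label_col: str = "class") -> DiscreteTable:
    """Map continuous values to state indices under a fitted scheme.

    A value v maps to the first state whose cut satisfies v <= cut, else
    the last state; values outside the training range therefore clamp to
    the end states.  Monotone by construction.
    """
    feats = _feature_columns(table, label_col)
    missing = [f for f in feats if f not in scheme.cuts]
    if missing:
        raise ValueError(f"scheme does not cover features: {missing}")
    states = {}
    labels = {}
    cond_means = {}
    for feat in feats:
        vals = table[feat].to_numpy(dtype=float)
        c = scheme.cuts[feat]
        idx = np.searchsorted(c, vals, side="left")
        states[feat] = idx
        labels[feat] = scheme.labels(feat)
        k = len(c) + 1
        means = np.full(k, np.nan)
        for s in range(k):
            sel = idx == s
            if sel.any():
                means[s] = vals[sel].mean()
        if np.isnan(means).any():
            warnings.warn(f"feature {feat!r}: empty state(s); conditional mean "
                          "falls back to overall mean", stacklevel=2)
            means[np.isnan(means)] = vals.mean()
        cond_means[feat] = means
    out = pd.DataFrame(states, index=table.index)
    lab = None
    if label_col in table.columns:
        out[label_col] = table[label_col].to_numpy()
        lab = label_col
    return DiscreteTable(states=out, labels=labels, conditional_means=cond_means,
                         label_col=lab)
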