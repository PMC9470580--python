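"""Gray-level co-occurrence matrices and Haralick-family texture features.

A co-occurrence matrix tabulates how often two gray levels appear at a
fixed pixel displacement (distance ``d``, angle ``theta`` in
{0, 45, 90, 135} degrees).  Thirteen scalar texture statistics
(energy, entropy, contrast, the two correlation variants, cluster
shade/prominence, dissimilarity, homogeneity variants, autocorrelation,
maximum probability, sum variance) are computed from the normalised
matrix.  Gray-level indices are 1-based throughout, matching the
levels-1..M convention for an M x M matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrayImage",
    "OffsetSpec",
    "CooccurrenceMatrix",
    "FEATURE_NAMES",
    "quantize",
    "cooccurrence",
    "haralick_features",
    "extract_features",
    "default_offsets",
]

#: Canonical order of the implemented texture features.
FEATURE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation1",
    "correlation2",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "max_probability",
    "sum_variance",
)

# Displacement (row, col) per canonical angle; rows grow downward, so 45
# degrees points up-and-right.
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GrayImage:
    """A 2-D integer intensity grid with a declared bit depth."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be a 2-D grid of at least 2x2 pixels")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("image intensities must be integers")
        hi = 2 ** self.bit_depth - 1
        if px.min() < 0 or px.max() > hi:
            raise ValueError(f"intensities outside [0, {hi}] for bit depth {self.bit_depth}")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class OffsetSpec:
    """Pixel displacement: distance in pixels, angle in degrees."""

    distance: int
    angle: int

    def __post_init__(self):
        if self.distance < 1:
            raise ValueError("distance must be a positive integer")
        if self.angle not in _ANGLE_STEPS:
            raise ValueError("angle must be one of 0, 45, 90, 135 degrees")

    @property
    def displacement(self) -> tuple[int, int]:
        dr, dc = _ANGLE_STEPS[self.angle]
        return dr * self.distance, dc * self.distance


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalised gray-level pair probabilities for one displacement."""

    P: np.ndarray
    offset: OffsetSpec
    symmetric: bool = True
    n_levels: int = field(default=0)

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if np.any(P < 0) or abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("co-occurrence entries must be non-negative and sum to 1")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "n_levels", P.shape[0])


def default_offsets(distances=(1, 2, 3, 4), angles=(0, 45, 90, 135)) -> list[OffsetSpec]:
    """The standard 16-offset grid: d = 1..4 crossed with the 4 angles."""
    return [OffsetSpec(d, a) for d in distances for a in angles]


def quantize(image: GrayImage, n_levels: int) -> GrayImage:
    """Reduce an image to ``n_levels`` gray levels labelled 1..n_levels.

    The full representable intensity range [0, 2^bit_depth - 1] is split
    into ``n_levels`` equal-width bins, so the mapping is order-preserving
    and independent of the particular image's dynamic range.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    span = 2 ** image.bit_depth
    levels = (image.pixels.astype(np.int64) * n_levels) // span + 1
    np.clip(levels, 1, n_levels, out=levels)
    # bit depth of the output is only nominal; keep levels within range
    out_depth = max(int(np.ceil(np.log2(n_levels + 1))), 2)
    return GrayImage(levels, bit_depth=out_depth)


def cooccurrence(image: GrayImage, offset: OffsetSpec, symmetric: bool = True,
                 n_levels: int | None = None) -> CooccurrenceMatrix:
    """Count (reference, neighbour) gray-level pairs at one displacement.

    The image must already be quantized to levels 1..M.  Pairs whose
    neighbour falls outside the image are skipped (no padding).  In
    symmetric mode each pair is counted in both directions, making the
    matrix exactly symmetric.  Counts are normalised to sum to 1.
    """
    px = image.pixels
    if px.min() < 1:
        raise ValueError("image must be quantized to levels 1..M before co-occurrence")
    m = int(n_levels if n_levels is not None else px.max())
    dr, dc = offset.displacement
    rows, cols = px.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        raise ValueError(
            f"offset displacement ({dr},{dc}) yields no pixel pairs in a {rows}x{cols} image")

    r0 = slice(max(0, -dr), min(rows, rows - dr))
    c0 = slice(max(0, -dc), min(cols, cols - dc))
    r1 = slice(max(0, dr), min(rows, rows + dr))
    c1 = slice(max(0, dc), min(cols, cols + dc))
    ref = px[r0, c0].ravel() - 1
    nbr = px[r1, c1].ravel() - 1

    counts = np.zeros((m, m))
    np.add.at(counts, (ref, nbr), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("offset produced no pixel pairs")
    return CooccurrenceMatrix(counts / total, offset=offset, symmetric=symmetric)


def haralick_features(matrix: CooccurrenceMatrix) -> pd.Series:
    """Compute the 13 implemented texture features from one matrix.

    Marginal means/s.d. use 1-based level indices.  If either marginal
    standard deviation is zero (degenerate texture) both correlation
    variants are set to 0 and a warning is issued.
    """
    p = matrix.P
    m = p.shape[0]
    i = np.arange(1, m + 1)[:, None]
    j = np.arange(1, m + 1)[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(1, m + 1) * px).sum())
    mu_y = float((np.arange(1, m + 1) * py).sum())
    sd_x = float(np.sqrt(((np.arange(1, m + 1) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(1, m + 1) - mu_y) ** 2 * py).sum()))

    feats: dict[str, float] = {}
    feats["autocorrelation"] = float((i * j * p).sum())
    feats["contrast"] = float(((i - j) ** 2 * p).sum())
    if sd_x * sd_y == 0:
        warnings.warn("degenerate texture: zero marginal variance, correlations set to 0",
                      stacklevel=2)
        feats["correlation1"] = 0.0
        feats["correlation2"] = 0.0
    else:
        feats["correlation1"] = float(((i - mu_x) * (j - mu_y) * p).sum() / (sd_x * sd_y))
        feats["correlation2"] = float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    feats["cluster_prominence"] = float(((i + j - mu_x - mu_y) ** 4 * p).sum())
    feats["cluster_shade"] = float(((i + j - mu_x - mu_y) ** 3 * p).sum())
    feats["dissimilarity"] = float((np.abs(i - j) * p).sum())
    feats["energy"] = float((p ** 2).sum())
    nz = p[p > 0]
    feats["entropy"] = float(-(nz * np.log(nz)).sum())
    feats["homogeneity1"] = float((p / (1.0 + np.abs(i - j))).sum())
    feats["homogeneity2"] = float((p / (1.0 + (i - j) ** 2)).sum())
    feats["max_probability"] = float(p.max())
    # p_{x+y}(k), k = 2..2M; sum variance about the sum average
    pxy = np.zeros(2 * m + 1)
    np.add.at(pxy, (i + j).ravel(), p.ravel())
    k = np.arange(2 * m + 1)
    sum_avg = float((k * pxy).sum())
    feats["sum_variance"] = float(((k - sum_avg) ** 2 * pxy).sum())
    return pd.Series(feats, index=list(FEATURE_NAMES), dtype=float)


def extract_features(images, labels, offsets=None, n_levels: int = 8,
                     symmetric: bool = True, aggregation: str = "mean") -> pd.DataFrame:
    """Per-image texture features aggregated over a set of offsets.

    Parameters
    ----------
    images : sequence of GrayImage or 2-D integer arrays (8-bit assumed)
    labels : sequence of class labels, one per image
    offsets : list of OffsetSpec, default the 16-offset d=1..4 x 4-angle grid
    n_levels : gray levels for quantization (default 8)
    aggregation : "mean" averages the per-offset feature vectors (the
        default, rotation-robust choice); "none" emits one row per
        image/offset pair with `distance` and `angle` columns.

    Returns a DataFrame with one feature column per name and a final
    ``class`` column.  Images that fail to process are skipped with a
    warning; an empty result raises.
    """
    if offsets is None:
        offsets = default_offsets()
    if not offsets:
        raise ValueError("at least one offset is required")
    if aggregation not in ("mean", "none"):
        raise ValueError("aggregation must be 'mean' or 'none'")
    labels = list(labels)
    if len(labels) != len(images):
        raise ValueError("images and labels differ in length")

    rows = []
    for idx, (img, lab) in enumerate(zip(images, labels)):
        try:
            if not isinstance(img, GrayImage):
                img = GrayImage(np.asarray(img))
            q = quantize(img, n_levels)
            per_offset = [
                haralick_features(cooccurrence(q, off, symmetric=symmetric, n_levels=n_levels))
                for off in offsets
            ]
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            warnings.warn(f"skipping image {idx}: {exc}", stacklevel=2)
            continue
        if aggregation == "mean":
            row = pd.concat(per_offset, axis=1).mean(axis=1)
            row["class"] = lab
            rows.append(row)
        else:
            for off, vec in zip(offsets, per_offset):
                vec = vec.copy()
                vec["distance"] = off.distance
                vec["angle"] = off.angle
                vec["class"] = lab
                rows.append(vec)
    if not rows:
        raise ValueError("no images could be processed")
    table = pd.DataFrame(rows).reset_index(drop=True)
    return table
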