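"""File round-trips: images, feature/state CSVs, network JSON."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .bayesnet import TreeNetwork
from .discretize import DiscreteTable
from .glcm import GrayImage

__all__ = [
    "read_image", "read_images_with_labels",
    "read_feature_csv", "write_feature_csv",
    "read_network_json", "write_network_json",
    "write_discrete_csv", "read_discrete_csv",
]


def read_image(path) -> GrayImage:
    """Read an 8-bit grayscale PNG/TIFF; RGB inputs are averaged."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return GrayImage(np.rint(arr).astype(np.int64), bit_depth=8)


def read_images_with_labels(image_dir, labels_csv) -> tuple[list[GrayImage], list[str]]:
    """Load images named in a two-column (filename, class) CSV."""
    table = pd.read_csv(labels_csv)
    if table.shape[1] < 2:
        raise ValueError("labels CSV needs two columns: filename, class")
    fname_col, class_col = table.columns[0], table.columns[1]
    images, labels = [], []
    for _, row in table.iterrows():
        images.append(read_image(Path(image_dir) / str(row[fname_col])))
        labels.append(str(row[class_col]))
    return images, labels


def read_feature_csv(path, label_col: str = "class") -> pd.DataFrame:
    """Feature table CSV: header row, one image per row, final class column."""
    table = pd.read_csv(path)
    if label_col not in table.columns:
        raise ValueError(f"feature CSV is missing the {label_col!r} column")
    na = table.isna()
    if na.any().any():
        row = int(na.any(axis=1).idxmax())
        raise ValueError(f"missing value in feature CSV at row {row}")
    return table


def write_feature_csv(table: pd.DataFrame, path, label_col: str = "class") -> None:
    cols = [c for c in table.columns if c != label_col]
    if label_col in table.columns:
        cols.append(label_col)
    table[cols].to_csv(path, index=False)


def write_discrete_csv(discrete: DiscreteTable, path) -> None:
    discrete.states.to_csv(path, index=False)


def read_discrete_csv(path, labels: dict[str, list[str]] | None = None,
                      label_col: str = "class") -> DiscreteTable:
    frame = pd.read_csv(path)
    lab = label_col if label_col in frame.columns else None
    feats = [c for c in frame.columns if c != lab]
    if labels is None:
        labels = {f: [str(s) for s in range(int(frame[f].max()) + 1)] for f in feats}
    return DiscreteTable(states=frame, labels=labels, label_col=lab)


def write_network_json(network: TreeNetwork, path) -> None:
    payload = {
        "nodes": list(network.nodes),
        "states": network.states,
        "parent": network.parent,
        "cpts": {v: c.tolist() for v, c in network.cpts.items()},
        "root": network.root,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_network_json(path) -> TreeNetwork:
    payload = json.loads(Path(path).read_text())
    return TreeNetwork(
        nodes=tuple(payload["nodes"]),
        states={v: list(s) for v, s in payload["states"].items()},
        parent={v: p for v, p in payload["parent"].items()},
        cpts={v: np.asarray(c, dtype=float) for v, c in payload["cpts"].items()},
        root=payload.get("root"),
    )
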