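"""End-to-end pipeline: extract -> rank -> discretize -> learn -> report.

The configuration is a plain YAML mapping validated against a small
schema; every stage writes its table(s) under the output directory and a
``manifest.json`` records the stage outputs, seeds, package version and
a hash of the resolved configuration, so a rerun with the same config
and seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesnet import TreeBayesNet
from .discretize import DiscretizationScheme, apply_scheme, fit_equal_frequency, fit_equal_width
from .glcm import OffsetSpec, extract_features
from .io import (read_feature_csv, read_images_with_labels, write_discrete_csv,
                 write_feature_csv, write_network_json)
from .ranking import relative_entropy_importance, select_target
from .synthetic import default_texture_specs, generate_textures

log = logging.getLogger("glcmbayes")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; every random stage draws from `seed`."""

    out_dir: str = "report"
    image_dir: str | None = None
    labels_csv: str | None = None
    features_csv: str | None = None          # precomputed features skip extraction
    synthetic: bool = False                  # no inputs: generate the study textures
    n_images_per_class: int = 100
    image_size: int = 64

    levels: int = 8
    distances: tuple[int, ...] = (1, 2, 3, 4)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    aggregation: str = "mean"

    ranking_bins: int = 10
    n_states: int = 4
    discretization: str = "equal-frequency"
    explicit_cuts: dict | None = None
    prior_count: float = 1.0
    target: str | None = None                # override the ranked target
    profile_state: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("distances", "angles"):
            if key in raw:
                raw[key] = tuple(int(x) for x in raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.discretization not in ("equal-frequency", "equal-width", "explicit"):
            raise ValueError("discretization must be equal-frequency, equal-width or explicit")
        if self.discretization == "explicit" and not self.explicit_cuts:
            raise ValueError("explicit discretization needs explicit_cuts")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def _stage(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            manifest.setdefault("stages", {}).setdefault(name, {})
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
            manifest.setdefault("stages", {}).setdefault(name, {})["seconds"] = round(dt, 3)
            return False
    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": int(config.seed),
                      "config_hash": config.config_hash(), "outputs": {}}

    def record(name: str, path: Path):
        manifest["outputs"][name] = str(path)

    # -- extract -------------------------------------------------------
    if config.features_csv:
        with _stage("extract", manifest):
            features = read_feature_csv(config.features_csv)
            manifest["outputs"]["features"] = str(config.features_csv)
            manifest["stages"]["extract"]["skipped"] = True
    else:
        with _stage("extract", manifest):
            if config.image_dir and config.labels_csv:
                images, labels = read_images_with_labels(config.image_dir, config.labels_csv)
            elif config.synthetic:
                specs = default_texture_specs(count=config.n_images_per_class,
                                              size=config.image_size)
                images, labels = generate_textures(specs, seed=config.seed)
            else:
                raise ValueError("no input images, labels or features configured")
            offsets = [OffsetSpec(d, a) for d in config.distances for a in config.angles]
            features = extract_features(images, labels, offsets=offsets,
                                        n_levels=config.levels,
                                        symmetric=config.symmetric,
                                        aggregation=config.aggregation)
            path = out / "features.csv"
            write_feature_csv(features, path)
            record("features", path)

    # -- rank ----------------------------------------------------------
    with _stage("rank", manifest):
        ranking = relative_entropy_importance(features, n_bins=config.ranking_bins)
        path = out / "ranking.csv"
        ranking.to_csv(path, index=False)
        record("ranking", path)
        target = config.target or select_target(ranking)
        manifest["target"] = target

    # -- discretize ----------------------------------------------------
    with _stage("discretize", manifest):
        if config.discretization == "explicit":
            scheme = DiscretizationScheme(
                {f: np.asarray(c, dtype=float) for f, c in config.explicit_cuts.items()})
        elif config.discretization == "equal-width":
            scheme = fit_equal_width(features, n_states=config.n_states)
        else:
            scheme = fit_equal_frequency(features, n_states=config.n_states)
        discrete = apply_scheme(features, scheme)
        spath = out / "scheme.json"
        spath.write_text(scheme.to_json())
        record("scheme", spath)
        dpath = out / "states.csv"
        write_discrete_csv(discrete, dpath)
        record("states", dpath)

    # -- learn + fit ---------------------------------------------------
    with _stage("learn", manifest):
        model = TreeBayesNet(discrete, features=features, target=target)
        results = model.fit(prior_count=config.prior_count)
        npath = out / "network.json"
        write_network_json(results.network, npath)
        record("network", npath)
        manifest["mdl_bits"] = results.mdl.total

    # -- analyze -------------------------------------------------------
    with _stage("analyze", manifest):
        arcs = results.arc_strengths()
        arcs.to_csv(out / "arc_strengths.csv", index=False)
        record("arc_strengths", out / "arc_strengths.csv")
        forces = results.node_forces()
        forces.to_csv(out / "node_forces.csv", index=False)
        record("node_forces", out / "node_forces.csv")
        tt = results.target_table()
        tt.to_csv(out / "target_table.csv", index=False)
        record("target_table", out / "target_table.csv")

    # -- profile -------------------------------------------------------
    with _stage("profile", manifest):
        state = config.profile_state
        torn = results.tornado(state)
        torn.to_csv(out / "tornado.csv", index=False)
        record("tornado", out / "tornado.csv")
        steps = results.dynamic_profile(state)
        prof = pd.DataFrame([{
            "step": i, "node": s.node, "state": s.state_label,
            "posterior_pct": 100 * s.posterior_prob,
            "marginal_likelihood_pct": 100 * s.marginal_likelihood,
            "likelihood_pct": 100 * s.likelihood,
            "bayes_factor": s.bayes_factor,
            "generalized_bayes_factor": s.generalized_bayes_factor,
        } for i, s in enumerate(steps)])
        prof.to_csv(out / "dynamic_profile.csv", index=False)
        record("dynamic_profile", out / "dynamic_profile.csv")
        seg = results.segment_profile(seed=config.seed, best_samples=4000)
        seg.to_csv(out / "segment_profile.csv", index=False)
        record("segment_profile", out / "segment_profile.csv")

    # -- evaluate ------------------------------------------------------
    with _stage("evaluate", manifest):
        perf = results.evaluate_target()
        perf.per_state.to_csv(out / "performance.csv", index=False)
        record("performance", out / "performance.csv")
        manifest["performance"] = {"r": perf.r, "r2": perf.r2,
                                   "rmse": perf.rmse, "nrmse": perf.nrmse}

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
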