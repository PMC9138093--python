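"""End-to-end pipeline: simulate -> extract -> select -> classify -> report.

A flat key-value config file drives every stage; the master seed
deterministically derives per-stage seeds, and a manifest records versions,
seeds and output checksums so any stage can be rerun from its predecessor's
files with identical results.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSpec, PreferenceBenchmark
from .importance import anova_f, correlation_heatmap_table
from .indices import INDEX_NAMES
from .selection import FeatureTable, importance_rank, mrmr_rank, pca_transform, relieff_rank, rfe_select
from .spectral import full_feature_table, index_feature_table, write_feature_table
from .synthgen import LabeledEpochSet, SynthConfig, make_dataset, write_epochs

#: Epoch files are only written for datasets up to this many epochs unless
#: forced: the long-format text dump grows ~200 kB per epoch.
EPOCH_WRITE_LIMIT = 200

_BOOL = {"true": True, "false": False}


@dataclass
class PipelineConfig:
    """Validated flat configuration for :func:`run_pipeline`."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    features: str = "indices"  # "indices" or "full"
    selectors: tuple[str, ...] = ("none", "mrmr", "relieff", "rfe", "importance", "pca")
    k: int = 10
    classifiers: tuple[str, ...] = ("lda", "svm_rbf", "rf", "mlp_hinge", "knn")
    train_fraction: float = 0.8
    seed: int = 0
    write_epochs: str = "auto"  # auto | true | false

    def __post_init__(self) -> None:
        if self.features not in ("indices", "full"):
            raise ValueError("features must be 'indices' or 'full'")
        if self.write_epochs not in ("auto", "true", "false"):
            raise ValueError("write_epochs must be auto, true or false")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a ``key = value`` text file; unknown keys are rejected."""
        synth_keys = {
            "n_subjects": int, "n_trials_per_subject": int, "epoch_seconds": float,
            "asymmetry_effect": float, "pink_noise_sd": float, "subject_sd": float,
        }
        own_keys = {
            "features": str, "k": int, "train_fraction": float, "seed": int,
            "write_epochs": str,
        }
        synth_kwargs, kwargs = {}, {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key in synth_keys:
                synth_kwargs[key] = synth_keys[key](value)
            elif key in own_keys:
                kwargs[key] = own_keys[key](value)
            elif key == "selectors":
                kwargs["selectors"] = tuple(s.strip() for s in value.split(","))
            elif key == "classifiers":
                kwargs["classifiers"] = tuple(s.strip() for s in value.split(","))
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        seed = kwargs.get("seed", 0)
        return cls(synth=SynthConfig(seed=seed, **synth_kwargs), **kwargs)


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, t0: float) -> None:
    print(f"[neuropref] {stage}: {time.perf_counter() - t0:.1f}s", file=sys.stderr)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, write all artifacts, return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.seed,
        "stages": {},
        "files": {},
    }

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            if not p.exists() or p.stat().st_size == 0:
                raise RuntimeError(f"stage {stage!r} produced no output at {p}")
            manifest["files"][p.name] = _sha256(p)

    try:
        # --- simulate ------------------------------------------------------
        t0 = time.perf_counter()
        dataset = make_dataset(config.synth)
        labels_path = out / "labels.csv"
        pd.DataFrame({
            "subject": [ep.subject_id for ep in dataset.epochs],
            "trial": [ep.trial_id for ep in dataset.epochs],
            "label": [ep.label for ep in dataset.epochs],
        }).to_csv(labels_path, index=False)
        do_write = config.write_epochs == "true" or (
            config.write_epochs == "auto" and len(dataset) <= EPOCH_WRITE_LIMIT
        )
        if do_write:
            write_epochs(dataset, out / "epochs.csv", labels_path)
            record("simulate", out / "epochs.csv")
        record("simulate", labels_path)
        manifest["stages"]["simulate"] = {"n_epochs": len(dataset)}
        _log("simulate", t0)

        # --- extract -------------------------------------------------------
        t0 = time.perf_counter()
        if config.features == "full":
            features = full_feature_table(dataset)
        else:
            features = index_feature_table(dataset)
        write_feature_table(features, out / "features.csv")
        index_cols = ["subject", "trial", "label"] + [
            f"index_{n}" for n in INDEX_NAMES
        ]
        indices_df = (
            features[index_cols]
            if set(index_cols) <= set(features.columns)
            else index_feature_table(dataset)
        )
        indices_df.to_csv(out / "indices.csv", index=False)
        record("extract", out / "features.csv", out / "indices.csv")
        manifest["stages"]["extract"] = {"n_features": features.shape[1] - 3}
        _log("extract", t0)

        # --- select --------------------------------------------------------
        t0 = time.perf_counter()
        table = FeatureTable.from_dataframe(features)
        sel_frames = []
        sel_seed = _stage_seed(config.seed, "select")
        for name in config.selectors:
            if name == "none":
                continue
            if name == "pca":
                _, ratios = pca_transform(table, n_components=min(config.k, table.n_trials, table.n_features))
                sel_frames.append(pd.DataFrame({
                    "rank": np.arange(1, len(ratios) + 1),
                    "feature": [f"pc{j + 1}" for j in range(len(ratios))],
                    "score": ratios,
                    "method": "pca",
                }))
                continue
            # ReliefF needs more class members than neighbours; shrink on tiny runs
            relieff_nn = min(10, int(np.bincount(table.labels).min()) - 1)
            fn = {
                "mrmr": lambda: mrmr_rank(table, k=config.k),
                "relieff": lambda: relieff_rank(table, k=config.k, n_neighbors=relieff_nn),
                "rfe": lambda: rfe_select(table, n_select=config.k, seed=sel_seed),
                "importance": lambda: importance_rank(table, k=config.k, seed=sel_seed),
            }[name]
            sel_frames.append(fn().to_frame())
        pd.concat(sel_frames, ignore_index=True).to_csv(out / "selection.csv", index=False)
        record("select", out / "selection.csv")
        manifest["stages"]["select"] = {"selectors": list(config.selectors), "k": config.k}
        _log("select", t0)

        # --- importance ----------------------------------------------------
        t0 = time.perf_counter()
        f_stats = anova_f(table)
        pd.DataFrame({"feature": table.feature_names, "anova_f": f_stats}).to_csv(
            out / "importance.csv", index=False
        )
        top = importance_rank(
            table, k=min(10, table.n_features), seed=_stage_seed(config.seed, "importance")
        )
        corr = correlation_heatmap_table(table, top.selected)
        corr.write(out / "correlation.csv")
        record("importance", out / "importance.csv", out / "correlation.csv")
        manifest["stages"]["importance"] = {"top_features": top.selected}
        _log("importance", t0)

        # --- classify ------------------------------------------------------
        t0 = time.perf_counter()
        cls_seed = _stage_seed(config.seed, "classify")
        specs = [ClassifierSpec(kind, seed=cls_seed) for kind in config.classifiers]
        train_min_class = int(config.train_fraction * np.bincount(table.labels).min())
        bench = PreferenceBenchmark(
            table,
            selectors=list(config.selectors),
            specs=specs,
            k=config.k,
            train_fraction=config.train_fraction,
            selector_params={"relieff": {"n_neighbors": min(10, train_min_class - 1)}},
        )
        results = bench.fit(seed=cls_seed)
        results.write(out / "report.csv", out / "report_full.csv")
        record("classify", out / "report.csv", out / "report_full.csv")
        manifest["stages"]["classify"] = {
            "seed": cls_seed,
            "best_accuracy": results.best().accuracy,
        }
        _log("classify", t0)
    except Exception as exc:
        print(f"[neuropref] pipeline failed: {exc}", file=sys.stderr)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
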