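"""End-to-end pipeline: config parsing, stage orchestration, provenance.

A :class:`PipelineConfig` is a nested YAML document with sections
``simulate`` (or ``data`` pointing at counts/labels files), ``deg``,
``evaluate``, ``wgan`` and ``cnn``, plus a global ``seed`` and ``out_dir``.
Unknown keys are rejected. ``run_all`` executes simulate/load -> DE ->
cross-validated augment/train/score and writes every artifact together with
a manifest (config, seed, input hash, package versions). The metrics JSON
contains no timestamps, so identical configs reproduce it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import txclass
from txclass import io
from txclass.cnn import ClassifierTrainConfig
from txclass.containers import DataError
from txclass.deg import SelectionThresholds, run_deg
from txclass.evaluate import CVConfig, CVResult, cross_validate
from txclass.sim import CohortSpec, simulate_counts
from txclass.wgan import CriticConfig, GeneratorConfig, WGANTrainConfig


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


_SECTIONS = ("simulate", "data", "deg", "evaluate", "wgan", "cnn")
_TOP_KEYS = _SECTIONS + ("seed", "out_dir")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "txclass_out"
    simulate: CohortSpec | None = None
    counts_path: str | None = None
    labels_path: str | None = None
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    cv: CVConfig = field(default_factory=CVConfig)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_TOP_KEYS)
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        seed = int(raw.get("seed", 0))
        out_dir = str(raw.get("out_dir", "txclass_out"))

        sim_cfg = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"] or {})
            _check_keys(sim_raw, CohortSpec, "simulate")
            for key in ("class_sizes", "baseline_log_mean_range", "libsize_factor_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim_raw.setdefault("seed", seed)
            try:
                sim_cfg = CohortSpec(**sim_raw)
            except (DataError, TypeError) as exc:
                raise ConfigError(f"simulate section: {exc}") from exc

        counts_path = labels_path = None
        if "data" in raw:
            data = dict(raw["data"] or {})
            unknown = set(data) - {"counts", "labels"}
            if unknown:
                raise ConfigError(f"unknown data keys: {sorted(unknown)}")
            counts_path = data.get("counts")
            labels_path = data.get("labels")
        if sim_cfg is None and (counts_path is None or labels_path is None):
            raise ConfigError(
                "config needs either a 'simulate' section or a 'data' section "
                "with both 'counts' and 'labels' paths"
            )

        deg_raw = dict(raw.get("deg") or {})
        _check_keys(deg_raw, SelectionThresholds, "deg")
        try:
            thresholds = SelectionThresholds(**deg_raw)
        except DataError as exc:
            raise ConfigError(f"deg section: {exc}") from exc

        wgan_raw = dict(raw.get("wgan") or {})
        wgan_keys = {
            "learning_rate",
            "batch_size",
            "epochs",
            "clip_value",
            "n_critic",
            "noise_dim",
            "generator_hidden",
            "critic_hidden",
            "target_per_class",
        }
        unknown = set(wgan_raw) - wgan_keys
        if unknown:
            raise ConfigError(f"unknown wgan keys: {sorted(unknown)}")
        gen_cfg = GeneratorConfig(
            noise_dim=int(wgan_raw.get("noise_dim", 100)),
            layer_widths=(*map(int, wgan_raw.get("generator_hidden", (512, 1024))), 1),
        )
        critic_cfg = CriticConfig(
            layer_widths=(1, *map(int, wgan_raw.get("critic_hidden", (512, 256))), 1)
        )
        try:
            wgan_train = WGANTrainConfig(
                learning_rate=float(wgan_raw.get("learning_rate", 1e-4)),
                batch_size=int(wgan_raw.get("batch_size", 16)),
                epochs=int(wgan_raw.get("epochs", 200)),
                clip_value=float(wgan_raw.get("clip_value", 0.01)),
                n_critic=int(wgan_raw.get("n_critic", 5)),
                seed=seed,
            )
        except DataError as exc:
            raise ConfigError(f"wgan section: {exc}") from exc

        cnn_raw = dict(raw.get("cnn") or {})
        arch_keys = {
            "conv_channels",
            "kernel_size",
            "n_conv_blocks",
            "pool",
            "attention_kernel",
            "dropout_rate",
            "fc_hidden",
        }
        train_keys = {"learning_rate", "batch_size", "max_epochs", "patience", "val_fraction"}
        unknown = set(cnn_raw) - arch_keys - train_keys
        if unknown:
            raise ConfigError(f"unknown cnn keys: {sorted(unknown)}")
        cnn_overrides = tuple((k, cnn_raw[k]) for k in sorted(arch_keys & set(cnn_raw)))
        try:
            clf_train = ClassifierTrainConfig(
                **{k: cnn_raw[k] for k in train_keys & set(cnn_raw)}, seed=seed
            )
        except DataError as exc:
            raise ConfigError(f"cnn section: {exc}") from exc

        ev_raw = dict(raw.get("evaluate") or {})
        ev_keys = {"k", "selector", "n_features", "augmenter", "classifier", "global_panel", "ddof"}
        unknown = set(ev_raw) - ev_keys
        if unknown:
            raise ConfigError(f"unknown evaluate keys: {sorted(unknown)}")
        try:
            cv = CVConfig(
                thresholds=thresholds,
                k=int(ev_raw.get("k", 5)),
                seed=seed,
                selector=str(ev_raw.get("selector", "deseq")),
                n_features=int(ev_raw.get("n_features", 300)),
                augmenter=str(ev_raw.get("augmenter", "wgan")),
                target_per_class=int(wgan_raw.get("target_per_class", 1000)),
                classifier=str(ev_raw.get("classifier", "cnn")),
                global_panel=bool(ev_raw.get("global_panel", False)),
                gen_cfg=gen_cfg,
                critic_cfg=critic_cfg,
                wgan_train=wgan_train,
                cnn_overrides=cnn_overrides,
                clf_train=clf_train,
                ddof=int(ev_raw.get("ddof", 0)),
            )
        except DataError as exc:
            raise ConfigError(f"evaluate section: {exc}") from exc

        return PipelineConfig(
            seed=seed,
            out_dir=out_dir,
            simulate=sim_cfg,
            counts_path=counts_path,
            labels_path=labels_path,
            thresholds=thresholds,
            cv=cv,
        )

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a YAML mapping")
        return PipelineConfig.from_dict(raw)

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "out_dir": self.out_dir}
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        if self.counts_path is not None:
            out["data"] = {"counts": self.counts_path, "labels": self.labels_path}
        out["deg"] = dataclasses.asdict(self.thresholds)
        cv = dataclasses.asdict(self.cv)
        cv["cnn_overrides"] = dict(self.cv.cnn_overrides)
        out["evaluate"] = cv
        return out


def _check_keys(raw: dict, cls, section: str) -> None:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown {section} keys: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> CVResult:
    """Execute the whole pipeline and populate ``cfg.out_dir``.

    Writes counts/labels (when simulated), per-contrast DEG tables and the
    panel from a whole-cohort DE pass (reporting artifacts; fold-internal
    selection is separate), metrics.json, per-fold predictions, and a
    manifest with config, input hashes and versions.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate is not None:
        cm, truth = simulate_counts(cfg.simulate)
        io.write_counts(cm, out / "counts.tsv", out / "labels.tsv")
        io.write_truth(truth, out / "truth.tsv")
    else:
        cm = io.read_counts(cfg.counts_path, cfg.labels_path)

    tables, panel, sf, _ = run_deg(cm, cfg.thresholds)
    for cid, table in tables.items():
        io.write_deg_table(table, out / f"deg_{cid}.tsv")
    io.write_panel(panel, out / "panel.txt")
    sf.rename_axis("sample_id").to_frame().to_csv(out / "size_factors.tsv", sep="\t")

    result = cross_validate(cm, cfg.cv)
    metrics = {
        "per_fold": [m.as_dict() for m in result.fold_metrics],
        "summary": result.summary,
        "panel_sizes": result.panel_sizes,
        "n_samples": cm.n_samples,
        "n_genes": cm.n_genes,
    }
    io.write_json(metrics, out / "metrics.json")
    result.predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    io.write_json(
        {f"fold_{i}": ids for i, ids in enumerate(result.folds)}, out / "folds.json"
    )

    manifest = {
        "config": cfg.to_dict(),
        "package": {"name": "txclass", "version": txclass.__version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {
            "counts_sha256": _sha256(out / "counts.tsv")
            if cfg.simulate is not None
            else _sha256(Path(cfg.counts_path)),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    io.write_json(manifest, out / "manifest.json")
    return result
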