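"""End-to-end experiment orchestration with seeding and manifests.

``run_experiment`` composes the full study loop on synthetic data:
synthesize charts -> digitize them back to signals -> standardize to model
inputs -> stratified k-fold cross-validation of the CBAM-EfficientNet ->
aggregated fold report.  Every stage draws its randomness from the single
configured seed, and a manifest (config hash, seed, versions) is written
next to the outputs so any artifact can be regenerated.

The default experiment scale targets a single CPU: a compound-scaled-down
network variant (width x0.25, depth x0.5, 56x56 inputs) and a from-scratch
learning rate; see docs/methods.md for the rationale and the full-size
defaults.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chart_synthesis import NON_REASSURING, ChartLayout, make_dataset
from .digitization import digitize_chart, standardize_to_input
from .evaluation import (FoldReport, aggregate_folds, evaluate_scores,
                         stratified_kfold)
from .model import TrainConfig, build_network, predict_scores, train_model
from .pipeline_labels import RecordLabel, map_label  # noqa: F401 (public API)


@dataclass
class RunConfig:
    """Configuration for one synthetic-data experiment."""

    n_samples: int = 400
    class_ratio: float = 0.5
    seed: int = 0
    cv_folds: int = 5
    image_size: int = 56
    width_mult: float = 0.25
    depth_mult: float = 0.5
    out_rate: float = 4.0
    label_scheme: str = "figo_binary"
    out_dir: str | None = None
    layout_path: str | None = None
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=3e-3, batch_size=16,
                                            max_epochs=10))

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_layout(path: str | None) -> ChartLayout:
    if path is None:
        return ChartLayout()
    import yaml

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"layout file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    if "page_size" in raw:
        raw["page_size"] = tuple(raw["page_size"])
    if "region_boxes" in raw and raw["region_boxes"] is not None:
        raw["region_boxes"] = [tuple(b) for b in raw["region_boxes"]]
    if "grid_spacing" in raw:
        raw["grid_spacing"] = tuple(raw["grid_spacing"])
    return ChartLayout(**raw)


def build_model_inputs(cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize, digitize and standardize a dataset; returns (X, y)."""
    layout = _load_layout(cfg.layout_path)
    dataset = make_dataset(cfg.n_samples, cfg.class_ratio, cfg.seed, layout)
    X = np.empty((cfg.n_samples, 3, cfg.image_size, cfg.image_size))
    y = np.empty(cfg.n_samples, dtype=int)
    for i, (chart, truth) in enumerate(dataset):
        fhr, uc = digitize_chart(chart, layout, out_rate=cfg.out_rate)
        X[i] = standardize_to_input(fhr, uc, size=cfg.image_size).tensor
        y[i] = 1 if truth.label == NON_REASSURING else 0
    return X, y


def run_holdout(cfg: RunConfig | None = None):
    """Single stratified-holdout smoke experiment.

    Synthesize -> digitize -> standardize -> train on four fifths of the
    data with one fifth held out for validation/early stopping -> evaluate
    on that held-out fifth.  Returns ``(metrics, confusion, history)``.
    """
    cfg = cfg or RunConfig()
    _load_layout(cfg.layout_path)
    X, y = build_model_inputs(cfg)
    folds = stratified_kfold(y, k=5, seed=cfg.seed)
    held = folds == 0
    net = build_network(width_mult=cfg.width_mult, depth_mult=cfg.depth_mult,
                        input_size=cfg.image_size, seed=cfg.train.seed)
    net, history = train_model(net, X[~held], y[~held], X[held], y[held],
                               cfg.train)
    scores = predict_scores(net, X[held])
    metrics, cm = evaluate_scores(scores, y[held].astype(bool))
    return metrics, cm, history


def run_experiment(cfg: RunConfig | None = None) -> FoldReport:
    """Full synthetic experiment under stratified k-fold cross-validation.

    Each fold trains a freshly initialized scaled network on the remaining
    folds (with an inner stratified validation split for early stopping) and
    is scored on its held-out fold.  Writes ``report.json`` and
    ``manifest.json`` to ``cfg.out_dir`` when set.
    """
    cfg = cfg or RunConfig()
    # fail fast on config errors before any compute
    _load_layout(cfg.layout_path)
    X, y = build_model_inputs(cfg)

    folds = stratified_kfold(y, k=cfg.cv_folds, seed=cfg.seed)
    per_fold, histories = [], []
    for fold in range(cfg.cv_folds):
        test = folds == fold
        train_idx = np.flatnonzero(~test)
        # inner validation split for early stopping
        inner = stratified_kfold(y[train_idx], k=5, seed=cfg.seed + fold)
        val_idx = train_idx[inner == 0]
        fit_idx = train_idx[inner != 0]

        net = build_network(width_mult=cfg.width_mult,
                            depth_mult=cfg.depth_mult,
                            input_size=cfg.image_size,
                            seed=cfg.train.seed + fold)
        fold_cfg = TrainConfig(**{**asdict(cfg.train),
                                  "seed": cfg.train.seed + fold})
        net, history = train_model(net, X[fit_idx], y[fit_idx],
                                   X[val_idx], y[val_idx], fold_cfg)
        scores = predict_scores(net, X[test])
        per_fold.append(evaluate_scores(scores, y[test].astype(bool)))
        histories.append(history)

    report = aggregate_folds(per_fold)
    if cfg.out_dir is not None:
        _write_artifacts(cfg, report, histories)
    return report


def _write_artifacts(cfg: RunConfig, report: FoldReport,
                     histories: list) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "python_version": platform.python_version(),
        "n_epochs_per_fold": [len(h["val_loss"]) for h in histories],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
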