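"""Leakage-safe stratified k-fold cross-validation with optional A-SMOTE.

The default scope resamples the *training partition only* inside each fold,
so no synthetic point — interpolated, in part, from held-out rows — can leak
into a test fold.  A ``global`` scope that resamples once before splitting
is available for replicating pipelines that oversample the whole dataset
first; it emits a prominent leakage warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import Dataset
from .errors import ConfigError, UnknownModelError
from .learners import build_model
from .metrics import ConfusionCounts, MetricsReport, compute_report
from .resample import asmote_resample


@dataclass
class CVConfig:
    """Cross-validation settings.

    k defaults to 10-fold stratified CV with seeded shuffling; ``resample``
    chooses no preprocessing or A-SMOTE, and ``resample_scope`` decides
    whether oversampling happens inside each training fold (leakage-safe)
    or once globally before splitting.
    """

    model: str = "nb"
    k: int = 10
    seed: int = 0
    resample: str = "none"          # none | asmote
    resample_scope: str = "train-only"  # train-only | global
    k_neighbors: int = 5
    boost_rounds: int = 50
    combine: str = "soft"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.resample not in ("none", "asmote"):
            raise ConfigError(f"unknown resample {self.resample!r}")
        if self.resample_scope not in ("train-only", "global"):
            raise ConfigError(f"unknown resample_scope {self.resample_scope!r}")


@dataclass
class FoldRecord:
    fold: int
    test_indices: np.ndarray
    n_train_original: int
    n_train_augmented: int
    skipped: bool = False
    resample_counts: dict = field(default_factory=dict)


@dataclass
class CVResult:
    """Per-fold and pooled metrics for one model configuration.

    The pooled (micro-averaged) report is computed from the concatenated
    out-of-fold predictions, so its confusion counts equal the sum of the
    per-fold counts; ``macro`` holds the per-fold metric means.
    """

    per_fold: list
    pooled: MetricsReport
    macro: dict
    folds: list
    config: CVConfig
    warnings: list = field(default_factory=list)


def stratified_folds(y, k: int, seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Deterministic stratified partition into k folds.

    Indices of each class are shuffled and dealt round-robin, so per-fold
    counts of every class differ by at most one.  A class with fewer than k
    members still partitions validly (some folds simply miss it) but a
    warning notes the relaxed stratification.
    """
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ConfigError(f"k={k} exceeds the number of samples n={n}")
    if k < 2:
        raise ConfigError("k must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls} has only {len(idx)} samples for k={k}: stratification relaxed",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[(offset + i) % k].append(int(j))
        offset += len(idx)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _subset(d: Dataset, idx: np.ndarray) -> Dataset:
    return Dataset(
        X=d.X[idx], y=d.y[idx], columns=list(d.columns),
        positive_label=d.positive_label, negative_label=d.negative_label,
        target_name=d.target_name,
    )


def run_cv(d: Dataset, cfg: CVConfig) -> CVResult:
    """Stratified k-fold CV of one model, with optional A-SMOTE.

    Every source of randomness (fold shuffling, candidate interpolation,
    bootstrap draws) flows from ``cfg.seed``, so results are reproducible
    bit for bit.  Folds whose training partition collapses to one class are
    skipped and recorded.
    """
    rng = np.random.default_rng(cfg.seed)
    notes: list[str] = []

    data = d
    if cfg.resample == "asmote" and cfg.resample_scope == "global":
        warnings.warn(
            "global-scope resampling synthesizes points from the full dataset "
            "before splitting: test folds are contaminated (leakage)",
            stacklevel=2,
        )
        notes.append("leakage: global-scope resampling active")
        res = asmote_resample(d, k_neighbors=cfg.k_neighbors, rng=rng)
        data = res.augmented

    folds = stratified_folds(data.y, cfg.k, rng)
    all_idx = np.arange(data.n_samples)
    per_fold: list[MetricsReport] = []
    records: list[FoldRecord] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []

    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train = _subset(data, train_idx)
        rec = FoldRecord(fold=i, test_indices=test_idx,
                         n_train_original=len(train_idx),
                         n_train_augmented=len(train_idx))
        if len(np.unique(train.y)) < 2 or len(test_idx) == 0:
            rec.skipped = True
            records.append(rec)
            notes.append(f"fold {i} skipped: single-class training partition")
            warnings.warn(f"fold {i} skipped: single-class training partition", stacklevel=2)
            continue
        if cfg.resample == "asmote" and cfg.resample_scope == "train-only":
            res = asmote_resample(train, k_neighbors=cfg.k_neighbors, rng=rng)
            train = res.augmented
            rec.n_train_augmented = train.n_samples
            rec.resample_counts = {
                "n_requested": res.n_requested,
                "n_accepted": res.n_accepted,
                "n_removed": res.n_removed,
            }
        model = build_model(cfg.model, T=cfg.boost_rounds, combine=cfg.combine)
        model.fit(train, rng=rng)
        y_pred = model.predict(data.X[test_idx])
        per_fold.append(compute_report(data.y[test_idx], y_pred))
        pooled_true.append(data.y[test_idx])
        pooled_pred.append(y_pred)
        records.append(rec)

    if not per_fold:
        raise ConfigError("all folds were skipped; cannot evaluate")
    pooled = compute_report(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    macro = {
        name: float(np.mean([getattr(r, name) for r in per_fold]))
        for name in ("accuracy", "precision", "recall", "f1", "mae", "rmse", "rae", "rrse")
    }
    return CVResult(per_fold=per_fold, pooled=pooled, macro=macro,
                    folds=records, config=cfg, warnings=notes)


#: row layout of the comparison tables (accuracy/RAE/RRSE printed as %)
TABLE_ROWS = ["Accuracy (%)", "MAE", "RMSE", "RAE (%)", "RRSE (%)", "F1-score"]


def model_grid_report(d: Dataset, models: list[str], cfg: CVConfig) -> pd.DataFrame:
    """Run CV for every named model and lay the pooled metrics out as a
    metrics-by-models table."""
    if len(set(models)) != len(models):
        raise UnknownModelError(f"duplicate model names in grid: {models}")
    table: dict[str, list[float]] = {}
    for name in models:
        build_model(name)  # fail fast on unknown names before any CV work
        result = run_cv(d, replace(cfg, model=name))
        m = result.pooled
        table[name] = [m.accuracy * 100, m.mae, m.rmse, m.rae * 100, m.rrse * 100, m.f1]
    return pd.DataFrame(table, index=TABLE_ROWS)
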