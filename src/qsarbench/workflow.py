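"""Factorial benchmarking harness.

One full run walks a grid of (dataset size NS, train/test split ratio SR,
algorithm ML) cells.  For each cell the pipeline is: balance the dataset to
the minority-class size (balance_reps repetitions), draw a stratified
subsample of NS rows (sample_reps repetitions; the sentinel ``"total"``
keeps everything and collapses this loop), split into train/test at SR
percent training (split_reps repetitions), then fit the algorithm and score
it twice -- a stratified k-fold cross-validation on the training part
(battery computed on the pooled out-of-fold predictions) and a test
validation on the held-out part.  With default repetitions (5, 5, 5) this
yields 125 models per cell, each contributing one CV and one test record.

Seeds for every random stage are spawned deterministically from the master
seed and the loop indices, so an identical config reproduces an identical
results table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .adapters import AlgorithmSpec, train_and_score
from .metrics import METRIC_NAMES, InputError, MetricConfig, PredictionSet, metric_battery
from .synthetic import DescriptorTable, ParameterError, _child_rng

logger = logging.getLogger(__name__)

TOTAL = "total"

#: long-format results header (the machine form of the benchmark's
#: one-row-per-(model, validation) results structure)
RESULT_KEY_COLUMNS = ("ML", "SR", "NS", "balance_rep", "sample_rep", "split_rep", "Split")


class DegenerateSplitError(ValueError):
    """A split leaves some class too small for stratified CV."""


@dataclass(frozen=True)
class GridConfig:
    """The experiment design: factor levels and repetition counts."""

    ns_levels: tuple = (100, 500, 1000, TOTAL)
    sr_levels: tuple = (50, 60, 70, 80)
    balance_reps: int = 5
    sample_reps: int = 5
    split_reps: int = 5
    cv_folds: int = 5
    algorithms: tuple = ()
    master_seed: int = 0
    stratified: bool = True
    metric_config: MetricConfig = MetricConfig()

    def __post_init__(self) -> None:
        if any(not (0 < sr < 100) for sr in self.sr_levels):
            raise ParameterError("sr_levels must be in (0, 100)")
        if min(self.balance_reps, self.sample_reps, self.split_reps) < 1:
            raise ParameterError("repetition counts must be >= 1")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        for ns in self.ns_levels:
            if ns != TOTAL and int(ns) < 1:
                raise ParameterError("ns levels must be positive or 'total'")

    def models_per_cell(self, ns) -> int:
        reps = self.balance_reps * self.split_reps
        return reps if ns == TOTAL else reps * self.sample_reps

    def config_hash(self) -> str:
        blob = json.dumps({
            "ns": list(self.ns_levels), "sr": list(self.sr_levels),
            "reps": [self.balance_reps, self.sample_reps, self.split_reps],
            "cv_folds": self.cv_folds, "seed": self.master_seed,
            "algorithms": [(a.name, sorted(a.settings.items())) for a in self.algorithms],
            "stratified": self.stratified,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultsTable:
    """Long-format collection of per-model metric batteries plus provenance."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    @property
    def n_models(self) -> int:
        key = ["ML", "SR", "NS", "balance_rep", "sample_rep", "split_rep"]
        return 0 if self.frame.empty else len(self.frame[key].drop_duplicates())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ResultsTable":
        return cls(frame=pd.read_csv(path))


# ---------------------------------------------------------------------------
# sampling stages
# ---------------------------------------------------------------------------

def balance_dataset(table: DescriptorTable, seed: int = 0) -> DescriptorTable:
    """Equal-balance undersampling: keep the minority-class count from every
    class, drawing majority-class rows uniformly without replacement."""
    counts = table.class_counts()
    if len(counts) < 2:
        raise InputError("balancing needs at least 2 nonempty classes")
    m = min(counts.values())
    rng = _child_rng(seed, 101)
    keep: list[np.ndarray] = []
    for c in table.classes.tolist():
        idx = np.flatnonzero(table.labels == c)
        keep.append(idx if len(idx) == m else rng.choice(idx, size=m, replace=False))
    return table.take(np.sort(np.concatenate(keep)), {"balanced_to": m})


def subsample(table: DescriptorTable, ns, seed: int = 0,
              stratified: bool = True) -> DescriptorTable:
    """Draw exactly ``ns`` rows (``"total"`` is the identity).

    Stratified mode allocates ns // K per class and hands the remainder to
    classes chosen by a seeded draw; unstratified mode is a plain uniform
    draw without replacement.
    """
    if ns == TOTAL:
        return table
    ns = int(ns)
    if ns > table.n_samples:
        raise InputError(f"requested {ns} rows from a table of {table.n_samples}")
    rng = _child_rng(seed, 102)
    if not stratified:
        return table.take(np.sort(rng.choice(table.n_samples, size=ns, replace=False)))

    classes = table.classes.tolist()
    k = len(classes)
    base, rem = divmod(ns, k)
    quota = {c: base for c in classes}
    for c in rng.choice(classes, size=rem, replace=False):
        quota[c] += 1
    keep = []
    for c in classes:
        idx = np.flatnonzero(table.labels == c)
        if quota[c] > len(idx):
            raise InputError(f"class {c!r} has {len(idx)} rows, needs {quota[c]}")
        keep.append(rng.choice(idx, size=quota[c], replace=False))
    return table.take(np.sort(np.concatenate(keep)))


def _largest_remainder(targets: np.ndarray, total: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Integer allocation summing to ``total``; fractional-remainder ties are
    broken by a seeded shuffle."""
    floors = np.floor(targets).astype(int)
    rem = targets - floors
    short = total - floors.sum()
    order = np.lexsort((rng.permutation(len(targets)), -rem))
    alloc = floors.copy()
    alloc[order[:short]] += 1
    return alloc


def split_train_test(table: DescriptorTable, sr: float, seed: int = 0,
                     cv_folds: int | None = None,
                     stratified: bool = True) -> tuple[DescriptorTable, DescriptorTable]:
    """Stratified train/test split keeping ``sr`` percent for training.

    Per-class training counts follow the largest-remainder rule so that
    |train| = round(sr/100 * N) exactly; train and test partition the input.
    """
    if not (0 < sr < 100):
        raise ParameterError("split ratio must be in (0, 100) percent")
    n = table.n_samples
    n_train = int(round(sr / 100.0 * n))
    rng = _child_rng(seed, 103)

    if stratified:
        classes = table.classes.tolist()
        counts = np.array([int((table.labels == c).sum()) for c in classes])
        alloc = _largest_remainder(counts * sr / 100.0, n_train, rng)
        train_idx = []
        for c, a, cnt in zip(classes, alloc, counts):
            if a > cnt:
                raise DegenerateSplitError(f"class {c!r}: cannot put {a} of {cnt} rows in train")
            idx = np.flatnonzero(table.labels == c)
            train_idx.append(rng.choice(idx, size=a, replace=False))
        train_idx = np.sort(np.concatenate(train_idx))
    else:
        train_idx = np.sort(rng.choice(n, size=n_train, replace=False))

    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    train, test = table.take(np.flatnonzero(mask)), table.take(np.flatnonzero(~mask))

    if cv_folds is not None:
        small = [c for c, cnt in train.class_counts().items() if cnt < cv_folds]
        if small:
            raise DegenerateSplitError(
                f"sr={sr}, N={n}: train class(es) {small} smaller than cv_folds={cv_folds}")
    return train, test


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _pooled_cv_predictions(alg: AlgorithmSpec, train: DescriptorTable,
                           cv_folds: int, seed: int) -> PredictionSet:
    """Stratified k-fold CV on the training set; out-of-fold predictions are
    pooled into one PredictionSet (one battery per model, not per fold)."""
    classes = np.unique(train.labels)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2 ** 31))
    n = train.n_samples
    scores = np.empty((n, len(classes)))
    predicted = np.empty(n, dtype=train.labels.dtype)
    for fold, (fit_idx, oof_idx) in enumerate(skf.split(train.values, train.labels)):
        pred = train_and_score(alg.with_seed(seed + fold + 1),
                               train.take(fit_idx), train.take(oof_idx))
        if len(pred.classes) != len(classes) or np.any(pred.classes != classes):
            raise InputError("CV fold lost a class; decrease cv_folds")
        scores[oof_idx] = pred.class_scores
        predicted[oof_idx] = pred.predicted_labels
    return PredictionSet(train.labels, predicted, scores, classes)


def evaluate_model(alg: AlgorithmSpec, train: DescriptorTable,
                   test: DescriptorTable, cv_folds: int, seed: int,
                   metric_config: MetricConfig) -> dict[str, "object"]:
    """One model = one CV battery (pooled out-of-fold) + one test battery."""
    cv_pred = _pooled_cv_predictions(alg, train, cv_folds, seed)
    test_pred = train_and_score(alg.with_seed(seed), train, test)
    return {
        "CV": metric_battery(cv_pred, metric_config),
        "test": metric_battery(test_pred, metric_config),
    }


def run_grid(table: DescriptorTable, config: GridConfig) -> ResultsTable:
    """Execute the full factorial benchmark on one descriptor table.

    Adapter failures and degenerate splits are recorded (cell + reason) and
    the grid continues; identical (table, config) reproduce identical output.
    """
    if not config.algorithms:
        raise ParameterError("config.algorithms must be non-empty")
    rows: list[dict] = []
    failures: list[dict] = []
    ms = config.master_seed

    for b in range(config.balance_reps):
        seed_b = int(_child_rng(ms, 1, b).integers(2 ** 31))
        balanced = balance_dataset(table, seed_b)
        for ns_i, ns in enumerate(config.ns_levels):
            sample_reps = 1 if ns == TOTAL else config.sample_reps
            for s in range(sample_reps):
                seed_s = int(_child_rng(ms, 2, b, ns_i, s).integers(2 ** 31))
                sampled = subsample(balanced, ns, seed_s, config.stratified)
                for sr_i, sr in enumerate(config.sr_levels):
                    for p in range(config.split_reps):
                        seed_p = int(_child_rng(ms, 3, b, ns_i, s, sr_i, p).integers(2 ** 31))
                        cell = {"SR": sr, "NS": str(ns), "balance_rep": b,
                                "sample_rep": s, "split_rep": p}
                        try:
                            train, test = split_train_test(
                                sampled, sr, seed_p, config.cv_folds, config.stratified)
                        except DegenerateSplitError as exc:
                            failures.append({**cell, "ML": "*", "reason": str(exc)})
                            logger.warning("degenerate split %s: %s", cell, exc)
                            continue
                        for a_i, alg in enumerate(config.algorithms):
                            seed_m = int(_child_rng(ms, 4, b, ns_i, s, sr_i, p,
                                                    a_i).integers(2 ** 31))
                            try:
                                batteries = evaluate_model(
                                    alg, train, test, config.cv_folds, seed_m,
                                    config.metric_config)
                            except Exception as exc:  # noqa: BLE001 - grid must finish
                                failures.append({**cell, "ML": alg.name, "reason": str(exc)})
                                logger.warning("model failed %s %s: %s", alg.name, cell, exc)
                                continue
                            for split_kind, battery in batteries.items():
                                rows.append({"ML": alg.name, **cell,
                                             "Split": split_kind,
                                             **battery.values})
                        logger.debug("cell done: %s", cell)

    columns = list(RESULT_KEY_COLUMNS) + list(METRIC_NAMES)
    frame = pd.DataFrame(rows, columns=columns)
    return ResultsTable(
        frame=frame,
        provenance={"config_hash": config.config_hash(),
                    "master_seed": config.master_seed},
        failures=failures,
    )


def normalize_euclidean(results: ResultsTable | pd.DataFrame,
                        columns: Sequence[str] = METRIC_NAMES):
    """Divide each metric column by its Euclidean norm over the rows analyzed
    together (this table by default; concatenate tables first to normalize
    jointly across merged studies).  All-zero columns are left as zeros."""
    frame = results.frame if isinstance(results, ResultsTable) else results
    out = frame.copy()
    for col in columns:
        norm = float(np.linalg.norm(out[col].to_numpy(dtype=float)))
        if norm == 0.0:
            logger.info("all-zero metric column %s left unnormalized", col)
            continue
        out[col] = out[col] / norm
    if isinstance(results, ResultsTable):
        return ResultsTable(out, {**results.provenance, "normalized": "euclidean"},
                            list(results.failures))
    return out


__all__ = [
    "TOTAL",
    "RESULT_KEY_COLUMNS",
    "GridConfig",
    "ResultsTable",
    "DegenerateSplitError",
    "balance_dataset",
    "subsample",
    "split_train_test",
    "evaluate_model",
    "run_grid",
    "normalize_euclidean",
]
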