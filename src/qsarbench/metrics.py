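"""The 25-parameter multiclass performance battery.

For one model evaluation (a set of true labels, predicted labels, and a
per-class score matrix) the battery computes 14 confusion-matrix parameters
and 11 ranking / early-recognition parameters.  Accuracy and Cohen's kappa
are computed on the full K x K confusion matrix; every other parameter is
computed per class one-vs-rest and macro-averaged over the classes present
in the true labels.  Early-recognition parameters (RIE, BEDROC, EF, ROC
enrichment) treat class c's score column as a virtual-screening ranking of
"actives" (class-c samples) against everything else.

Conventions (fixed once, recorded here):

* ties in the ranked list get fractional (mid) ranks for AUC/AUAC/RIE;
* relative ranks are ``x_i = r_i / N``;
* ``RIE(a) = sum_i exp(-a x_i) / [(n/N) (1 - e^-a) / (e^(a/N) - 1)]``;
* BEDROC is RIE min-max scaled onto [0, 1] using the exact best/worst
  placements (Truchon-Bailey scaling in discrete form), so a perfect ranking
  scores exactly 1 at any N;
* ``EF_f`` uses the top ``ceil(f N)`` of a stable descending sort;
* ROC enrichment is the TPR linearly interpolated at FPR = f;
* rate denominators (LRp's 1-TNR, PPV's TP+FP, ...) are clipped at
  ``epsilon`` (default 1/(2N), Haldane-style); DOR's count-product
  denominator FP*FN is clipped at a half count (0.25 = 0.5*0.5), the
  count-scale analogue, so every battery value is finite and the clipping
  ceiling does not blow up for small evaluation sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

#: canonical battery column order
METRIC_NAMES: tuple[str, ...] = (
    "RIE20", "RIE1609", "BEDROC20", "BEDROC1609",
    "EF1", "EF5", "ROC_EF1", "ROC_EF5",
    "AUAC", "AUC", "AP",
    "TPR", "TNR", "PPV", "NPV",
    "BM", "MK", "LRp", "DOR",
    "MCC", "Cohen", "ACC", "BACC", "Jaccard", "F1",
)

CONFUSION_METRIC_NAMES: tuple[str, ...] = (
    "TPR", "TNR", "PPV", "NPV", "BM", "MK", "LRp", "DOR",
    "MCC", "Cohen", "ACC", "BACC", "Jaccard", "F1",
)

RANKING_METRIC_NAMES: tuple[str, ...] = (
    "RIE20", "RIE1609", "BEDROC20", "BEDROC1609",
    "EF1", "EF5", "ROC_EF1", "ROC_EF5", "AUAC", "AUC", "AP",
)


class InputError(ValueError):
    """Invalid prediction input (label mismatch, empty set, ...)."""


@dataclass(frozen=True)
class MetricConfig:
    """Battery configuration.

    alphas:    exponential weights for RIE/BEDROC (default 20 and 160.9).
    fractions: screening fractions for EF / ROC enrichment (default 1%, 5%).
    averaging: only "macro" (one-vs-rest, unweighted over classes) is defined.
    epsilon:   denominator clip; None means 1/(2N) at battery time.
    tie_policy: "fractional" mid-ranks (the only implemented policy).
    """

    alphas: tuple[float, float] = (20.0, 160.9)
    fractions: tuple[float, float] = (0.01, 0.05)
    averaging: str = "macro"
    epsilon: float | None = None
    tie_policy: str = "fractional"

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alphas):
            raise InputError("alphas must be positive")
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise InputError("fractions must be in (0, 1)")
        if self.epsilon is not None and self.epsilon <= 0:
            raise InputError("epsilon must be positive")
        if self.averaging != "macro":
            raise InputError("only macro one-vs-rest averaging is implemented")
        if self.tie_policy != "fractional":
            raise InputError("only fractional (mid-rank) tie policy is implemented")

    def resolve_epsilon(self, n: int) -> float:
        return self.epsilon if self.epsilon is not None else 1.0 / (2 * n)


@dataclass
class PredictionSet:
    """True labels, predicted labels, and an N x K per-class score matrix.

    ``classes`` fixes the score-column order.  Score rows need not sum to 1;
    adapters may emit unnormalized (e.g. log-kernel) scores.
    """

    true_labels: np.ndarray
    predicted_labels: np.ndarray
    class_scores: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels)
        self.predicted_labels = np.asarray(self.predicted_labels)
        self.class_scores = np.asarray(self.class_scores, dtype=float)
        self.classes = np.asarray(self.classes)
        n = len(self.true_labels)
        if n == 0:
            raise InputError("empty prediction set")
        if len(self.predicted_labels) != n or self.class_scores.shape[0] != n:
            raise InputError("true/predicted/scores length mismatch")
        if self.class_scores.shape[1] != len(self.classes):
            raise InputError("score matrix needs one column per class")
        class_set = set(self.classes.tolist())
        for name, arr in (("true", self.true_labels), ("predicted", self.predicted_labels)):
            extra = set(arr.tolist()) - class_set
            if extra:
                raise InputError(f"{name} labels outside declared class set: {extra}")
        if not np.all(np.isfinite(self.class_scores)):
            raise InputError("class scores must be finite")

    @property
    def n(self) -> int:
        return len(self.true_labels)


@dataclass
class MetricVector:
    """The 25 named performance parameters for one model/validation pair."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(METRIC_NAMES) - set(self.values)
        extra = set(self.values) - set(METRIC_NAMES)
        if missing or extra:
            raise InputError(f"battery must have exactly the 25 canonical parameters "
                             f"(missing={sorted(missing)}, extra={sorted(extra)})")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in METRIC_NAMES})

    def to_csv_row(self) -> str:
        return ",".join(f"{self.values[k]:.10g}" for k in METRIC_NAMES)


# ---------------------------------------------------------------------------
# confusion-matrix side
# ---------------------------------------------------------------------------

def confusion_counts(pred: PredictionSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """K x K confusion matrix plus one-vs-rest (TP, FP, FN, TN) per class.

    Matrix rows are true classes, columns predicted classes; entries sum to
    N, and TP + FP + FN + TN = N for every class.
    """
    classes = pred.classes
    k = len(classes)
    index = {c: i for i, c in enumerate(classes.tolist())}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(pred.true_labels.tolist(), pred.predicted_labels.tolist()):
        cm[index[t], index[p]] += 1

    tp = np.diag(cm).astype(int)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    ovr = pd.DataFrame({"TP": tp, "FP": fp, "FN": fn, "TN": tn}, index=classes)
    return pd.DataFrame(cm, index=classes, columns=classes), ovr


def _binary_stats(tp: float, fp: float, fn: float, tn: float, eps: float) -> dict[str, float]:
    tpr = tp / max(tp + fn, eps)
    tnr = tn / max(tn + fp, eps)
    ppv = tp / max(tp + fp, eps)
    npv = tn / max(tn + fn, eps)
    mcc_den = math.sqrt(max((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn), eps))
    return {
        "TPR": tpr,
        "TNR": tnr,
        "PPV": ppv,
        "NPV": npv,
        "BM": tpr + tnr - 1.0,
        "MK": ppv + npv - 1.0,
        "BACC": (tpr + tnr) / 2.0,
        "F1": 2.0 * ppv * tpr / max(ppv + tpr, eps),
        "Jaccard": tp / max(tp + fp + fn, eps),
        "MCC": (tp * tn - fp * fn) / mcc_den,
        "LRp": tpr / max(1.0 - tnr, eps),
        # FP*FN is a count product, not a rate: clip at half a count per factor
        "DOR": (tp * tn) / max(fp * fn, 0.25),
    }


def confusion_metrics(cm: pd.DataFrame, ovr: pd.DataFrame,
                      config: MetricConfig | None = None) -> dict[str, float]:
    """The 14 confusion-matrix parameters.

    ACC and Cohen's kappa on the full K x K matrix; everything else macro
    one-vs-rest over classes actually present in the true labels (classes
    with an all-zero matrix row are excluded from the average and logged).
    """
    config = config or MetricConfig()
    n = int(cm.to_numpy().sum())
    if n == 0:
        raise InputError("empty confusion matrix")
    eps = config.resolve_epsilon(n)

    m = cm.to_numpy(dtype=float)
    acc = np.trace(m) / n
    p_o = acc
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / n ** 2
    cohen = 0.0 if abs(1.0 - p_e) < 1e-15 else (p_o - p_e) / (1.0 - p_e)

    present = m.sum(axis=1) > 0
    absent = [c for c, pres in zip(cm.index.tolist(), present) if not pres]
    if absent:
        logger.info("classes absent from true labels excluded from macro average: %s", absent)

    per_class = [
        _binary_stats(*(float(ovr.loc[c, k]) for k in ("TP", "FP", "FN", "TN")), eps)
        for c, pres in zip(cm.index.tolist(), present) if pres
    ]
    out = {key: float(np.mean([d[key] for d in per_class]))
           for key in per_class[0]}
    out["ACC"] = float(acc)
    out["Cohen"] = float(cohen)
    return {k: out[k] for k in CONFUSION_METRIC_NAMES}


# ---------------------------------------------------------------------------
# ranking / early-recognition side
# ---------------------------------------------------------------------------

def _rie(rel_ranks_of_actives: np.ndarray, n_total: int, n_active: int,
         alpha: float) -> float:
    num = float(np.exp(-alpha * rel_ranks_of_actives).sum())
    denom = (n_active / n_total) * (1.0 - math.exp(-alpha)) / (math.expm1(alpha / n_total))
    return num / denom


def _binary_ranking(y: np.ndarray, scores: np.ndarray,
                    config: MetricConfig) -> dict[str, float]:
    """All 11 ranking parameters for one active/inactive split."""
    n_total = len(y)
    n_act = int(y.sum())

    # fractional descending ranks: best score -> rank ~1
    r_desc = rankdata(-scores, method="average")
    x = r_desc[y] / n_total

    # AUC via mid-rank Mann-Whitney (ties count 1/2)
    r_asc = rankdata(scores, method="average")
    n_inact = n_total - n_act
    auc = (r_asc[y].sum() - n_act * (n_act + 1) / 2.0) / (n_act * n_inact)

    auac = float(np.mean(1.0 - x)) + 1.0 / (2 * n_total)

    out = {"AUC": float(auc), "AUAC": float(auac)}

    for alpha in config.alphas:
        tag = f"{alpha:g}".replace(".", "")
        rie = _rie(x, n_total, n_act, alpha)
        best = _rie(np.arange(1, n_act + 1) / n_total, n_total, n_act, alpha)
        worst = _rie(np.arange(n_total - n_act + 1, n_total + 1) / n_total,
                     n_total, n_act, alpha)
        bedroc = (rie - worst) / (best - worst) if best > worst else 0.0
        out[f"RIE{tag}"] = float(rie)
        out[f"BEDROC{tag}"] = float(min(max(bedroc, 0.0), 1.0))

    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    cum_act = np.cumsum(y_sorted)
    base_rate = n_act / n_total
    for frac in config.fractions:
        tag = f"{frac * 100:g}"
        top = max(int(math.ceil(frac * n_total)), 1)
        out[f"EF{tag}"] = float((cum_act[top - 1] / top) / base_rate)

    fpr, tpr, _ = roc_curve(y.astype(int), scores)
    for frac in config.fractions:
        tag = f"{frac * 100:g}"
        out[f"ROC_EF{tag}"] = float(np.interp(frac, fpr, tpr))

    # AP: mean over actives of precision at that active's (stable) rank
    prec_at_k = cum_act / np.arange(1, n_total + 1)
    out["AP"] = float(prec_at_k[y_sorted].mean())
    return out


def ranking_metrics(pred: PredictionSet,
                    config: MetricConfig | None = None) -> dict[str, float]:
    """The 11 ranking parameters, macro-averaged one-vs-rest.

    Each class c is scored by its own score column against the rest.  Classes
    with zero actives or zero inactives in the true labels are skipped from
    the macro average (logged); all-equal scores are handled by the fractional
    tie policy, never an exception.
    """
    config = config or MetricConfig()
    per_class: list[dict[str, float]] = []
    skipped = []
    for j, c in enumerate(pred.classes.tolist()):
        y = pred.true_labels == c
        n_act = int(y.sum())
        if n_act == 0 or n_act == pred.n:
            skipped.append(c)
            continue
        per_class.append(_binary_ranking(y, pred.class_scores[:, j], config))
    if skipped:
        logger.info("classes without both actives and inactives skipped "
                    "from ranking macro average: %s", skipped)
    if not per_class:
        raise InputError("no class has both actives and inactives")
    return {key: float(np.mean([d[key] for d in per_class]))
            for key in RANKING_METRIC_NAMES}


def metric_battery(pred: PredictionSet,
                   config: MetricConfig | None = None) -> MetricVector:
    """All 25 performance parameters for one prediction set."""
    config = config or MetricConfig()
    cm, ovr = confusion_counts(pred)
    values = {}
    values.update(ranking_metrics(pred, config))
    values.update(confusion_metrics(cm, ovr, config))
    return MetricVector(values)


__all__ = [
    "METRIC_NAMES",
    "CONFUSION_METRIC_NAMES",
    "RANKING_METRIC_NAMES",
    "MetricConfig",
    "MetricVector",
    "PredictionSet",
    "InputError",
    "confusion_counts",
    "confusion_metrics",
    "ranking_metrics",
    "metric_battery",
]
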