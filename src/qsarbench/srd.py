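"""Sum of Ranking Differences (SRD) with CRRN validation.

SRD compares columns (here: the four train/test split ratios) of an
objects x systems matrix (here: 25 performance parameters x 4 split ratios)
against a reference column -- by default the row maximum, i.e. an ideal
model that maximizes every performance parameter.  Every column and the
reference are rank-transformed (ascending, fractional ranks on ties) and
SRD_j = sum_i |rank_ij - rank_i,ref|; smaller is better, and 0 means the
column orders the objects exactly like the reference.

Validation is two-fold:

* CRRN (comparison of ranks by random numbers): the exact or Monte-Carlo
  null distribution of SRD between the reference and a uniformly random
  permutation of the n objects.  A column below the null's 5th percentile
  ranks better than chance.
* k-fold cross-validation: SRD recomputed leaving each fold of rows out,
  each fold's value rescaled to percent of the reduced-n maximum, giving a
  fold x column matrix suitable for a one-way ANOVA over columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .metrics import InputError
from .synthetic import _child_rng

REFERENCE_POLICIES = ("rowmax", "rowmin", "rowmean")

#: largest n for which the exact n! enumeration is allowed
EXACT_CRRN_LIMIT = 10


@dataclass
class SRDResult:
    """Per-column SRD values with CRRN percentiles and CV folds."""

    columns: list[str]
    srd_raw: np.ndarray
    srd_percent: np.ndarray
    null_percentiles: dict[str, float]
    cv_values: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "columns": self.columns,
            "srd_raw": self.srd_raw.tolist(),
            "srd_percent": self.srd_percent.tolist(),
            "null_percentiles": self.null_percentiles,
        }
        if self.cv_values is not None:
            out["cv_values"] = self.cv_values.to_dict(orient="list")
        return out


def max_srd(n: int) -> int:
    """Largest possible SRD for n objects: n^2/2 (even) or (n^2-1)/2 (odd),
    attained by the rank-reversing permutation."""
    if n < 2:
        raise InputError("max_srd needs n >= 2")
    return n * n // 2 if n % 2 == 0 else (n * n - 1) // 2


def _reference_vector(matrix: np.ndarray, policy) -> np.ndarray:
    if isinstance(policy, str):
        if policy == "rowmax":
            return matrix.max(axis=1)
        if policy == "rowmin":
            return matrix.min(axis=1)
        if policy == "rowmean":
            return matrix.mean(axis=1)
        raise InputError(f"unknown reference policy {policy!r}; "
                         f"choose from {REFERENCE_POLICIES} or pass a vector")
    ref = np.asarray(policy, dtype=float)
    if ref.shape != (matrix.shape[0],):
        raise InputError("explicit reference must have one value per row")
    return ref


def compute_srd(matrix: np.ndarray | pd.DataFrame,
                reference: str | np.ndarray = "rowmax") -> np.ndarray:
    """Raw SRD value of every column against the reference.

    Ascending fractional ranks in both the columns and the reference, so the
    result is integer-or-half valued and invariant to strictly monotone
    transformations of whole columns.
    """
    m = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 1:
        raise InputError("SRD input must be an n>=2 by m>=1 matrix")
    if not np.all(np.isfinite(m)):
        raise InputError("SRD input must be finite")
    ref_ranks = rankdata(_reference_vector(m, reference), method="average")
    col_ranks = np.apply_along_axis(lambda v: rankdata(v, method="average"), 0, m)
    return np.abs(col_ranks - ref_ranks[:, None]).sum(axis=0)


def srd_percent(raw: np.ndarray, n: int) -> np.ndarray:
    """Raw SRD rescaled to percent of the theoretical maximum."""
    return 100.0 * np.asarray(raw, dtype=float) / max_srd(n)


def _exact_footrule_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of sum_i |pi(i) - i| over all n! permutations."""
    base = np.arange(1, n + 1)
    counts: dict[int, int] = {}
    perms = itertools.permutations(range(1, n + 1))
    while chunk := list(itertools.islice(perms, 200_000)):
        d = np.abs(np.asarray(chunk, dtype=np.int16) - base).sum(axis=1)
        for v, c in zip(*np.unique(d, return_counts=True)):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    values = np.array(sorted(counts), dtype=float)
    pmf = np.array([counts[int(v)] for v in values], dtype=float)
    return values, pmf / pmf.sum()


def _percentiles(values: np.ndarray, pmf: np.ndarray) -> dict[str, float]:
    cdf = np.cumsum(pmf)
    def point(q: float) -> float:
        return float(values[np.searchsorted(cdf, q)])
    return {"p5": point(0.05), "median": point(0.50), "p95": point(0.95)}


def crrn_null(n: int, method: str = "auto", draws: int = 100_000,
              seed: int = 0) -> dict:
    """CRRN null distribution of SRD for n objects.

    ``exact`` enumerates all n! permutations (n <= 10); ``montecarlo`` draws
    uniform random permutations; ``auto`` picks exact when feasible.  Returns
    ``{"values", "pmf", "percentiles"}`` with the 5% / median / 95% points
    (the XX1/Med/XX19 lines of an SRD plot).
    """
    if n < 2:
        raise InputError("crrn_null needs n >= 2")
    if method == "auto":
        method = "exact" if n <= EXACT_CRRN_LIMIT else "montecarlo"
    if method == "exact":
        if n > EXACT_CRRN_LIMIT:
            raise InputError(f"exact CRRN limited to n <= {EXACT_CRRN_LIMIT}; got {n}")
        values, pmf = _exact_footrule_distribution(n)
    elif method == "montecarlo":
        rng = _child_rng(seed, 201, n)
        base = np.arange(1, n + 1)
        perms = np.argsort(rng.random((int(draws), n)), axis=1) + 1
        d = np.abs(perms - base).sum(axis=1)
        values, counts = np.unique(d, return_counts=True)
        values = values.astype(float)
        pmf = counts / counts.sum()
    else:
        raise InputError(f"unknown CRRN method {method!r}")
    return {"values": values, "pmf": pmf, "percentiles": _percentiles(values, pmf)}


def srd_crossvalidate(matrix: np.ndarray | pd.DataFrame,
                      reference: str | np.ndarray = "rowmax",
                      folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """Leave-one-fold-out SRD, rescaled to percent of the reduced maximum.

    Rows (objects) are partitioned into ``folds`` contiguous groups after a
    seeded shuffle; fold f's value is the SRD computed on the rows outside
    fold f, as percent of max_srd(rows kept).  Output: folds x columns.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    m = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if folds > n:
        raise InputError(f"folds={folds} exceeds n={n} rows")
    if folds < 2:
        raise InputError("need at least 2 folds")
    ref = _reference_vector(m, reference) if isinstance(reference, str) else np.asarray(reference, float)

    rng = _child_rng(seed, 202)
    order = rng.permutation(n)
    assignment = np.array_split(order, folds)
    rows = []
    for leave_out in assignment:
        keep = np.setdiff1d(np.arange(n), leave_out)
        raw = compute_srd(m[keep], ref[keep])
        rows.append(srd_percent(raw, len(keep)))
    cols = list(matrix.columns) if is_df else [f"col{j}" for j in range(m.shape[1])]
    return pd.DataFrame(rows, columns=cols,
                        index=[f"fold{f + 1}" for f in range(folds)])


def run_srd(matrix: pd.DataFrame, reference: str | np.ndarray = "rowmax",
            folds: int = 5, crrn_method: str = "auto",
            crrn_draws: int = 100_000, seed: int = 0) -> SRDResult:
    """SRD + CRRN percentiles + CV folds in one call (the `srd` CLI core)."""
    raw = compute_srd(matrix, reference)
    n = matrix.shape[0]
    null = crrn_null(n, crrn_method, crrn_draws, seed)
    pct_null = {k: 100.0 * v / max_srd(n) for k, v in null["percentiles"].items()}
    cv = srd_crossvalidate(matrix, reference, folds, seed)
    return SRDResult(
        columns=[str(c) for c in matrix.columns],
        srd_raw=raw,
        srd_percent=srd_percent(raw, n),
        null_percentiles=pct_null,
        cv_values=cv,
    )


__all__ = [
    "SRDResult",
    "max_srd",
    "compute_srd",
    "srd_percent",
    "crrn_null",
    "srd_crossvalidate",
    "run_srd",
    "EXACT_CRRN_LIMIT",
    "REFERENCE_POLICIES",
]
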