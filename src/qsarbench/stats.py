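"""Factorial ANOVA, Tukey post hoc, and interaction-mean summaries.

The benchmark's results table is melted to one observation per (model
record x performance parameter), giving four categorical factors: PP (the
25 performance parameters), ML (five algorithms), NS (dataset sizes), and
SR (split ratios).  A fixed-effects factorial ANOVA (main effects plus a
configurable set of two-way interactions, Type-III sums of squares so
unbalanced designs from failed cells stay interpretable) tests which
factors drive performance; Tukey's HSD locates the significant pairs; the
interaction-mean tables (cell mean, SE, t-based 95% CI) are the data behind
the benchmark's summary figures (per-parameter profiles and algorithm x
size bubble charts).  The fold x split-ratio SRD matrix feeds a one-way
ANOVA with SR as the only factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .metrics import METRIC_NAMES, InputError
from .workflow import ResultsTable

logger = logging.getLogger(__name__)

FACTOR_NAMES = ("PP", "ML", "NS", "SR")

#: the two-way interactions reported by default
DEFAULT_INTERACTIONS: tuple[tuple[str, str], ...] = (
    ("PP", "NS"), ("NS", "SR"), ("ML", "NS"),
)


class DegenerateDataError(ValueError):
    """Zero between-group variance or empty design cells."""


@dataclass
class AnovaSummary:
    """ANOVA table plus optional post hoc / interaction products."""

    table: pd.DataFrame                      # index: effect; cols: sum_sq, df, F, PR(>F)
    formula: str = ""
    warnings: list[str] = field(default_factory=list)

    def p_value(self, effect: str) -> float:
        for idx in self.table.index:
            if idx == effect or idx == f"C({effect})":
                return float(self.table.loc[idx, "PR(>F)"])
        raise KeyError(f"effect {effect!r} not in ANOVA table")

    def f_value(self, effect: str) -> float:
        for idx in self.table.index:
            if idx == effect or idx == f"C({effect})":
                return float(self.table.loc[idx, "F"])
        raise KeyError(f"effect {effect!r} not in ANOVA table")

    def to_dict(self) -> dict:
        return {"formula": self.formula,
                "table": self.table.reset_index().to_dict(orient="records"),
                "warnings": self.warnings}


def melt_results(results: ResultsTable | pd.DataFrame,
                 validation: str = "CV") -> pd.DataFrame:
    """Long observation table: one row per (record, performance parameter).

    ``validation`` selects "CV", "test", or "both"; each record yields 25
    observations with factor columns value, PP, ML, NS, SR, Split.
    """
    frame = results.frame if isinstance(results, ResultsTable) else results
    missing = [c for c in METRIC_NAMES if c not in frame.columns]
    if missing:
        raise InputError(f"results table lacks metric columns: {missing}")
    if validation not in ("CV", "test", "both"):
        raise InputError("validation must be 'CV', 'test' or 'both'")
    sub = frame if validation == "both" else frame[frame["Split"] == validation]
    melted = sub.melt(
        id_vars=[c for c in sub.columns if c not in METRIC_NAMES],
        value_vars=list(METRIC_NAMES), var_name="PP", value_name="value",
    )
    melted["NS"] = melted["NS"].astype(str)
    melted["SR"] = melted["SR"].astype(str)
    return melted


def _check_observations(table: pd.DataFrame, factors) -> list[str]:
    """Validate; return the factors that actually vary (>= 2 levels)."""
    if table.empty:
        raise InputError("empty observation table")
    usable = [f for f in factors if table[f].nunique() >= 2]
    if not usable:
        raise InputError("no factor has >= 2 levels")
    if float(np.var(table["value"].to_numpy())) == 0.0:
        raise DegenerateDataError("all observations identical; F undefined")
    return usable


def factorial_anova(table: pd.DataFrame,
                    factors=("PP", "ML", "NS", "SR"),
                    interactions=DEFAULT_INTERACTIONS,
                    typ: int = 3) -> AnovaSummary:
    """Fixed-effects factorial ANOVA over the named categorical factors.

    Main effects for every factor plus the requested two-way interactions
    (only those whose factors are both included); Type-III sums of squares by
    default.  Empty design cells are reported as warnings, not errors.
    """
    present = [f for f in factors if f in table.columns]
    usable = _check_observations(table, present)
    warnings: list[str] = []
    dropped = [f for f in present if f not in usable]
    if dropped:
        warnings.append(f"single-level factor(s) dropped from the model: {dropped}")
        logger.warning(warnings[-1])
    factors = usable
    cell_sizes = table.groupby(list(factors), observed=True).size()
    expected = int(np.prod([table[f].nunique() for f in factors]))
    if len(cell_sizes) < expected:
        warnings.append(f"unbalanced design: {expected - len(cell_sizes)} empty cell(s) "
                        f"of {expected}")
        logger.warning(warnings[-1])

    terms = [f"C({f})" for f in factors]
    terms += [f"C({a}):C({b})" for a, b in interactions
              if a in factors and b in factors]
    formula = "value ~ " + " + ".join(terms)
    model = smf.ols(formula, data=table).fit()
    anova = sm.stats.anova_lm(model, typ=typ)
    anova.index = [i.replace("C(", "").replace(")", "") for i in anova.index]
    return AnovaSummary(table=anova, formula=formula, warnings=warnings)


def tukey_hsd(table: pd.DataFrame, factor: str,
              alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD on one factor.

    Returns a symmetric matrix of family-wise-adjusted p-values with 1.0 on
    the diagonal (a level is never different from itself).
    """
    if factor not in table.columns:
        raise InputError(f"unknown factor {factor!r}")
    levels = sorted(table[factor].astype(str).unique())
    if len(levels) < 2:
        raise InputError(f"factor {factor!r} needs >= 2 levels")
    res = pairwise_tukeyhsd(table["value"].to_numpy(),
                            table[factor].astype(str).to_numpy(), alpha=alpha)
    mat = pd.DataFrame(1.0, index=levels, columns=levels)
    summary = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    for _, row in summary.iterrows():
        a, b, p = str(row["group1"]), str(row["group2"]), float(row["p-adj"])
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat


def interaction_means(table: pd.DataFrame, factors: tuple[str, ...],
                      conf_level: float = 0.95) -> pd.DataFrame:
    """Cell means with SE and t-based confidence intervals for a factor
    combination; for (ML, NS) the cell mean is the bubble-chart value."""
    for f in factors:
        if f not in table.columns:
            raise InputError(f"unknown factor {f!r}")
    grouped = table.groupby(list(factors), observed=True)["value"]
    out = grouped.agg(mean="mean", sd="std", n="size").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    tcrit = np.where(out["n"] > 1,
                     sps.t.ppf(0.5 + conf_level / 2, np.maximum(out["n"] - 1, 1)),
                     np.nan)
    out["ci_low"] = out["mean"] - tcrit * out["se"]
    out["ci_high"] = out["mean"] + tcrit * out["se"]
    empty = out["n"] == 0
    if empty.any():
        logger.info("%d empty cell(s) emitted as missing", int(empty.sum()))
    return out


def oneway_anova(cv_values: pd.DataFrame, value_name: str = "SRD") -> AnovaSummary:
    """One-way ANOVA of cross-validated SRD values grouped by split ratio.

    ``cv_values`` is the fold x column matrix from
    :func:`qsarbench.srd.srd_crossvalidate` (columns = split ratios).
    """
    if cv_values.shape[1] < 2:
        raise InputError("need >= 2 groups")
    if cv_values.shape[0] < 2:
        raise InputError("need >= 2 folds")
    long = cv_values.melt(var_name="SR", value_name="value")
    if float(np.var(long["value"].to_numpy())) == 0.0:
        raise DegenerateDataError("all SRD values identical; F undefined")
    model = smf.ols("value ~ C(SR)", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = [i.replace("C(", "").replace(")", "") for i in anova.index]
    return AnovaSummary(table=anova, formula=f"{value_name} ~ C(SR)")


__all__ = [
    "FACTOR_NAMES",
    "DEFAULT_INTERACTIONS",
    "AnovaSummary",
    "DegenerateDataError",
    "melt_results",
    "factorial_anova",
    "tukey_hsd",
    "interaction_means",
    "oneway_anova",
]
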