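"""Group-comparison and correlation reporting for cohort results.

Comparisons follow the clinical-report shape: per-variable group mean ± SD
with two-sample t-tests between adjacent groups (1 vs 2, 2 vs 3, 3 vs 4) and
a correlation table of DI and MEI_LS against numeric subject metadata.
Welch's unequal-variance t is the default (group SDs visibly differ);
pooled-variance mode is available for sensitivity analysis.  P-values are
two-sided throughout and no multiple-testing correction is applied — the
report states this explicitly.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["independent_t", "summary_t", "pearson", "cohort_report"]

ADJACENT_PAIRS = ((1, 2), (2, 3), (3, 4))


def independent_t(sample_a: Sequence[float], sample_b: Sequence[float],
                  welch: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test on raw samples: returns (t, df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate samples: both groups have zero variance")
    res = sstats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summary_t(mean_a: float, sd_a: float, n_a: int,
              mean_b: float, sd_b: float, n_b: int,
              welch: bool = True) -> tuple[float, float, float]:
    """Two-sample t from printed summary statistics (mean, SD, n per group).

    Uses the Welch–Satterthwaite degrees of freedom when ``welch``; lets
    published group summaries be checked without the raw data.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be non-negative")
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        raise ValueError("degenerate summaries: both SDs zero")
    res = sstats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                      equal_var=not welch)
    if welch:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    else:
        df = n_a + n_b - 2
    return float(res.statistic), float(df), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value
    (t transform, n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def _sig_mark(p: float) -> str:
    if not math.isfinite(p):
        return ""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cohort_report(results: pd.DataFrame, welch: bool = True) -> dict:
    """Build group-summary and correlation tables from per-subject results.

    ``results`` needs columns ``group`` (1–4), the outcome variables
    (``di_percent``, ``mei_ss``, ``mei_ls``) and any numeric metadata columns
    to correlate against.  Returns ``{"table1": DataFrame, "table2":
    DataFrame, "notes": [...]}``: table1 holds mean ± SD per group with
    adjacent-group p-values and significance marks (* P<0.05, ** P<0.001);
    table2 correlates DI and MEI_LS with the metadata columns.
    """
    if "group" not in results.columns:
        raise ValueError("results must have a 'group' column")
    notes = ["Two-sided tests; no multiple-testing correction applied.",
             f"{'Welch' if welch else 'Pooled-variance'} two-sample t-test."]
    groups_present = sorted(int(g) for g in results["group"].unique())
    for g in (1, 2, 3, 4):
        if g not in groups_present:
            notes.append(f"warning: group {g} missing from results")

    outcome_cols = [c for c in results.columns
                    if c not in ("group", "subject_id") and
                    pd.api.types.is_numeric_dtype(results[c])]
    rows = []
    for var in outcome_cols:
        row: dict = {"variable": var}
        by_group = {}
        for g in groups_present:
            vals = results.loc[results["group"] == g, var].dropna().to_numpy()
            by_group[g] = vals
            if vals.size == 0:
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
            row[f"g{g}_mean"] = mean
            row[f"g{g}_sd"] = sd
            row[f"g{g}"] = (f"{mean:.2f} ± {sd:.2f}" if math.isfinite(sd)
                            else f"{mean:.2f}")
        for ga, gb in ADJACENT_PAIRS:
            key = f"p_g{ga}_vs_g{gb}"
            va, vb = by_group.get(ga, np.array([])), by_group.get(gb, np.array([]))
            if va.size >= 2 and vb.size >= 2:
                try:
                    _, _, p = independent_t(va, vb, welch=welch)
                except ValueError:
                    p = math.nan
                row[key] = p
                row[key + "_sig"] = _sig_mark(p)
            else:
                row[key] = math.nan
                row[key + "_sig"] = ""
        rows.append(row)
    table1 = pd.DataFrame(rows)

    corr_targets = [c for c in ("di_percent", "mei_ls") if c in results.columns]
    meta_cols = [c for c in outcome_cols
                 if c not in ("di_percent", "mei_ss", "mei_ls")]
    corr_rows = []
    for var in meta_cols:
        row = {"parameter": var}
        for target in corr_targets:
            sub = results[[var, target]].dropna()
            try:
                r, p = pearson(sub[var], sub[target])
            except ValueError:
                r, p = math.nan, math.nan
            row[f"{target}_R"] = r
            row[f"{target}_P"] = p
        corr_rows.append(row)
    table2 = pd.DataFrame(corr_rows)
    return {"table1": table1, "table2": table2, "notes": notes}
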