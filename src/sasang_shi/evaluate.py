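"""Rater agreement, group comparisons and cohort summaries.

Two clinicians scored every subject's health on a 0-100 visual
analogue scale; their agreement is quantified with the intraclass
correlation coefficient.  The default form is ICC(2,1): two-way
random effects, absolute agreement, single rater -- both raters scored
all subjects and are treated as a random sample of possible raters.
ICC(3,1) (raters fixed) is available via ``form``.  One-way ANOVA
compares scores across the three constitution groups, and the cohort
summary reproduces the demographic/health-category table layout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .published import CATEGORIES, CONSTITUTIONS, categorize_vas


def icc_agreement(ratings: np.ndarray, form: str = "icc2") -> float:
    """Single-rater intraclass correlation of a subjects x raters matrix.

    ``form`` "icc2" is ICC(2,1) (two-way random, absolute agreement),
    "icc3" is ICC(3,1) (two-way mixed, consistency).  NaN with a
    warning when there is no between-subject variance.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ratings must be (>=2 subjects, >=2 raters)")
    if np.any(~np.isfinite(X)):
        raise ValueError("ratings must have no missing cells")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((X - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("form must be 'icc2' or 'icc3'")
    if denom <= 0:
        warnings.warn("no between-subject variance; ICC undefined")
        return math.nan
    return float((msr - mse) / denom)


def anova_oneway(*groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and P value.

    F is exactly 0 when all group means coincide and infinite (P = 0,
    with a warning) when group means differ with zero within-group
    variance.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >=2 groups with >=2 values each")
    grand = np.concatenate(gs).mean()
    n_total = sum(len(g) for g in gs)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    df_b = len(gs) - 1
    df_w = n_total - len(gs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance; F is infinite")
        return math.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


@dataclass
class CohortSummary:
    """Per-constitution demographics and health-level distribution."""

    table: pd.DataFrame          # one row per constitution
    anova: pd.DataFrame          # variable -> F, P across constitutions

    def __str__(self) -> str:  # human-readable rendition
        lines = ["Cohort summary (per constitution)"]
        for const, row in self.table.iterrows():
            cats = ", ".join(
                f"{c}: {int(row[f'n_{c}'])} ({row[f'pct_{c}']:.0f}%)"
                for c in CATEGORIES
            )
            lines.append(
                f"  {const}: n={int(row['n'])}, "
                f"age {row['age_mean']:.1f}±{row['age_sd']:.1f}, "
                f"BMI {row['bmi_mean']:.1f}±{row['bmi_sd']:.1f}, "
                f"VAS {row['vas_mean']:.1f}±{row['vas_sd']:.1f} [{cats}]"
            )
        for var, row in self.anova.iterrows():
            lines.append(
                f"  ANOVA {var}: F={row['F']:.2f}, P={row['P']:.2g}"
            )
        return "\n".join(lines)


def summarize_cohort(subjects) -> CohortSummary:
    """Demographics, category counts/percentages and VAS per
    constitution, with one-way ANOVA across constitutions.

    Percentages are recomputed from the counts; single-subject groups
    report NaN SDs; empty constitutions are omitted with a warning.
    """
    frame = pd.DataFrame(
        {
            "constitution": s.constitution,
            "age": s.age,
            "bmi": s.bmi,
            "vas": s.vas_mean,
            "category": categorize_vas(s.vas_mean),
        }
        for s in subjects
    )
    rows = {}
    for const in CONSTITUTIONS:
        sub = frame[frame["constitution"] == const]
        if len(sub) == 0:
            warnings.warn(f"no subjects in constitution {const}; omitted")
            continue
        n = len(sub)
        row = {"n": n}
        for var in ("age", "bmi", "vas"):
            row[f"{var}_mean"] = sub[var].mean()
            row[f"{var}_sd"] = sub[var].std(ddof=1) if n > 1 else math.nan
        for cat in CATEGORIES:
            cnt = int((sub["category"] == cat).sum())
            row[f"n_{cat}"] = cnt
            row[f"pct_{cat}"] = 100.0 * cnt / n
        rows[const] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    anova_rows = {}
    if len(rows) >= 2:
        for var in ("age", "bmi", "vas"):
            groups = [
                frame.loc[frame["constitution"] == c, var].to_numpy()
                for c in rows
            ]
            if all(len(g) >= 2 for g in groups):
                f, p = anova_oneway(*groups)
                anova_rows[var] = {"F": f, "P": p}
    return CohortSummary(
        table=table, anova=pd.DataFrame.from_dict(anova_rows, orient="index")
    )


def ratings_matrix(subjects) -> np.ndarray:
    """The (n_subjects, 2) matrix of the two raters' VAS scores."""
    return np.array([[s.vas_rater1, s.vas_rater2] for s in subjects])
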