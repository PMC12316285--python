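"""Cohort-level statistics over per-sample PUL-PorB calls.

Prevalence with Wilson intervals, probe-vs-assembly validation
(sensitivity/specificity), Pearson chi-squared contingency tests over
population x group tables, pairwise two-proportion tests with
Benjamini-Hochberg FDR ("q-values"), and covariate checks (coverage vs
prevalence correlation, ANOVA on log10 abundance, chi-squared for
age/sex vs positivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint, proportions_chisquare


@dataclass
class CohortTable:
    """Population x group count table."""

    table: pd.DataFrame  # rows: populations, cols: groups, values: counts

    def __post_init__(self):
        if (self.table.values < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_calls(cls, populations, groups) -> "CohortTable":
        """Cross-tabulate per-sample population labels and group labels."""
        df = pd.crosstab(pd.Series(populations, name="population"),
                         pd.Series(groups, name="group"))
        return cls(df)

    @property
    def margins(self) -> pd.Series:
        return self.table.sum(axis=1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Agreement of a test screen against a truth screen over ``total`` items."""

    both_positive: int
    truth_only: int
    test_only: int
    total: int

    def __post_init__(self):
        if self.both_positive + self.truth_only + self.test_only > self.total:
            raise ValueError("cells exceed total")
        if min(self.both_positive, self.truth_only, self.test_only, self.total) < 0:
            raise ValueError("negative counts")


def prevalence(positives: int, n: int, alpha: float = 0.05
               ) -> tuple[float, tuple[float, float]]:
    """Carrier fraction with a Wilson score interval."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = proportion_confint(positives, n, alpha=alpha, method="wilson")
    return positives / n, (float(lo), float(hi))


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity (percent, full precision) of the test
    screen against truth; round for reporting."""
    pos = c.both_positive + c.truth_only
    if pos <= 0:
        raise ValueError("no truth positives")
    tn = c.total - c.both_positive - c.truth_only - c.test_only
    sens = 100.0 * c.both_positive / pos
    spec = 100.0 * tn / (tn + c.test_only)
    return sens, spec


def contingency_test(table: CohortTable) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on the r x c table.

    Zero-margin rows/columns are dropped with a warning; a warning is also
    raised when any expected count falls below 5.
    """
    df = table.table
    keep_r = df.sum(axis=1) > 0
    keep_c = df.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        df = df.loc[keep_r, keep_c]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("contingency test needs >= 2 non-empty rows and columns")
    chi2, p, dof, expected = sps.chi2_contingency(df.values, correction=False)
    if (expected < 5).any():
        warnings.warn("expected counts < 5; chi-squared approximation is rough")
    return float(chi2), int(dof), float(p)


def pairwise_group_tests(table: CohortTable) -> pd.DataFrame:
    """Two families of proportion tests with BH correction applied within
    each family:

    * ``population_pair``: for each pair of populations, a chi-squared test of
      their full group composition (are the two populations different?);
    * ``group``: for each group, a test of its prevalence across all
      populations (which group drives the differentiation?).
    """
    df = table.table
    pops = list(df.index)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            sub = df.loc[[a, b]]
            sub = sub.loc[:, sub.sum(axis=0) > 0]
            chi2, p, _, _ = sps.chi2_contingency(sub.values, correction=False)
            rows.append(("population_pair", f"{a}|{b}", float(chi2), float(p)))
    margins = df.sum(axis=1).values
    for g in df.columns:
        count = df[g].values
        if count.sum() == 0 or (count == margins).all():
            p = 1.0
            chi2 = 0.0
        else:
            chi2, p, _ = proportions_chisquare(count, margins)
        rows.append(("group", str(g), float(chi2), float(p)))
    out = pd.DataFrame(rows, columns=["family", "comparison", "statistic", "p"])
    out["q"] = np.nan
    for fam in out["family"].unique():
        m = out["family"] == fam
        out.loc[m, "q"] = multipletests(out.loc[m, "p"].values, method="fdr_bh")[1]
    return out


def covariate_tests(meta: pd.DataFrame) -> dict[str, dict]:
    """Covariate checks on per-sample metadata.

    Expected columns (used when present): ``dataset``, ``coverage``,
    ``positive``, ``country``, ``abundance``, ``age_band``, ``sex``.
    Computes the per-dataset coverage vs prevalence Pearson correlation,
    one-way ANOVA of log10 abundance by country (positives only), and
    chi-squared tests of age band / sex vs positivity.
    """
    out: dict[str, dict] = {}
    if {"dataset", "coverage", "positive"} <= set(meta.columns):
        per = meta.groupby("dataset").agg(cov=("coverage", "mean"),
                                          prev=("positive", "mean"))
        if len(per) < 3:
            raise ValueError("coverage correlation needs >= 3 datasets")
        if per["prev"].nunique() == 1 or per["cov"].nunique() == 1:
            out["coverage_correlation"] = {"r": 0.0, "p": None, "degenerate": True}
        else:
            r, p = sps.pearsonr(per["cov"], per["prev"])
            out["coverage_correlation"] = {"r": float(r), "p": float(p),
                                           "degenerate": False}
    if {"country", "abundance", "positive"} <= set(meta.columns):
        pos = meta[(meta["positive"]) & (meta["abundance"] > 0)]
        grps = [np.log10(g["abundance"].values)
                for _, g in pos.groupby("country") if len(g) >= 2]
        if len(grps) >= 2:
            f, p = sps.f_oneway(*grps)
            out["abundance_anova"] = {"F": float(f), "p": float(p),
                                      "n_groups": len(grps)}
    for col in ("age_band", "sex"):
        if {col, "positive"} <= set(meta.columns):
            tab = pd.crosstab(meta[col], meta["positive"])
            if tab.shape[0] >= 2 and tab.shape[1] >= 2:
                chi2, p, _, _ = sps.chi2_contingency(tab.values, correction=False)
                out[f"{col}_vs_positivity"] = {"chi2": float(chi2), "p": float(p)}
    return out
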