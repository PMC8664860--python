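"""Methylation-set versus measurement statistics.

Given per-condition sets of cap-methylated genes and measurement tables
(expression, ribosome footprints, half-life, protein abundance), this
module computes the gain/loss set algebra between conditions,
methylated-gene fractions across expression percentile bins, rank tests
(Mann-Whitney U), covariate-adjusted group effects (ANCOVA on a linear
model), and the differential-expression contingency test comparing the
up/down split of gained versus lost genes with the background split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneSetPair", "gain_loss", "percentile_bin_fractions",
           "rank_compare", "ancova_group_effect", "de_gain_loss_test"]


@dataclass(frozen=True)
class GeneSetPair:
    condition_a: frozenset
    condition_b: frozenset

    @classmethod
    def of(cls, a, b) -> "GeneSetPair":
        return cls(frozenset(a), frozenset(b))


def gain_loss(pair: GeneSetPair):
    """Set algebra between two conditions' methylated-gene sets.

    Returns ``(gained, lost, common, specificity_fraction)`` where
    gained = b \\ a, lost = a \\ b, common = a & b and the specificity
    fraction is |gained | lost| / |a | b| (0 on empty union).
    """
    a, b = set(pair.condition_a), set(pair.condition_b)
    gained, lost, common = b - a, a - b, a & b
    union = a | b
    spec = len(gained | lost) / len(union) if union else 0.0
    return gained, lost, common, spec


def percentile_bin_fractions(expr: pd.Series, methylated, n_bins: int = 10,
                             universe: str = "expressed") -> pd.Series:
    """Fraction of methylated genes per expression percentile bin.

    Genes are ranked by expression and cut into ``n_bins`` equal-count
    bins; the universe defaults to genes with value > 0 ("expressed"),
    or every finite gene with ``universe="all"``.
    """
    expr = expr.dropna()
    if universe == "expressed":
        expr = expr[expr > 0]
    elif universe != "all":
        raise ValueError("universe must be 'expressed' or 'all'")
    if n_bins > len(expr):
        raise ValueError(f"n_bins={n_bins} exceeds the {len(expr)} genes "
                         f"in the universe")
    methylated = set(methylated)
    order = expr.sort_values(kind="stable").index
    fractions = []
    for chunk in np.array_split(np.asarray(order), n_bins):
        members = sum(g in methylated for g in chunk)
        fractions.append(members / len(chunk))
    return pd.Series(fractions,
                     index=pd.RangeIndex(1, n_bins + 1, name="bin"))


def rank_compare(values: pd.Series, in_set):
    """Mann-Whitney U comparing the named set against its complement.

    Exact p-value for small, tie-free samples (both groups <= 20);
    tie-corrected normal approximation otherwise.  Two-tailed.
    Returns ``(U, p, median_in, median_out)``.
    """
    values = values.dropna()
    in_set = set(in_set)
    x = values[[g in in_set for g in values.index]]
    y = values[[g not in in_set for g in values.index]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty after dropping "
                         "missing values")
    pooled = np.concatenate([x.to_numpy(), y.to_numpy()])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return (float(res.statistic), float(res.pvalue),
            float(x.median()), float(y.median()))


def ancova_group_effect(response: pd.Series, in_set, covariate: pd.Series):
    """Group effect on the response after adjusting for a covariate.

    Fits ``response ~ 1 + covariate + group`` by OLS on the genes present
    in both tables and returns the F statistic for the group term with
    (1, n - 3) degrees of freedom and its two-tailed p-value:
    ``(F, (1, n - 3), p)``.
    """
    import statsmodels.api as sm
    df = pd.concat({"y": response, "x": covariate}, axis=1).dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 genes shared by both tables")
    in_set = set(in_set)
    group = np.array([1.0 if g in in_set else 0.0 for g in df.index])
    if group.min() == group.max():
        raise ValueError("group indicator is constant: model degenerate")
    X = sm.add_constant(np.column_stack([df["x"].to_numpy(), group]))
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    t = fit.tvalues[2]
    F = float(t ** 2)
    df_resid = int(fit.df_resid)
    p = float(stats.f.sf(F, 1, df_resid))
    return F, (1, df_resid), p


def de_gain_loss_test(gained, lost, de_table: pd.Series,
                      fc_threshold: float = 1.5,
                      expected_universe: str = "all-de",
                      mode: str = "goodness-of-fit"):
    """Contingency test: do gained genes skew up- and lost genes
    down-regulated, relative to the background up/down split?

    ``de_table`` holds signed fold changes (condition B over A): values
    > 1 are up-regulated, < 1 down-regulated; "differentially expressed"
    means fold change > ``fc_threshold`` or < 1/``fc_threshold``.
    Expected proportions come from the up/down split among all
    differentially expressed genes (``expected_universe="all-de"``) or
    among all genes (``"all-genes"``).  The default test is a
    goodness-of-fit chi-square of the observed 2x2 {gained,lost} x
    {up,down} counts against row totals times the background
    proportions (df = 2); ``mode="independence"`` runs the standard
    2x2 independence test instead (df = 1).

    Returns ``(observed_df, expected_df, chi2, df, p)``.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    de = de_table.dropna()
    up_all = de > fc_threshold
    down_all = de < 1.0 / fc_threshold
    if expected_universe == "all-de":
        n_up, n_down = int(up_all.sum()), int(down_all.sum())
    elif expected_universe == "all-genes":
        n_up, n_down = int(up_all.sum()), int(len(de) - up_all.sum())
    else:
        raise ValueError("expected_universe must be 'all-de' or 'all-genes'")
    if n_up + n_down == 0:
        raise ValueError("no genes pass the fold-change threshold")
    p_up = n_up / (n_up + n_down)

    gained, lost = set(gained), set(lost)
    obs = pd.DataFrame(0, index=["gained", "lost"], columns=["up", "down"])
    for g in de.index:
        if not (up_all.get(g, False) or down_all.get(g, False)):
            continue
        direction = "up" if up_all[g] else "down"
        if g in gained:
            obs.loc["gained", direction] += 1
        elif g in lost:
            obs.loc["lost", direction] += 1
    if obs.to_numpy().sum() == 0:
        raise ValueError("no differentially expressed gained/lost genes: "
                         "test undefined")

    row_totals = obs.sum(axis=1)
    exp = pd.DataFrame({"up": row_totals * p_up,
                        "down": row_totals * (1.0 - p_up)})
    if mode == "goodness-of-fit":
        mask = exp.to_numpy() > 0
        chi2 = float((((obs.to_numpy() - exp.to_numpy()) ** 2
                       / np.where(mask, exp.to_numpy(), 1.0))[mask]).sum())
        dof = int(mask.sum() - obs.shape[0])   # one constraint per row
        p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else math.nan
    elif mode == "independence":
        res = stats.chi2_contingency(obs.to_numpy(), correction=False)
        chi2, dof, p = float(res.statistic), int(res.dof), float(res.pvalue)
    else:
        raise ValueError("mode must be 'goodness-of-fit' or 'independence'")
    return obs, exp, chi2, dof, p
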