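"""Allele frequencies, homogeneity tests, effect tables and qPCR folds.

Frequency tables summarize allele or haplotype calls per group (taxon,
breeding era, panel) with half-up one-decimal percentages; homogeneity of
allele composition across groups is tested with a Pearson chi-square on the
contingency table.  Effect tables report least-squares means per haplotype
group from the environments-as-blocks ANOVA, with absolute and percent
differences relative to the low-SNS baseline.  qRT-PCR transcript levels
are expressed as fold-ACTIN with the 2**dCT method and compared across
groups with Tukey's HSD, summarized as compact letter displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genetics import round_half_up
from .scan import BlockedAnovaResult, blocked_ls_means

DEFAULT_EXCLUDED_LABELS = ("inconsistent", "unassigned", "missing")


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Counts and percentages of allele labels per group."""

    counts: pd.DataFrame       # groups x alleles, integer counts
    percentages: pd.DataFrame  # same shape, one-decimal half-up percentages
    denominators: pd.Series    # per-group denominator
    excluded: pd.DataFrame     # groups x excluded labels


def frequency_table(
    calls: pd.DataFrame,
    group_col: str = "group",
    allele_col: str = "allele",
    excluded_labels: Sequence[str] = DEFAULT_EXCLUDED_LABELS,
    exclude_from_denominator: bool = True,
) -> FrequencyTable:
    """Tabulate allele calls per group.

    Unclassified calls (labels in ``excluded_labels``) are reported
    separately and, by default, left out of the percentage denominators.
    Percentages are rounded half-up to one decimal.
    """
    d = calls[[group_col, allele_col]].dropna()
    if d.empty:
        raise ValueError("no calls to tabulate")
    is_excluded = d[allele_col].isin(excluded_labels)
    main = d[~is_excluded]
    counts = (
        main.groupby([group_col, allele_col], sort=True).size().unstack(fill_value=0)
    )
    excl = (
        d[is_excluded]
        .groupby([group_col, allele_col], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(counts.index, fill_value=0)
    )
    if exclude_from_denominator:
        denom = counts.sum(axis=1)
    else:
        denom = counts.sum(axis=1) + excl.sum(axis=1)
    empty = denom[denom == 0].index.tolist()
    if empty:
        import warnings

        warnings.warn(f"dropping empty group(s): {empty}")
        counts = counts.drop(index=empty)
        excl = excl.drop(index=empty)
        denom = denom.drop(index=empty)
    pct = counts.div(denom, axis=0) * 100.0
    pct = pct.map(lambda x: round_half_up(x, 1))
    return FrequencyTable(
        counts=counts, percentages=pct, denominators=denom, excluded=excl
    )


# ---------------------------------------------------------------------------
# Homogeneity chi-square
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p: float
    low_expected_cells: list[tuple[str, str]]  # cells with expected < 5


def chi2_homogeneity(counts: pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square homogeneity test on a groups x alleles table.

    Requires at least a 2 x 2 table with no zero row/column margins;
    cells with expected count below 5 are flagged but not excluded.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 allele categories")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    low = [
        (str(counts.index[i]), str(counts.columns[j]))
        for i, j in zip(*np.where(expected < 5))
    ]
    return ContingencyResult(chi2=float(chi2), df=int(dof), p=float(p),
                             low_expected_cells=low)


# ---------------------------------------------------------------------------
# Effect tables
# ---------------------------------------------------------------------------

def percent_difference(difference: float, baseline: float, ndigits: int = 1) -> float:
    """100 * difference / baseline, rounded half-up (printed-table style)."""
    return round_half_up(100.0 * difference / baseline, ndigits)


@dataclass
class EffectTable:
    """Per-trait LS means by haplotype group with differences."""

    table: pd.DataFrame  # trait, mean/se per level, diff, pct_diff, F, P
    high_level: str
    baseline_level: str


def effect_table(
    phenotypes: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    high_level: str,
    baseline_level: str,
    trait_col: str = "trait",
    line_col: str = "line_id",
    env_col: str = "environment",
    value_col: str = "value",
) -> EffectTable:
    """LS means and (high - baseline) effects per trait.

    ``groups`` maps line id to haplotype group (e.g. H1/H2 by the
    diagnostic marker).  Each trait is analyzed with the
    environments-as-blocks ANOVA; the table reports the group LS means and
    standard errors, the high-minus-baseline difference, the percent
    difference over the baseline, and the group F test P value.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    d = phenotypes.copy()
    d["_group"] = d[line_col].map(groups)
    d = d.dropna(subset=["_group"])
    rows = []
    for trait, sub in d.groupby(trait_col, sort=True):
        res = blocked_ls_means(
            sub, classifier="_group", blocks=env_col, response=value_col
        )
        ls = res.ls_means
        hi = float(ls.loc[high_level, "mean"])
        base = float(ls.loc[baseline_level, "mean"])
        diff = hi - base
        row = {"trait": trait, "F": res.f_value, "P": res.p_value,
               "diff": diff, "pct_diff": percent_difference(diff, base)}
        for lvl in ls.index:
            row[f"mean_{lvl}"] = float(ls.loc[lvl, "mean"])
            row[f"se_{lvl}"] = float(ls.loc[lvl, "se"])
        rows.append(row)
    return EffectTable(
        table=pd.DataFrame(rows),
        high_level=high_level,
        baseline_level=baseline_level,
    )


# ---------------------------------------------------------------------------
# qRT-PCR quantification
# ---------------------------------------------------------------------------

def fold_actin(
    ct_target: "float | np.ndarray", ct_actin: "float | np.ndarray",
    efficiency: float | None = None,
) -> "float | np.ndarray":
    """Transcript level as fold of the ACTIN endogenous control.

    Plain 2**dCT with dCT = ct_actin - ct_target (the default, matching
    common practice for fold-ACTIN reporting).  Passing an amplification
    ``efficiency`` e (e.g. 0.92) switches to (1+e)**dCT; this correction is
    off by default.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_actin = np.asarray(ct_actin, dtype=float)
    if np.any(ct_target <= 0) or np.any(ct_actin <= 0):
        raise ValueError("CT values must be positive")
    base = 2.0 if efficiency is None else 1.0 + efficiency
    out = base ** (ct_actin - ct_target)
    return float(out) if out.ndim == 0 else out


def tukey_letters(
    data: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey HSD with a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Returns a frame indexed by group with columns mean, n, letters.
    """
    d = data[[group_col, value_col]].dropna()
    groups = sorted(d[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for Tukey comparisons")
    res = pairwise_tukeyhsd(
        d[value_col].to_numpy(float), d[group_col].astype(str).to_numpy(),
        alpha=alpha,
    )
    sig = {}
    tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    for _, r in tbl.iterrows():
        sig[(str(r["group1"]), str(r["group2"]))] = bool(r["reject"])

    # insert-and-absorb compact letter display
    letter_sets: list[set[str]] = [set(groups)]
    for (g1, g2), reject in sig.items():
        if not reject:
            continue
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            s1, s2 = s - {g1}, s - {g2}
            for cand in (s1, s2):
                if cand and not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    rows = []
    means = d.groupby(d[group_col].astype(str))[value_col].agg(["mean", "count"])
    order = means.sort_values("mean", ascending=False).index
    lettered = {
        g: "".join(
            alphabet[k] for k, s in enumerate(letter_sets) if g in s
        )
        for g in groups
    }
    for g in order:
        rows.append(
            {"group": g, "mean": float(means.loc[g, "mean"]),
             "n": int(means.loc[g, "count"]), "letters": lettered[g]}
        )
    return pd.DataFrame(rows).set_index("group")
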