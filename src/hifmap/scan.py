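"""Interval mapping by Haley-Knott regression on genotype probabilities.

The scan computes, at every marker and at pseudo-positions every 1 cM,
conditional genotype probabilities from the nearest informative flanking
markers (Markov under no interference), regresses the phenotype on the
expected additive dosage (plus a dominance term for F2), and reports a LOD
curve with additive effects and percent variance explained:

    LOD = (n/2) * log10(RSS0 / RSS1),      PVE = 1 - 10**(-2 LOD / n).

Selfed RILs use the expanded recombination fraction R = 2r/(1+2r) and the
two-state {A, B} support; residual heterozygous calls are treated as
uninformative there.  Peaks above the LOD threshold (default 2.0) carry
1.5-LOD support intervals; a joint multi-QTL fit reports drop-one percent
variance explained per QTL.  Least-squares group means over environment
blocks (the fixed-effects replacement for mixed-model adjustment) live
here too, shared with the progeny-test and effect-table stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.anova import anova_lm

from .genetics import (
    GeneticMap,
    GenomicInterval,
    GenotypeMatrix,
    _MAP_FUNCS,
    ril_expansion,
)

PopulationType = Literal["F2", "RIL_self"]

DEFAULT_LOD_THRESHOLD = 2.0
DEFAULT_LOD_DROP = 1.5

_F2_PRIOR = np.array([0.25, 0.5, 0.25])
_RIL_PRIOR = np.array([0.5, 0.0, 0.5])


# ---------------------------------------------------------------------------
# Conditional genotype probabilities
# ---------------------------------------------------------------------------

@dataclass
class GenotypeProbabilities:
    """Per line x scan position probabilities over {A, H, B}."""

    line_ids: list[str]
    positions: pd.DataFrame  # chrom, pos_cM, pos_bp, marker (or "")
    probs: np.ndarray        # (n_lines, n_positions, 3), rows sum to 1
    population_type: PopulationType
    uninformative_lines: list[tuple[str, str]]  # (line, chrom) with no data

    @property
    def additive_dosage(self) -> np.ndarray:
        """E[x] with x = -1 (A), 0 (H), +1 (B); shape (n_lines, n_pos)."""
        return self.probs[:, :, 2] - self.probs[:, :, 0]

    @property
    def het_probability(self) -> np.ndarray:
        return self.probs[:, :, 1]


def _f2_rows(g: np.ndarray, r: np.ndarray) -> np.ndarray:
    """T[g, :] of the F2 genotype transition matrix, vectorized.

    T(A->.) = [(1-r)^2, 2r(1-r), r^2]; T(H->.) = [r(1-r), (1-r)^2+r^2,
    r(1-r)]; T(B->.) mirrors T(A->.).  Rows for g < 0 (missing) are the
    prior.
    """
    q = 1.0 - r
    rows = np.empty((len(r), 3))
    a = np.stack([q * q, 2 * r * q, r * r], axis=1)
    h = np.stack([r * q, q * q + r * r, r * q], axis=1)
    rows[:] = _F2_PRIOR
    rows[g == 0] = a[g == 0]
    rows[g == 1] = h[g == 1]
    rows[g == 2] = a[g == 2][:, ::-1]
    return rows


def _f2_cols(g: np.ndarray, r: np.ndarray) -> np.ndarray:
    """T[:, g] of the F2 transition matrix (P(observed flank | state))."""
    q = 1.0 - r
    cols = np.empty((len(r), 3))
    ca = np.stack([q * q, r * q, r * r], axis=1)
    ch = np.stack([2 * r * q, q * q + r * r, 2 * r * q], axis=1)
    cols[:] = 1.0  # missing flank contributes no information
    cols[g == 0] = ca[g == 0]
    cols[g == 1] = ch[g == 1]
    cols[g == 2] = ca[g == 2][:, ::-1]
    return cols


def _ril_rows(g: np.ndarray, bigR: np.ndarray) -> np.ndarray:
    rows = np.empty((len(bigR), 3))
    a = np.stack([1.0 - bigR, np.zeros_like(bigR), bigR], axis=1)
    rows[:] = _RIL_PRIOR
    rows[g == 0] = a[g == 0]
    rows[g == 2] = a[g == 2][:, ::-1]
    return rows


def _ril_cols(g: np.ndarray, bigR: np.ndarray) -> np.ndarray:
    cols = np.empty((len(bigR), 3))
    a = np.stack([1.0 - bigR, np.zeros_like(bigR), bigR], axis=1)
    cols[:] = 1.0
    cols[g == 0] = a[g == 0]
    cols[g == 2] = a[g == 2][:, ::-1]
    return cols


def _scan_grid(cm: np.ndarray, bp: np.ndarray, step_cm: float) -> np.ndarray:
    """Union of marker positions and a regular cM grid, as cM values."""
    grid = [cm]
    if step_cm > 0 and cm[-1] - cm[0] > step_cm:
        grid.append(np.arange(cm[0], cm[-1], step_cm))
    allcm = np.concatenate(grid)
    allcm = np.unique(np.round(allcm, 9))
    return allcm


def conditional_genotype_probs(
    observed: GenotypeMatrix,
    gmap: GeneticMap,
    population_type: PopulationType,
    step_cm: float = 1.0,
) -> GenotypeProbabilities:
    """Genotype probabilities at markers and pseudo-positions.

    At a typed, non-missing marker the probability mass sits on the
    observed call; elsewhere probabilities come from the nearest
    informative flanking markers through the map function of ``gmap``
    (expanded to the RIL scale for selfed RILs).  Lines with no
    informative marker on a chromosome get the population prior there and
    are flagged.
    """
    if population_type not in ("F2", "RIL_self"):
        raise ValueError(f"unsupported population type {population_type!r}")
    from_cm = _MAP_FUNCS[(gmap.map_function, "from_cM")]
    codes_all = observed.codes()
    name_to_col = {n: j for j, n in enumerate(observed.marker_names)}

    pos_rows = []
    prob_chunks = []
    flagged: list[tuple[str, str]] = []
    n = observed.n_lines

    for chrom in gmap.chroms:
        markers = [m for m in gmap.chrom_markers(chrom) if m.name in name_to_col]
        if not markers:
            continue
        cm = np.asarray(
            [gmap.positions_cM(chrom)[i]
             for i, m in enumerate(gmap.chrom_markers(chrom))
             if m.name in name_to_col]
        )
        bp = np.array([m.pos_bp for m in markers], dtype=float)
        codes = codes_all[:, [name_to_col[m.name] for m in markers]]
        m = len(markers)

        informative = codes >= 0
        if population_type == "RIL_self":
            informative &= codes != 1

        idx = np.arange(m)
        last_inf = np.maximum.accumulate(np.where(informative, idx, -1), axis=1)
        next_inf = np.minimum.accumulate(
            np.where(informative, idx, m)[:, ::-1], axis=1
        )[:, ::-1]

        none_inf = ~informative.any(axis=1)
        for i in np.flatnonzero(none_inf):
            flagged.append((observed.line_ids[i], chrom))

        grid = _scan_grid(cm, bp, step_cm)
        grid_bp = np.interp(grid, cm, bp)
        marker_at = {}
        for j, c in enumerate(cm):
            marker_at.setdefault(round(float(c), 9), markers[j].name)

        chunk = np.empty((n, len(grid), 3))
        prior = _F2_PRIOR if population_type == "F2" else _RIL_PRIOR
        rows_fn = _f2_rows if population_type == "F2" else _ril_rows
        cols_fn = _f2_cols if population_type == "F2" else _ril_cols

        jL_all = np.searchsorted(cm, grid, side="right") - 1
        jR_all = np.searchsorted(cm, grid, side="left")
        for k, c in enumerate(grid):
            jL, jR = jL_all[k], min(jR_all[k], m - 1)
            li = last_inf[:, jL]
            ri = next_inf[:, jR]
            has_l = li >= 0
            has_r = ri < m
            dL = np.maximum(np.where(has_l, c - cm[np.clip(li, 0, m - 1)], 0.0), 0.0)
            dR = np.maximum(np.where(has_r, cm[np.clip(ri, 0, m - 1)] - c, 0.0), 0.0)
            rL = np.array([from_cm(d) for d in dL])
            rR = np.array([from_cm(d) for d in dR])
            if population_type == "RIL_self":
                rL = np.array([ril_expansion(x) for x in rL])
                rR = np.array([ril_expansion(x) for x in rR])
            gL = np.where(has_l, codes[np.arange(n), np.clip(li, 0, m - 1)], -1)
            gR = np.where(has_r, codes[np.arange(n), np.clip(ri, 0, m - 1)], -1)
            w = rows_fn(gL, rL) * cols_fn(gR, rR)
            neither = ~(has_l | has_r)
            w[neither] = prior
            w /= w.sum(axis=1, keepdims=True)
            chunk[:, k, :] = w

        prob_chunks.append(chunk)
        for k, c in enumerate(grid):
            pos_rows.append(
                (chrom, float(c), float(grid_bp[k]),
                 marker_at.get(round(float(c), 9), ""))
            )

    positions = pd.DataFrame(pos_rows, columns=["chrom", "pos_cM", "pos_bp", "marker"])
    probs = np.concatenate(prob_chunks, axis=1) if prob_chunks else np.empty((n, 0, 3))
    return GenotypeProbabilities(
        line_ids=observed.line_ids,
        positions=positions,
        probs=probs,
        population_type=population_type,
        uninformative_lines=flagged,
    )


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------

@dataclass
class LODCurve:
    """LOD, additive effect and PVE at each scan position."""

    table: pd.DataFrame  # chrom, pos_cM, pos_bp, marker, lod, effect, pve
    n_lines: int

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


@dataclass
class QTLPeak:
    chrom: str
    pos_bp: float
    pos_cM: float
    lod: float
    effect: float
    pve: float
    support: GenomicInterval


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def hk_scan(
    probs: GenotypeProbabilities,
    phenotype: "pd.Series | np.ndarray",
) -> LODCurve:
    """Haley-Knott regression of the phenotype on expected dosages.

    ``phenotype`` is one adjusted value per line (a pandas Series indexed
    by line id, or an array aligned with ``probs.line_ids``).  Lines with
    missing phenotype are dropped; at least three are required.  Positions
    where the expected dosage is constant contribute LOD exactly 0.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(probs.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != len(probs.line_ids):
            raise ValueError("phenotype length does not match lines")
    keep = np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 non-missing phenotyped lines")
    y = y[keep]
    xa_all = probs.additive_dosage[keep]
    xd_all = probs.het_probability[keep]
    n = len(y)

    tss = float(((y - y.mean()) ** 2).sum())
    n_pos = xa_all.shape[1]
    lod = np.zeros(n_pos)
    effect = np.zeros(n_pos)
    if tss <= 0:
        warnings.warn("phenotype has zero variance; LOD curve is identically 0")
    else:
        ones = np.ones(n)
        use_dom = probs.population_type == "F2"
        for k in range(n_pos):
            xa = xa_all[:, k]
            cols = [ones]
            if np.ptp(xa) > 1e-12:
                cols.append(xa)
            if use_dom and np.ptp(xd_all[:, k]) > 1e-12:
                cols.append(xd_all[:, k])
            if len(cols) == 1:
                continue  # constant genotype column: LOD exactly 0
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss1 = float(resid @ resid)
            if rss1 <= 0:
                rss1 = np.finfo(float).tiny
            lod[k] = max(0.0, (n / 2.0) * np.log10(tss / rss1))
            effect[k] = beta[1] if len(cols) > 1 and np.ptp(xa) > 1e-12 else 0.0

    pve = 1.0 - 10.0 ** (-2.0 * lod / n)
    table = probs.positions.copy()
    table["lod"] = lod
    table["effect"] = effect
    table["pve"] = pve
    return LODCurve(table=table, n_lines=n)


def find_peaks(
    curve: LODCurve,
    threshold: float = DEFAULT_LOD_THRESHOLD,
    lod_drop: float = DEFAULT_LOD_DROP,
) -> list[QTLPeak]:
    """LOD peaks above ``threshold`` with LOD-drop support intervals.

    Each contiguous supra-threshold run on a chromosome yields one peak
    (its maximum; ties break toward the smaller bp coordinate), so linked
    QTLs on one chromosome whose curves dip below the threshold between
    them are reported separately.  The support interval is the contiguous
    run around the peak where LOD stays within ``lod_drop`` of the peak.
    """
    peaks = []
    for chrom, sub in curve.table.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos_bp"]).reset_index(drop=True)
        lods = sub["lod"].to_numpy()
        above = lods >= threshold
        i = 0
        while i < len(lods):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(lods) and above[j + 1]:
                j += 1
            run = lods[i : j + 1]
            best = i + int(np.flatnonzero(run == run.max())[0])
            lo = best
            while lo > 0 and lods[lo - 1] >= lods[best] - lod_drop:
                lo -= 1
            hi = best
            while hi < len(lods) - 1 and lods[hi + 1] >= lods[best] - lod_drop:
                hi += 1
            support = GenomicInterval(
                chrom,
                int(round(sub.loc[lo, "pos_bp"])),
                int(round(sub.loc[hi, "pos_bp"])),
            )
            peaks.append(
                QTLPeak(
                    chrom=chrom,
                    pos_bp=float(sub.loc[best, "pos_bp"]),
                    pos_cM=float(sub.loc[best, "pos_cM"]),
                    lod=float(lods[best]),
                    effect=float(sub.loc[best, "effect"]),
                    pve=float(sub.loc[best, "pve"]),
                    support=support,
                )
            )
            i = j + 1
    return peaks


def multi_qtl_fit(
    peaks: Sequence[QTLPeak | tuple[str, float]],
    probs: GenotypeProbabilities,
    phenotype: "pd.Series | np.ndarray",
) -> pd.DataFrame:
    """Joint additive fit at the peak positions with drop-one PVE.

    Returns one row per QTL (chrom, pos_bp, effect, pve_drop_one) plus the
    total model PVE in ``df.attrs['total_pve']``.  No interaction terms are
    fitted (effects are additive across loci).
    """
    if not peaks:
        raise ValueError("multi_qtl_fit requires at least one peak")
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(probs.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]

    pos_tab = probs.positions
    idxs = []
    for p in peaks:
        chrom, pos = (p.chrom, p.pos_bp) if isinstance(p, QTLPeak) else p
        on_chrom = pos_tab.index[pos_tab["chrom"] == chrom]
        if len(on_chrom) == 0:
            raise ValueError(f"no scan positions on chromosome {chrom}")
        j = on_chrom[np.argmin(np.abs(pos_tab.loc[on_chrom, "pos_bp"] - pos))]
        if j in idxs:
            raise ValueError("collinear peaks: the same scan position twice")
        idxs.append(j)

    xa = probs.additive_dosage[keep][:, idxs]
    n = len(y)
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, xa])
    tss = float(((y - y.mean()) ** 2).sum())
    rss_full = _rss(y, X_full)
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)

    rows = []
    for q, p in enumerate(peaks):
        chrom, pos = (p.chrom, p.pos_bp) if isinstance(p, QTLPeak) else p
        X_drop = np.hstack([ones, np.delete(xa, q, axis=1)])
        rss_drop = _rss(y, X_drop)
        rows.append(
            {
                "chrom": chrom,
                "pos_bp": pos,
                "effect": float(beta[1 + q]),
                "pve_drop_one": (rss_drop - rss_full) / tss,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total_pve"] = 1.0 - rss_full / tss
    return out


# ---------------------------------------------------------------------------
# Blocked least-squares means
# ---------------------------------------------------------------------------

@dataclass
class BlockedAnovaResult:
    """Two-way fixed-effects ANOVA (classifier + block) for one response."""

    f_value: float
    p_value: float
    df_num: int
    df_den: int
    ls_means: pd.DataFrame  # index: level; columns: mean, se, n


def _check_connected(d: pd.DataFrame) -> None:
    """Levels and blocks must form one connected bipartite component."""
    cells = set(zip(d["_lvl"], d["_blk"]))
    levels = sorted({c[0] for c in cells})
    adj: dict = {}
    for lvl, blk in cells:
        adj.setdefault(("L", lvl), set()).add(("B", blk))
        adj.setdefault(("B", blk), set()).add(("L", lvl))
    seen = set()
    stack = [("L", levels[0])]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adj[node] - seen)
    if any(("L", lvl) not in seen for lvl in levels):
        raise ValueError(
            "design is not connected across blocks; LS means are not estimable"
        )


def blocked_ls_means(
    phenotypes: pd.DataFrame,
    classifier: str,
    blocks: str,
    response: str = "value",
) -> BlockedAnovaResult:
    """Least-squares means per classifier level with environments as blocks.

    Fits the additive fixed-effects model ``response ~ classifier + block``
    by OLS and reports the classifier F test (type II, equal to type III
    for this additive model) plus model-adjusted means: each level's
    prediction averaged over all blocks with equal weight, with standard
    errors from the coefficient covariance.  With balanced data and no
    missing cells these equal the raw level means.
    """
    d = pd.DataFrame(
        {
            "_y": phenotypes[response].astype(float),
            "_lvl": phenotypes[classifier].astype(str),
            "_blk": phenotypes[blocks].astype(str),
        }
    ).dropna()
    counts = d["_lvl"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classifier levels")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 observations per level; too few in {small}")
    _check_connected(d)

    block_levels = sorted(d["_blk"].unique())
    formula = "_y ~ C(_lvl) + C(_blk)" if len(block_levels) > 1 else "_y ~ C(_lvl)"
    model = smf.ols(formula, data=d).fit()
    table = anova_lm(model, typ=2)
    f_value = float(table.loc["C(_lvl)", "F"])
    p_value = float(table.loc["C(_lvl)", "PR(>F)"])
    df_num = int(table.loc["C(_lvl)", "df"])
    df_den = int(table.loc["Residual", "df"])

    design_info = model.model.data.design_info
    cov = model.cov_params().to_numpy()
    params = model.params.to_numpy()
    rows = []
    for lvl in sorted(d["_lvl"].unique()):
        new = pd.DataFrame({"_lvl": [lvl] * len(block_levels), "_blk": block_levels})
        (X,) = build_design_matrices([design_info], new)
        L = np.asarray(X).mean(axis=0)
        mean = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        rows.append({"level": lvl, "mean": mean, "se": se, "n": int(counts[lvl])})
    ls = pd.DataFrame(rows).set_index("level")
    return BlockedAnovaResult(
        f_value=f_value, p_value=p_value, df_num=df_num, df_den=df_den, ls_means=ls
    )


# ---------------------------------------------------------------------------
# Null behavior of the scan
# ---------------------------------------------------------------------------

def estimate_null_lod_exceedance(
    n_lines: int = 100,
    n_sims: int = 200,
    threshold: float = DEFAULT_LOD_THRESHOLD,
    seed: int = 0,
    n_markers: int = 9,
    chrom_length_cm: float = 100.0,
) -> float:
    """Fraction of null simulations whose maximum LOD reaches ``threshold``.

    Simulates selfed-RIL genotypes on a single chromosome, draws phenotypes
    independent of genotype, scans, and reports the genome-wide type-I
    rate at the given LOD threshold.  No reference value is asserted; this
    quantifies the permissiveness of a fixed LOD cutoff.
    """
    from . import simulate as sim
    from .genetics import GeneticMap, Marker

    spacing = chrom_length_cm / (n_markers - 1)
    markers = [
        Marker(f"M{j}", "1X", 1_000_000 + j * 10_000_000, pos_cM=j * spacing)
        for j in range(n_markers)
    ]
    gmap = GeneticMap(markers=markers, map_function="haldane")
    rng = np.random.default_rng(seed)
    hits = 0
    for s in range(n_sims):
        pop = sim.simulate_population(
            sim.CrossDesign(
                "RIL_self", n_lines, gmap,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
        )
        probs = conditional_genotype_probs(pop.genotypes, gmap, "RIL_self")
        y = rng.normal(size=n_lines)
        if hk_scan(probs, y).max_lod() >= threshold:
            hits += 1
    return hits / n_sims
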