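"""Recombinant screening, progeny tests and interval deduction for HIFs.

The high-resolution mapping procedure encoded here: screen segregating
progeny for recombination between two flanking markers, group recombinants
by breakpoint class, progeny-test homozygous recombinant vs non-recombinant
sister lines (combined ANOVA with experiments as blocks), classify each
family as *heterozygous* (the locus still segregates: it lies inside the
family's heterozygous segment) or *homozygous* (it does not), and intersect
those constraints to deduce the candidate interval that must contain the
Mendelized locus.

Segment conventions: a family's *maximal* heterozygous segment extends to,
but excludes, the nearest flanking non-H non-missing markers (the locus
lies strictly between them); its *minimal* segment spans the outermost H
calls inclusive.  A heterozygous family constrains the locus to the open
interval between its flanks; a homozygous family excludes its minimal
segment.  The deduced candidate is the widest marker-bounded run of
between-marker gaps consistent with every constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genetics import GenomicInterval, GenotypeMatrix, Marker, MISSING
from .scan import BlockedAnovaResult, blocked_ls_means

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Recombinant screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Outcome of a two-flank recombinant screen."""

    recombinant_ids: list[str]
    excluded_missing_ids: list[str]
    n_screened: int

    @property
    def n_recombinant(self) -> int:
        return len(self.recombinant_ids)

    @property
    def recombinant_fraction(self) -> float:
        n_eval = self.n_screened - len(self.excluded_missing_ids)
        return self.n_recombinant / n_eval if n_eval else math.nan


def find_recombinants(
    genotypes: GenotypeMatrix, left_marker: str, right_marker: str
) -> ScreenResult:
    """Lines whose calls at the two flanking markers differ.

    Any discordant pattern (A/H, H/B, A/B, ...) counts as a recombination
    event between the flanks; lines missing either flank are excluded and
    reported separately.  Swapped flank arguments are auto-corrected with a
    warning.
    """
    by_name = {m.name: m for m in genotypes.markers}
    for name in (left_marker, right_marker):
        if name not in by_name:
            raise KeyError(f"flanking marker {name!r} not in genotype matrix")
    if by_name[left_marker].pos_bp > by_name[right_marker].pos_bp:
        import warnings

        warnings.warn("left/right flanking markers were swapped; corrected")
        left_marker, right_marker = right_marker, left_marker
    left = genotypes.calls[left_marker]
    right = genotypes.calls[right_marker]
    missing = (left == MISSING) | (right == MISSING)
    discordant = (left != right) & ~missing
    return ScreenResult(
        recombinant_ids=list(genotypes.calls.index[discordant]),
        excluded_missing_ids=list(genotypes.calls.index[missing]),
        n_screened=genotypes.n_lines,
    )


# ---------------------------------------------------------------------------
# Breakpoint classes
# ---------------------------------------------------------------------------

@dataclass
class BreakpointClasses:
    """Recombinant lines grouped by identical (missing-tolerant) genotype
    vectors over the region markers."""

    classes: list[list[str]]            # line ids per class
    class_keys: list[str]               # marker interval holding the transition
    unclassifiable: list[str]           # lines with > 50% missing in region

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _compatible(u: np.ndarray, v: np.ndarray) -> bool:
    both = (u >= 0) & (v >= 0)
    return bool(np.all(u[both] == v[both]))


def _transition_key(vec: np.ndarray, markers: Sequence[Marker]) -> str:
    """Marker interval containing the (first) genotype transition."""
    obs = np.flatnonzero(vec >= 0)
    for a, b in zip(obs, obs[1:]):
        if vec[a] != vec[b]:
            return f"{markers[a].name}..{markers[b].name}"
    return "none"


def group_by_breakpoint(
    genotypes: GenotypeMatrix, recombinant_ids: Sequence[str]
) -> BreakpointClasses:
    """Group recombinants whose region genotype vectors match wherever both
    are observed (connected components of pairwise compatibility).

    Lines with more than 50% missing calls over the region markers are
    flagged unclassifiable and left out of the classes.
    """
    sub = genotypes.subset_lines(list(recombinant_ids))
    codes = sub.codes()
    miss_frac = (codes < 0).mean(axis=1)
    usable = np.flatnonzero(miss_frac <= 0.5)
    unclassifiable = [sub.line_ids[i] for i in np.flatnonzero(miss_frac > 0.5)]

    parent = {int(i): int(i) for i in usable}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai in range(len(usable)):
        for bi in range(ai + 1, len(usable)):
            a, b = int(usable[ai]), int(usable[bi])
            if _compatible(codes[a], codes[b]):
                parent[find(a)] = find(b)

    groups: dict[int, list[int]] = {}
    for i in usable:
        groups.setdefault(find(int(i)), []).append(int(i))

    ordered = sorted(groups.values(), key=lambda g: min(g))
    classes = [[sub.line_ids[i] for i in g] for g in ordered]
    keys = []
    for g in ordered:
        # consensus vector: first observed call per site within the class
        cons = np.full(codes.shape[1], -1, dtype=np.int8)
        for i in g:
            fill = (cons < 0) & (codes[i] >= 0)
            cons[fill] = codes[i][fill]
        keys.append(_transition_key(cons, sub.markers))
    return BreakpointClasses(classes=classes, class_keys=keys,
                             unclassifiable=unclassifiable)


# ---------------------------------------------------------------------------
# Families and progeny tests
# ---------------------------------------------------------------------------

@dataclass
class RecombinantFamily:
    """A recombinant line/family with its heterozygous-segment bounds.

    ``het_segment_max`` runs between (exclusive of) the nearest non-H,
    non-missing markers flanking the observed H calls; ``het_segment_min``
    spans the outermost H calls inclusive.  ``het_runs`` lists the maximal
    contiguous runs of H calls separately: a line can carry more than one
    residual heterozygous segment, and only the observed runs — not the
    non-H markers between them — are evidence that the locus is absent
    from a homozygous-classified family.
    """

    family_id: str
    het_segment_max: GenomicInterval | None  # open: flanks excluded
    het_segment_min: GenomicInterval | None  # inclusive span of H calls
    het_runs: "list[GenomicInterval] | None" = None

    def exclusion_segments(self) -> list[GenomicInterval]:
        """Intervals a homozygous classification rules out for the locus."""
        if self.het_runs is not None:
            return self.het_runs
        return [self.het_segment_min] if self.het_segment_min else []

    @classmethod
    def from_genotypes(
        cls,
        family_id: str,
        calls: pd.Series,
        markers: Sequence[Marker],
        region: GenomicInterval,
    ) -> "RecombinantFamily":
        """Derive segment bounds from founder calls at the region markers.

        All segments are ``None``/empty when the founder shows no H call
        in the region.
        """
        vec = np.array([calls[m.name] for m in markers])
        pos = np.array([m.pos_bp for m in markers])
        het = np.flatnonzero(vec == "H")
        if len(het) == 0:
            return cls(family_id, None, None)
        first, last = het[0], het[-1]
        hom = np.flatnonzero((vec != "H") & (vec != MISSING))
        left_flank = hom[hom < first]
        right_flank = hom[hom > last]
        lo = int(pos[left_flank[-1]]) if len(left_flank) else region.start_bp
        hi = int(pos[right_flank[0]]) if len(right_flank) else region.end_bp
        runs = []
        start = het[0]
        prev = het[0]
        for j in het[1:]:
            # a run breaks where a non-H, non-missing marker intervenes
            if np.any((vec[prev + 1 : j] != "H") & (vec[prev + 1 : j] != MISSING)):
                runs.append(GenomicInterval(region.chrom, int(pos[start]),
                                            int(pos[prev])))
                start = j
            prev = j
        runs.append(GenomicInterval(region.chrom, int(pos[start]), int(pos[prev])))
        return cls(
            family_id,
            het_segment_max=GenomicInterval(region.chrom, lo, hi),
            het_segment_min=GenomicInterval(
                region.chrom, int(pos[first]), int(pos[last])
            ),
            het_runs=runs,
        )


@dataclass
class ProgenyTestResult:
    """Combined-ANOVA classification of a recombinant family."""

    family_id: str
    f_value: float
    p_value: float
    classification: Literal["heterozygous", "homozygous"]
    alpha: float
    ls_means: pd.DataFrame
    anova: BlockedAnovaResult = field(repr=False)


def progeny_test_classify(
    family_id: str,
    phenotypes: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    class_col: str = "sister_class",
    experiment_col: str = "experiment",
    value_col: str = "value",
) -> ProgenyTestResult:
    """Classify a family from its sister-line progeny test.

    ``phenotypes`` holds the per-plant records of the two homozygous
    sister-line classes across experiments.  A combined two-way ANOVA
    (class + experiment block) is fitted; the family is *heterozygous* iff
    the class effect is significant at ``alpha`` (the locus segregates in
    the family), else *homozygous*.
    """
    n_classes = phenotypes[class_col].nunique()
    if n_classes < 2:
        raise ValueError(
            f"progeny test incomplete for {family_id}: both homozygous "
            "sister-line classes are required"
        )
    res = blocked_ls_means(
        phenotypes, classifier=class_col, blocks=experiment_col, response=value_col
    )
    cls = "heterozygous" if res.p_value < alpha else "homozygous"
    return ProgenyTestResult(
        family_id=family_id,
        f_value=res.f_value,
        p_value=res.p_value,
        classification=cls,
        alpha=alpha,
        ls_means=res.ls_means,
        anova=res,
    )


# ---------------------------------------------------------------------------
# Interval deduction
# ---------------------------------------------------------------------------

@dataclass
class LocusDeduction:
    """Candidate interval plus the per-family constraints that shaped it.

    When the homozygous-family exclusions split the consistent region into
    disjoint pieces, the locus could lie in any of them: the widest piece
    is reported as ``candidate_interval`` and the rest as
    ``alternative_intervals`` (the evidence is ambiguous until further
    markers or families resolve it — never silently discarded).
    """

    candidate_interval: GenomicInterval
    left_marker: str
    right_marker: str
    constraints: pd.DataFrame  # family, classification, segment bounds
    conflicts: list[str]       # families removed to restore consistency
    alternative_intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def ambiguous(self) -> bool:
        return bool(self.alternative_intervals)

    def viable_intervals(self) -> list[GenomicInterval]:
        """Every region consistent with the constraints (candidate first)."""
        return [self.candidate_interval, *self.alternative_intervals]


def _viable_gaps(
    gap_bounds: list[tuple[int, int]],
    het_max: list[GenomicInterval],
    hom_min: list[GenomicInterval],
) -> list[bool]:
    out = []
    for lo, hi in gap_bounds:
        ok = all(seg.start_bp <= lo and hi <= seg.end_bp for seg in het_max)
        # a homozygous family's minimal segment vetoes a gap iff it covers
        # part of the open gap interval
        ok = ok and not any(
            seg.start_bp < hi and seg.end_bp > lo for seg in hom_min
        )
        out.append(ok)
    return out


def _viable_runs(viable: list[bool], gap_bounds: list[tuple[int, int]]):
    """Contiguous runs of viable gaps as (width, first gap, last gap),
    widest first; ties toward the smaller bp coordinate."""
    runs = []
    i = 0
    while i < len(viable):
        if viable[i]:
            j = i
            while j + 1 < len(viable) and viable[j + 1]:
                j += 1
            runs.append((gap_bounds[j][1] - gap_bounds[i][0], i, j))
            i = j + 1
        else:
            i += 1
    return sorted(runs, key=lambda r: (-r[0], gap_bounds[r[1]][0]))


def deduce_locus_interval(
    families: Sequence[tuple[RecombinantFamily, "ProgenyTestResult | str"]],
    markers: Sequence[Marker],
    region: GenomicInterval,
) -> LocusDeduction:
    """Intersect family constraints into the candidate locus interval.

    Heterozygous families confine the locus to the open interval between
    their non-H flanking markers; homozygous families exclude each of
    their observed heterozygous runs.  The candidate is the widest
    contiguous run of between-marker gaps satisfying every constraint,
    reported as the marker-bounded interval spanning the run; any other
    surviving runs are returned as ``alternative_intervals`` (ambiguous
    evidence).  If no gap survives, families are removed greedily (most
    gaps vetoed first) and reported as conflicts; an empty result after
    removal raises with a full report.
    """
    marks = sorted(
        (m for m in markers if region.contains_pos(m.chrom, m.pos_bp)),
        key=lambda m: m.pos_bp,
    )
    if len(marks) < 2:
        raise ValueError("need at least two region markers to bound the locus")
    pos = [m.pos_bp for m in marks]
    gap_bounds = list(zip(pos, pos[1:]))

    het_fams, hom_fams, rows = [], [], []
    for fam, test in families:
        label = test if isinstance(test, str) else test.classification
        if label not in ("heterozygous", "homozygous"):
            raise ValueError(f"unknown classification {label!r}")
        rows.append(
            {
                "family_id": fam.family_id,
                "classification": label,
                "het_max_start": fam.het_segment_max.start_bp if fam.het_segment_max else None,
                "het_max_end": fam.het_segment_max.end_bp if fam.het_segment_max else None,
                "het_min_start": fam.het_segment_min.start_bp if fam.het_segment_min else None,
                "het_min_end": fam.het_segment_min.end_bp if fam.het_segment_min else None,
            }
        )
        if label == "heterozygous":
            if fam.het_segment_max is None:
                raise ValueError(
                    f"family {fam.family_id} classified heterozygous but has "
                    "no heterozygous segment"
                )
            het_fams.append(fam)
        elif fam.het_segment_min is not None:
            hom_fams.append(fam)
    if not het_fams:
        raise ValueError("at least one heterozygous-classified family required")

    constraints = pd.DataFrame(rows)
    active = list(het_fams) + list(hom_fams)
    conflicts: list[str] = []

    def gaps_for(fams: list[RecombinantFamily]) -> list[bool]:
        hm = [f.het_segment_max for f in fams if f in het_fams]
        ho = [seg for f in fams if f in hom_fams
              for seg in f.exclusion_segments()]
        return _viable_gaps(gap_bounds, hm, ho)

    def solo_vetoes(f: RecombinantFamily) -> int:
        """Gaps this family's constraint rules out on its own."""
        if f in het_fams:
            seg = f.het_segment_max
            return sum(
                not (seg.start_bp <= lo and hi <= seg.end_bp)
                for lo, hi in gap_bounds
            )
        return sum(
            any(seg.start_bp < hi and seg.end_bp > lo
                for seg in f.exclusion_segments())
            for lo, hi in gap_bounds
        )

    viable = gaps_for(active)
    while not any(viable) and len(active) > 1:
        # Greedy removal: prefer the family whose removal reopens the most
        # gaps; when no single removal helps, drop the family with the
        # largest individual constraint violation and continue.
        removable = [
            f for f in active
            if sum(g in het_fams for g in active if g is not f) >= 1
        ]
        if not removable:
            break
        reopened = [sum(gaps_for([g for g in active if g is not f]))
                    for f in removable]
        best = max(reopened)
        if best > 0:
            worst = removable[int(np.argmax(reopened))]
        else:
            worst = max(removable, key=solo_vetoes)
        conflicts.append(worst.family_id)
        active = [g for g in active if g is not worst]
        viable = gaps_for(active)

    if not any(viable):
        report = constraints.to_string(index=False)
        raise ValueError(
            "no locus interval is consistent with the family constraints, "
            f"even after conflict removal:\n{report}"
        )

    runs = _viable_runs(viable, gap_bounds)
    _, i, j = runs[0]
    candidate = GenomicInterval(region.chrom, gap_bounds[i][0], gap_bounds[j][1])
    alternatives = [
        GenomicInterval(region.chrom, gap_bounds[a][0], gap_bounds[b][1])
        for _, a, b in runs[1:]
    ]
    return LocusDeduction(
        candidate_interval=candidate,
        left_marker=marks[i].name,
        right_marker=marks[j + 1].name,
        constraints=constraints,
        conflicts=conflicts,
        alternative_intervals=alternatives,
    )


# ---------------------------------------------------------------------------
# Planning the next screening phase
# ---------------------------------------------------------------------------

@dataclass
class RescreenPlan:
    n_plants: int
    expected_fraction: float
    p_zero_recombinants: float


def plan_rescreen(
    interval: GenomicInterval,
    cm_per_mb: float,
    target_new_recombinants: int,
    population: Literal["F2"] = "F2",
    n_planned: int | None = None,
) -> RescreenPlan:
    """Plants to screen for a target number of new recombinants.

    The expected per-plant recombinant fraction comes from the calibrated
    cM/Mb scalar over the interval width (Haldane), through the F2 screen
    expectation.  Also reports the probability of observing zero
    recombinants among ``n_planned`` plants (default: the computed N).
    """
    from .genetics import haldane_from_cM
    from .simulate import expected_f2_screen_fraction

    if target_new_recombinants <= 0:
        raise ValueError("target must be positive")
    d_cm = interval.width_bp("between_markers") / 1e6 * cm_per_mb
    r = haldane_from_cM(d_cm)
    p = expected_f2_screen_fraction(r)
    if p <= 0:
        raise ValueError("expected recombinant fraction is zero in this interval")
    n = math.ceil(target_new_recombinants / p)
    n_eval = n_planned if n_planned is not None else n
    return RescreenPlan(
        n_plants=n,
        expected_fraction=p,
        p_zero_recombinants=(1.0 - p) ** n_eval,
    )
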