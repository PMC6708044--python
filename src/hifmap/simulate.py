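"""Synthetic biparental populations segregating a Mendelian SNS locus.

Generates the population structures the fine-mapping pipeline consumes:

* F2 progeny of a heterozygous plant (the genotype screened for
  recombinants between flanking markers);
* selfed recombinant inbred lines (RILs) by single-seed descent, whose
  expected residual heterozygosity at generation g is (1/2)**(g-1);
* heterogeneous inbred families (HIFs): sister lines selfed from a
  late-generation RIL that is still heterozygous at the target region, so
  sisters segregate only inside the residual heterozygous segments.

Meiosis follows a Poisson/no-interference crossover model: the crossover
count per chromosome is Poisson in the map length in Morgans and crossover
positions are uniform on the cM scale, i.e. the cM scale is treated as
Haldane cM.  Phenotypes are additive across QTLs (no epistasis), with a
dominance term for heterozygotes, fixed environment (block) effects, an
optional per-line polygenic background term, and Gaussian residual noise.

The cM <-> bp calibration defaults to the scalar that makes an F2 screen of
the 9.13-Mb IWB713--IWB53096 window on 7AL yield the observed recombinant
fraction 74/617: the published screen size is used as a calibration anchor,
not as a validation claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import wheat7al
from .genetics import (
    GeneticMap,
    GenotypeMatrix,
    Marker,
    haldane_to_cM,
)

# Default simulated SNS parameters.  The homozygote gap at the 7AL locus is
# 2 * ADDITIVE_SNS = 2.1 spikelets, the gap estimated in the Berkut x
# RAC875 RILs.  HIF-level residual SD is per-plant greenhouse noise; the
# polygenic background SD makes the RIL-level pooled SD four times the
# HIF-level pooled SD (background loci segregate among RILs but are fixed
# within a HIF).
MU_SNS = 18.0
ADDITIVE_SNS = 1.05
HIF_RESIDUAL_SD = 1.2
RIL_POLYGENIC_SD = HIF_RESIDUAL_SD * math.sqrt(15.0)  # => RIL pooled SD = 4x
DEFAULT_ENV_EFFECTS = {"E1": -1.0, "E2": -0.3, "E3": 0.3, "E4": 1.0}


@dataclass(frozen=True)
class QTLEffect:
    """A QTL with additive effect ``a`` (half the homozygote difference, in
    trait units per allele substitution) and dominance ``d``."""

    chrom: str
    pos_bp: int
    additive: float
    dominance: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.additive) and math.isfinite(self.dominance)):
            raise ValueError("QTL effects must be finite")


@dataclass
class CrossDesign:
    """Specification of a simulated biparental population."""

    population_type: Literal["F2", "RIL_self", "HIF"]
    n_lines: int
    genetic_map: GeneticMap
    rng_seed: int = 0
    ril_generation: int = 6
    hif_source_generation: int = 5
    hif_family_size: int = 20
    #: Optionally require each HIF source line to be heterozygous at this
    #: (chrom, pos_bp) marker, mirroring how HIFs are chosen in practice.
    require_het_at: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.population_type == "RIL_self" and self.ril_generation < 2:
            raise ValueError("RIL generation must be >= 2")
        if self.population_type == "HIF" and self.hif_source_generation < 2:
            raise ValueError("HIF source generation must be >= 2")


@dataclass
class SimulatedPopulation:
    """A simulated population: observed-style calls plus the full truth."""

    genotypes: GenotypeMatrix
    diplotypes: np.ndarray  # (n_lines, 2, n_markers) parental origin 0/1
    pedigree: dict
    design: CrossDesign


def _chrom_slices(gmap: GeneticMap) -> list[tuple[str, slice, np.ndarray]]:
    """Per-chromosome (name, marker slice, cM positions) in map order."""
    out = []
    start = 0
    for chrom in gmap.chroms:
        n = len(gmap.chrom_markers(chrom))
        out.append((chrom, slice(start, start + n), gmap.positions_cM(chrom)))
        start += n
    return out


def simulate_gamete(
    parent_diplotype: np.ndarray,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a parent diplotype.

    ``parent_diplotype`` is a (2, n_markers) array of parental origins
    (0/1) over the map's markers in map order.  The returned haplotype is a
    mosaic of the two parental rows with Poisson crossover counts and
    uniform crossover positions on the cM scale.
    """
    slices = _chrom_slices(genetic_map)
    n_markers = sum(s.stop - s.start for _, s, _ in slices)
    if parent_diplotype.shape != (2, n_markers):
        raise ValueError(
            f"parent diplotype shape {parent_diplotype.shape} does not match "
            f"map with {n_markers} markers"
        )
    gamete = np.empty(n_markers, dtype=np.int8)
    for _, sl, cm in slices:
        length_cm = cm[-1] - cm[0]
        n_xo = rng.poisson(length_cm / 100.0) if length_cm > 0 else 0
        strand = rng.integers(2)
        if n_xo == 0:
            gamete[sl] = parent_diplotype[strand, sl]
            continue
        xo = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
        strands = (strand + np.searchsorted(xo, cm, side="right")) % 2
        gamete[sl] = parent_diplotype[strands, np.arange(sl.start, sl.stop)]
    return gamete


def _f1_diplotype(n_markers: int) -> np.ndarray:
    return np.vstack([np.zeros(n_markers, dtype=np.int8),
                      np.ones(n_markers, dtype=np.int8)])


def _self_once(
    diplotype: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    return np.vstack([simulate_gamete(diplotype, gmap, rng),
                      simulate_gamete(diplotype, gmap, rng)])


def _ril_diplotype(
    gmap: GeneticMap, generation: int, rng: np.random.Generator
) -> np.ndarray:
    """Single-seed descent: F1 selfed ``generation - 1`` times."""
    plant = _f1_diplotype(len(gmap.markers))
    for _ in range(generation - 1):
        plant = _self_once(plant, gmap, rng)
    return plant


def diplotype_to_codes(diplotype: np.ndarray) -> np.ndarray:
    """Genotype codes from parental origins: 0=A, 1=H, 2=B."""
    return (diplotype[0] + diplotype[1]).astype(np.int8)


def simulate_population(design: CrossDesign) -> SimulatedPopulation:
    """Simulate a population according to ``design``.

    For ``HIF`` designs, ``n_lines`` counts families; each family consists
    of ``hif_family_size`` sister lines (ids ``F{i}_S{j}``) selfed from one
    RIL source plant of generation ``hif_source_generation``.  The source
    plants' diplotypes are recorded in the pedigree.
    """
    gmap = design.genetic_map
    rng = np.random.default_rng(design.rng_seed)
    n_markers = len(gmap.markers)
    pedigree: dict = {"design": design.population_type, "seed": design.rng_seed}

    if design.population_type == "F2":
        f1 = _f1_diplotype(n_markers)
        diplos = np.stack(
            [_self_once(f1, gmap, rng) for _ in range(design.n_lines)]
        )
        line_ids = [f"F2_{i + 1}" for i in range(design.n_lines)]
        pedigree["parents"] = ["P1", "P2"]

    elif design.population_type == "RIL_self":
        diplos = np.stack(
            [_ril_diplotype(gmap, design.ril_generation, rng)
             for _ in range(design.n_lines)]
        )
        line_ids = [f"RIL_{i + 1}" for i in range(design.n_lines)]
        pedigree["generation"] = design.ril_generation

    elif design.population_type == "HIF":
        locus_idx = None
        if design.require_het_at is not None:
            chrom, pos = design.require_het_at
            for j, m in enumerate(gmap.markers):
                if m.chrom == chrom and m.pos_bp == pos:
                    locus_idx = j
                    break
            if locus_idx is None:
                raise ValueError(
                    f"require_het_at {design.require_het_at} is not a marker "
                    "of the map"
                )
        diplo_list = []
        line_ids = []
        sources = {}
        for i in range(design.n_lines):
            for _ in range(10_000):
                src = _ril_diplotype(gmap, design.hif_source_generation, rng)
                if locus_idx is None or src[0, locus_idx] != src[1, locus_idx]:
                    break
            else:
                raise RuntimeError(
                    "could not sample a HIF source heterozygous at the "
                    "required position"
                )
            sources[f"F{i + 1}"] = src.copy()
            for j in range(design.hif_family_size):
                diplo_list.append(_self_once(src, gmap, rng))
                line_ids.append(f"F{i + 1}_S{j + 1}")
        diplos = np.stack(diplo_list)
        pedigree["sources"] = sources
        pedigree["family_size"] = design.hif_family_size

    else:
        raise ValueError(f"unknown population type {design.population_type!r}")

    codes = np.stack([diplotype_to_codes(d) for d in diplos])
    genotypes = GenotypeMatrix.from_codes(line_ids, gmap.markers, codes)
    return SimulatedPopulation(
        genotypes=genotypes, diplotypes=diplos, pedigree=pedigree, design=design
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    qtl_effects: Sequence[QTLEffect],
    env_effects: dict[str, float] | None = None,
    residual_sd: float = HIF_RESIDUAL_SD,
    reps_per_env: int = 2,
    rng: np.random.Generator | None = None,
    mu: float = MU_SNS,
    trait: str = "SNS",
    polygenic_sd: float = 0.0,
    polygenic_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Long-format phenotype table for simulated genotypes.

    value = mu + sum_q a_q * x_q + d_q * [het] + polygenic(line)
            + env effect + N(0, residual_sd^2)

    with additive dosage x in {-1 (A), 0 (H), +1 (B)}.  QTLs must sit at
    markers of the genotype matrix (off-map QTLs are rejected).  The
    polygenic term models background loci segregating among independent
    lines; pass ``polygenic_sd=0`` (default) for HIF sister lines, whose
    background is fixed, or supply precomputed ``polygenic_values``.
    """
    if residual_sd <= 0:
        raise ValueError("residual_sd must be > 0")
    rng = rng if rng is not None else np.random.default_rng()
    env_effects = env_effects if env_effects is not None else dict(DEFAULT_ENV_EFFECTS)

    marker_idx = {(m.chrom, m.pos_bp): i for i, m in enumerate(genotypes.markers)}
    codes = genotypes.codes().astype(float)
    genetic = np.zeros(genotypes.n_lines)
    for q in qtl_effects:
        try:
            j = marker_idx[(q.chrom, q.pos_bp)]
        except KeyError:
            raise ValueError(
                f"QTL at {q.chrom}:{q.pos_bp} is not at a marker of the "
                "genotype matrix (off-map QTLs are rejected)"
            )
        col = codes[:, j]
        observed = col >= 0
        dosage = np.where(observed, col - 1.0, 0.0)
        het = np.where(observed, (col == 1.0).astype(float), 0.0)
        genetic += q.additive * dosage + q.dominance * het

    if polygenic_values is not None:
        poly = polygenic_values.reindex(genotypes.line_ids).to_numpy(dtype=float)
    elif polygenic_sd > 0:
        poly = rng.normal(0.0, polygenic_sd, size=genotypes.n_lines)
    else:
        poly = np.zeros(genotypes.n_lines)

    records = []
    for env, env_off in env_effects.items():
        for rep in range(1, reps_per_env + 1):
            noise = rng.normal(0.0, residual_sd, size=genotypes.n_lines)
            vals = mu + genetic + poly + env_off + noise
            for line, v in zip(genotypes.line_ids, vals):
                records.append((line, env, rep, trait, v))
    return pd.DataFrame(
        records, columns=["line_id", "environment", "replicate", "trait", "value"]
    )


def simulate_progeny_test_phenotypes(
    gap: float = 2 * ADDITIVE_SNS,
    residual_sd: float = HIF_RESIDUAL_SD,
    n_per_class: int = 25,
    n_experiments: int = 2,
    rng: np.random.Generator | None = None,
    mu: float = MU_SNS,
    experiment_effects: Sequence[float] | None = None,
    heterozygous: bool = True,
) -> pd.DataFrame:
    """Phenotypes of homozygous sister-line classes in a progeny test.

    Under a ``heterozygous`` family the two classes differ by ``gap`` trait
    units; under a homozygous family both classes share the same mean.
    Returns a long table with columns sister_class ('A'/'B'), experiment,
    value.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if experiment_effects is None:
        experiment_effects = [0.0, 0.6][:n_experiments] + [0.0] * max(
            0, n_experiments - 2
        )
    class_means = {"A": mu, "B": mu + (gap if heterozygous else 0.0)}
    rows = []
    for e in range(n_experiments):
        for cls, m in class_means.items():
            vals = rng.normal(m + experiment_effects[e], residual_sd, n_per_class)
            rows.extend((cls, f"GH{e + 1}", v) for v in vals)
    return pd.DataFrame(rows, columns=["sister_class", "experiment", "value"])


# ---------------------------------------------------------------------------
# Marker assay noise
# ---------------------------------------------------------------------------

def simulate_marker_assay(
    true_genotypes: GenotypeMatrix,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """KASP-like assay noise: independent miscalls and dropouts.

    Each call is corrupted with probability ``error_rate`` to one of the
    two *wrong* visible codes (uniformly), then masked with probability
    ``missing_rate``.  The expected mismatch fraction among non-missing
    calls therefore equals ``error_rate`` exactly.
    """
    for name, rate in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    rng = rng if rng is not None else np.random.default_rng()
    codes = true_genotypes.codes().copy()
    observed = codes >= 0
    if error_rate > 0:
        flip = observed & (rng.random(codes.shape) < error_rate)
        # wrong code = (true + 1 or 2) mod 3, uniformly
        shift = rng.integers(1, 3, size=codes.shape).astype(np.int8)
        codes[flip] = (codes[flip] + shift[flip]) % 3
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = -1
    return GenotypeMatrix.from_codes(
        true_genotypes.line_ids, true_genotypes.markers, codes
    )


# ---------------------------------------------------------------------------
# Calibration of the cM <-> bp scale
# ---------------------------------------------------------------------------

def expected_f2_screen_fraction(r: float) -> float:
    """Probability an F2 plant shows discordant calls at two flanking
    markers with recombination fraction ``r`` between them.

    Exact enumeration of independent gamete pairs: both-parental pairs are
    concordant, single-recombinant pairs discordant, and of the
    double-recombinant pairs the two complementary gametes give H/H
    (concordant), whence P = 1 - (1-r)^2 - r^2/2.
    """
    if not 0.0 <= r < 0.5:
        raise ValueError("r must be in [0, 0.5)")
    return 1.0 - (1.0 - r) ** 2 - r**2 / 2.0


def calibrate_recombination_fraction(
    recombinants: int = wheat7al.BXR_PHASE1_SCREEN[0],
    screened: int = wheat7al.BXR_PHASE1_SCREEN[1],
) -> float:
    """Recombination fraction whose expected F2 screen fraction matches an
    observed recombinant count (default: the 74/617 phase-1 screen)."""
    target = recombinants / screened
    return brentq(lambda r: expected_f2_screen_fraction(r) - target, 1e-9, 0.499)


def default_cm_per_mb(window: "tuple[int, int] | None" = None) -> float:
    """cM-per-Mb scalar calibrated so the 9.13-Mb IWB713--IWB53096 window
    gives the observed 12.0% F2 recombinant fraction under Haldane cM."""
    if window is None:
        iv = wheat7al.BXR_INITIAL_WINDOW
        width_mb = iv.width_bp("between_markers") / 1e6
    else:
        width_mb = (window[1] - window[0]) / 1e6
    r = calibrate_recombination_fraction()
    return haldane_to_cM(r) / width_mb


# ---------------------------------------------------------------------------
# Ready-made maps for demos and tests
# ---------------------------------------------------------------------------

#: Default position of the simulated SNS locus, inside the 87-kb candidate
#: interval (between markers AX-111159341 and AX-109360122).
DEFAULT_LOCUS_BP = 674_062_000
LOCUS_MARKER_NAME = "SNS_locus"


def region_map_7al(
    include_locus: bool = True,
    locus_pos_bp: int = DEFAULT_LOCUS_BP,
    cm_per_mb: float | None = None,
    max_gap_mb: float | None = None,
) -> GeneticMap:
    """Genetic map of the 7AL fine-mapping region (named markers, Haldane
    cM from the calibrated cM/Mb scalar).

    With ``include_locus`` a pseudo-marker for the causal locus is placed at
    ``locus_pos_bp``; simulations type it like any marker, and the
    fine-mapping logic is handed the matrix *without* it.  ``max_gap_mb``
    inserts additional evenly spaced markers (``fill_*``) so that no
    between-marker gap exceeds the given size — the in-silico counterpart
    of developing extra KASP markers across the target region, which keeps
    undetected double crossovers within a gap negligible.
    """
    cmmb = cm_per_mb if cm_per_mb is not None else default_cm_per_mb()
    markers = [
        Marker(name, "7A", pos) for name, pos in wheat7al.MARKERS_7AL.items()
    ]
    if max_gap_mb is not None:
        gap_bp = int(max_gap_mb * 1e6)
        pos_sorted = sorted(m.pos_bp for m in markers)
        for lo, hi in zip(pos_sorted, pos_sorted[1:]):
            n_fill = (hi - lo - 1) // gap_bp
            for k in range(1, n_fill + 1):
                p = lo + k * (hi - lo) // (n_fill + 1)
                markers.append(Marker(f"fill_{p}", "7A", p))
    if include_locus and all(m.pos_bp != locus_pos_bp for m in markers):
        markers.append(Marker(LOCUS_MARKER_NAME, "7A", locus_pos_bp))
    return GeneticMap(markers=markers, map_function="haldane", cm_per_mb=cmmb)


def demo_genetic_map(cm_per_mb: float | None = None) -> GeneticMap:
    """Three-chromosome demo map: background SNS QTL regions on 2BS and 7AS
    plus the 7AL fine-mapping region with its named markers."""
    cmmb = cm_per_mb if cm_per_mb is not None else default_cm_per_mb()
    markers: list[Marker] = []
    for i in range(11):  # 2B: 0..100 cM
        markers.append(
            Marker(f"2B_{i * 10:03d}", "2B", 5_000_000 + i * 30_000_000,
                   pos_cM=float(i * 10))
        )
    for i in range(8):  # 7A short arm: 0..70 cM
        markers.append(
            Marker(f"7AS_{i * 10:03d}", "7A", 5_000_000 + i * 35_000_000,
                   pos_cM=float(i * 10))
        )
    base_cm = 150.0
    base_bp = wheat7al.MARKERS_7AL["IWB713"]
    for name, pos in wheat7al.MARKERS_7AL.items():
        markers.append(
            Marker(name, "7A", pos,
                   pos_cM=base_cm + (pos - base_bp) / 1e6 * cmmb)
        )
    return GeneticMap(markers=markers, map_function="haldane", cm_per_mb=cmmb)


#: Default QTL set for the demo map: the 7AL SNS locus plus the two
#: background QTLs on 2BS and 7AS (additive across loci, no epistasis).
def demo_qtl_effects() -> list[QTLEffect]:
    return [
        QTLEffect("2B", 5_000_000 + 3 * 30_000_000, additive=0.5),
        QTLEffect("7A", 5_000_000 + 2 * 35_000_000, additive=0.6),
        QTLEffect("7A", wheat7al.MARKERS_7AL["IWA5913"], additive=ADDITIVE_SNS),
    ]


# ---------------------------------------------------------------------------
# Synthetic accession panels (haplotype / allele structure)
# ---------------------------------------------------------------------------

def synthetic_snp_panel(
    group_counts: dict[str, int] | None = None,
    n_sites: int = 20,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    start_bp: int = 672_000_000,
    end_bp: int = 674_300_000,
):
    """A SNP matrix over the 2.3-Mb haplotype-block window with one
    distinct site pattern per haplotype group.

    Defaults reproduce the exome-capture hexaploid panel structure (13 H1,
    33 H2, 3 H3 accessions).  Returns (SNPMatrix, truth labels dict).
    """
    from .haplotypes import SNPMatrix

    rng = rng if rng is not None else np.random.default_rng()
    counts = dict(group_counts or wheat7al.EXOME_HEXAPLOID_HAPLOTYPES)
    k = len(counts)
    # distinct, pairwise well-separated haplotype patterns
    patterns = {}
    names = sorted(counts)
    for gi, name in enumerate(names):
        pat = np.zeros(n_sites, dtype=np.int8)
        pat[gi::k] = 1
        patterns[name] = pat
    positions = np.sort(
        rng.choice(np.arange(start_bp, end_bp), size=n_sites, replace=False)
    )
    ids, rows, truth = [], [], {}
    i = 0
    for name in names:
        for _ in range(counts[name]):
            i += 1
            acc = f"acc{i:03d}"
            row = patterns[name].copy()
            if missing_rate > 0:
                row = row.copy()
                row[rng.random(n_sites) < missing_rate] = -1
            ids.append(acc)
            rows.append(row)
            truth[acc] = name
    return (
        SNPMatrix(accession_ids=ids, positions=positions,
                  genotypes=np.array(rows, dtype=np.int8)),
        truth,
    )


def diagnostics_for_haplotype(haplotype: str):
    """The diagnostic-marker genotype carried by each haplotype group:
    H1 accessions carry WAPO-A1a, H2 carry WAPO-A1b, H3 the ancestral
    P+/C47/D384 combination (allele c in this panel)."""
    from .haplotypes import DiagnosticGenotype

    allele = {"H1": "WAPO-A1a", "H2": "WAPO-A1b", "H3": "WAPO-A1c"}[haplotype]
    spec = wheat7al.ALLELE_DEFINITIONS[allele]
    return DiagnosticGenotype(
        promoter_indel=spec["promoter"],
        codon47=spec["codon47"],
        codon384=spec["codon384"],
        linked_snps=dict(spec["linked_snps"]),
    )
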