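"""Haplotype blocks, H-group assignment and WAPO-A1 allele classification.

Haplotype blocks over a SNP window are delimited with the four-gamete
test: a historical recombination event is inferred between adjacent sites
exhibiting all four gametes (00, 01, 10, 11) among non-missing accessions,
and blocks are the maximal boundary-free runs.  Accessions are grouped
into haplotypes by missing-tolerant exact match over a block and labeled
H1..Hk in descending group size (the numbering is frequency-based, not
ancestral; an anchor mapping, e.g. RAC875 -> H1, can rename groups).

*WAPO-A1* alleles are called from the diagnostic polymorphisms of the
candidate gene: the 115-bp promoter indel (P+/P-), the C47F change in the
conserved F-box (dCAPS assay) and the D384N change, plus linked SNPs that
separate the two P+/C47/D384 alleles c and d from the ancestral consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: Linked-SNP keys recognized by the allele classifier, with the derived
#: (diagnostic) state of each.  c397/c787/c974 mark WAPO-A1c; g764/cneg66
#: mark WAPO-A1d; the rest are unique to WAPO-A1b.
LINKED_SNP_STATES: dict[str, tuple[str, str]] = {
    # key: (ancestral, derived)
    "c397": ("C", "T"),
    "c787": ("C", "T"),
    "c974": ("C", "G"),
    "g764": ("G", "A"),
    "cneg66": ("C", "T"),
    "g460": ("G", "A"),
    "a244": ("A", "G"),
    "g134": ("G", "T"),
    "t842": ("T", "C"),
}
_C_DIAGNOSTIC = {"c397": "T", "c787": "T", "c974": "G"}
_D_DIAGNOSTIC = {"g764": "A", "cneg66": "T"}

AlleleLabel = Literal[
    "WAPO-A1a", "WAPO-A1b", "WAPO-A1c", "WAPO-A1d",
    "ancestral_unresolved", "inconsistent",
]


# ---------------------------------------------------------------------------
# SNP matrix
# ---------------------------------------------------------------------------

@dataclass
class SNPMatrix:
    """Accessions x ordered biallelic sites; alleles 0/1, missing -1."""

    accession_ids: list[str]
    positions: np.ndarray       # bp, strictly increasing
    genotypes: np.ndarray       # (n_accessions, n_sites) int8 in {-1, 0, 1}
    chrom: str = "7A"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if self.genotypes.shape != (len(self.accession_ids), len(self.positions)):
            raise ValueError("genotype matrix shape mismatch")
        bad = ~np.isin(self.genotypes, (-1, 0, 1))
        if bad.any():
            raise ValueError("alleles must be coded 0/1 with -1 for missing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def site_missingness(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=0)

    def window(self, start_bp: int, end_bp: int) -> "SNPMatrix":
        keep = (self.positions >= start_bp) & (self.positions <= end_bp)
        return SNPMatrix(
            self.accession_ids,
            self.positions[keep],
            self.genotypes[:, keep],
            chrom=self.chrom,
        )


# ---------------------------------------------------------------------------
# Four-gamete blocks
# ---------------------------------------------------------------------------

def _four_gametes(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two sites show all four gametes among non-missing pairs."""
    both = (a >= 0) & (b >= 0)
    if not both.any():
        return False
    pairs = {(int(x), int(y)) for x, y in zip(a[both], b[both])}
    return len(pairs) == 4


def four_gamete_block_boundaries(snps: SNPMatrix) -> list[tuple[int, int]]:
    """Haplotype blocks as (start_bp, end_bp) site spans.

    A boundary is placed between adjacent sites exhibiting all four
    gametes; blocks are maximal runs without a boundary.  Sites missing in
    every accession are skipped with a warning.
    """
    if snps.n_sites < 2:
        raise ValueError("need at least two sites")
    usable = [j for j in range(snps.n_sites)
              if (snps.genotypes[:, j] >= 0).any()]
    if len(usable) < snps.n_sites:
        import warnings

        warnings.warn(
            f"skipped {snps.n_sites - len(usable)} all-missing site(s)"
        )
    blocks = []
    start = usable[0]
    prev = usable[0]
    for j in usable[1:]:
        if _four_gametes(snps.genotypes[:, prev], snps.genotypes[:, j]):
            blocks.append((int(snps.positions[start]), int(snps.positions[prev])))
            start = j
        prev = j
    blocks.append((int(snps.positions[start]), int(snps.positions[prev])))
    return blocks


# ---------------------------------------------------------------------------
# Haplotype assignment
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAssignment:
    """Accession -> H-group over one block."""

    labels: dict[str, str]              # accession -> "H1".."Hk"/"unassigned"
    group_counts: dict[str, int]
    consensus: dict[str, str]           # group -> consensus string ('.'=unknown)
    block: tuple[int, int]

    def relabel(self, anchors: Mapping[str, str]) -> "HaplotypeAssignment":
        """Rename groups so each anchor accession carries its given name.

        ``anchors`` maps accession id -> desired group name (e.g.
        ``{"RAC875": "H1", "Chinese Spring": "H2"}``).  Non-anchored groups
        keep their frequency-rank names where unclaimed.
        """
        rename: dict[str, str] = {}
        for acc, want in anchors.items():
            cur = self.labels.get(acc)
            if cur is None or cur == "unassigned":
                raise ValueError(f"anchor accession {acc!r} is not assigned")
            rename[cur] = want
        labels = {a: rename.get(g, g) for a, g in self.labels.items()}
        counts = {rename.get(g, g): c for g, c in self.group_counts.items()}
        cons = {rename.get(g, g): s for g, s in self.consensus.items()}
        return HaplotypeAssignment(labels, counts, cons, self.block)


def assign_haplotypes(
    snps: SNPMatrix,
    block: tuple[int, int] | None = None,
    max_missing_per_accession: float = 0.5,
) -> HaplotypeAssignment:
    """Group accessions by missing-tolerant exact match over a block.

    Two accessions belong together when their genotypes agree at every
    site where both are observed (connected components of the pairwise
    compatibility graph).  Groups are labeled H1..Hk in descending size,
    ties broken by the lexicographically smaller consensus string.
    Accessions whose missing fraction over the block exceeds
    ``max_missing_per_accession`` are left unassigned.
    """
    sub = snps if block is None else snps.window(*block)
    if sub.n_sites == 0:
        raise ValueError("empty block")
    geno = sub.genotypes
    n = len(sub.accession_ids)
    miss = (geno < 0).mean(axis=1)
    usable = [i for i in range(n) if miss[i] <= max_missing_per_accession]

    parent = {i: i for i in usable}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai in range(len(usable)):
        for bi in range(ai + 1, len(usable)):
            a, b = usable[ai], usable[bi]
            both = (geno[a] >= 0) & (geno[b] >= 0)
            if np.all(geno[a][both] == geno[b][both]):
                parent[find(a)] = find(b)

    comps: dict[int, list[int]] = {}
    for i in usable:
        comps.setdefault(find(i), []).append(i)

    def consensus_str(members: list[int]) -> str:
        out = []
        for j in range(sub.n_sites):
            vals = [int(geno[i, j]) for i in members if geno[i, j] >= 0]
            if not vals:
                out.append(".")
            else:
                # majority, ties toward the 0 allele
                out.append("1" if sum(vals) * 2 > len(vals) else "0")
        return "".join(out)

    groups = sorted(
        comps.values(),
        key=lambda g: (-len(g), consensus_str(g)),
    )
    labels: dict[str, str] = {a: "unassigned" for a in sub.accession_ids}
    counts: dict[str, int] = {}
    consensus: dict[str, str] = {}
    for k, members in enumerate(groups, start=1):
        name = f"H{k}"
        counts[name] = len(members)
        consensus[name] = consensus_str(members)
        for i in members:
            labels[sub.accession_ids[i]] = name
    blk = block if block is not None else (
        int(sub.positions[0]), int(sub.positions[-1])
    )
    return HaplotypeAssignment(
        labels=labels, group_counts=counts, consensus=consensus, block=blk
    )


# ---------------------------------------------------------------------------
# WAPO-A1 allele classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticGenotype:
    """Diagnostic marker calls for one accession."""

    promoter_indel: Literal["P_plus", "P_minus", "missing"] = "missing"
    codon47: Literal["C", "F", "missing"] = "missing"
    codon384: Literal["D", "N", "missing"] = "missing"
    linked_snps: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.promoter_indel not in ("P_plus", "P_minus", "missing"):
            raise ValueError(f"bad promoter state {self.promoter_indel!r}")
        if self.codon47 not in ("C", "F", "missing"):
            raise ValueError(f"bad codon-47 state {self.codon47!r}")
        if self.codon384 not in ("D", "N", "missing"):
            raise ValueError(f"bad codon-384 state {self.codon384!r}")
        for key, val in self.linked_snps.items():
            if key not in LINKED_SNP_STATES:
                raise ValueError(f"unknown linked SNP {key!r}")
            anc, der = LINKED_SNP_STATES[key]
            if val not in (anc, der):
                raise ValueError(
                    f"linked SNP {key} must be {anc} or {der}, got {val!r}"
                )


@dataclass
class AlleleCall:
    label: AlleleLabel
    evidence: list[str]


def classify_wapo_allele(g: DiagnosticGenotype) -> AlleleCall:
    """Call the WAPO-A1 allele from diagnostic polymorphisms.

    Rules (missing fields are permissive, contradictions yield
    ``inconsistent`` rather than an exception):

    * P- with C47 (and N384 when typed) -> *WAPO-A1a*;
    * P+ with F47 (and D384 when typed) -> *WAPO-A1b*;
    * P+/C47/D384 with a c-diagnostic linked SNP (C397T, C787T or C974G)
      -> *WAPO-A1c*; with a d-diagnostic SNP (G764A or C-66T) ->
      *WAPO-A1d*; with both -> ``inconsistent``;
    * P+/C47 without informative linked SNPs -> ``ancestral_unresolved``
      (the P+/C47/D384 consensus shared by c, d and the ancestral state).
    """
    evidence: list[str] = []
    c_hits = [k for k, v in _C_DIAGNOSTIC.items()
              if g.linked_snps.get(k) == v]
    d_hits = [k for k, v in _D_DIAGNOSTIC.items()
              if g.linked_snps.get(k) == v]

    def call(label: AlleleLabel) -> AlleleCall:
        return AlleleCall(label=label, evidence=evidence)

    if g.promoter_indel == "P_minus":
        evidence.append("115-bp promoter deletion (P-)")
        if g.codon47 == "F" or g.codon384 == "D" or c_hits or d_hits:
            return call("inconsistent")
        if g.codon47 == "C":
            evidence.append("C47")
        if g.codon384 == "N":
            evidence.append("N384")
        return call("WAPO-A1a")

    if g.codon47 == "F":
        evidence.append("F47 (dCAPS)")
        if g.codon384 == "N" or c_hits or d_hits:
            return call("inconsistent")
        if g.promoter_indel == "P_plus":
            evidence.append("P+")
        return call("WAPO-A1b")

    # promoter is P_plus or missing; codon47 is C or missing
    if g.codon384 == "N":
        # N384 without the promoter deletion contradicts every definition
        return call("inconsistent")
    if c_hits and d_hits:
        evidence.extend(c_hits + d_hits)
        return call("inconsistent")
    if g.promoter_indel == "missing" and g.codon47 == "missing" and not (
        c_hits or d_hits
    ):
        return call("ancestral_unresolved")
    if c_hits:
        evidence.extend(f"{k} derived" for k in c_hits)
        return call("WAPO-A1c")
    if d_hits:
        evidence.extend(f"{k} derived" for k in d_hits)
        return call("WAPO-A1d")
    evidence.append("P+/C47 consensus, no informative linked SNPs")
    return call("ancestral_unresolved")


# ---------------------------------------------------------------------------
# Candidate-polymorphism filter
# ---------------------------------------------------------------------------

FUNCTIONAL_CLASSES = {"non_synonymous", "promoter_indel"}
POLYMORPHIC_CLASSES = FUNCTIONAL_CLASSES | {"synonymous", "intron"}


@dataclass
class CandidateFilterResult:
    candidates: list[str]
    supporting: pd.DataFrame
    exclusions: dict[str, str]   # gene -> reason


def candidate_polymorphism_filter(
    table: pd.DataFrame,
    contrast_cols: tuple[str, str] = ("contrast_h2_h1", "contrast_h2_h3"),
    region: "object | None" = None,
) -> CandidateFilterResult:
    """Genes with a functional change separating the high-SNS haplotype
    from both alternatives.

    A gene passes iff at least one of its records is a functional change
    (non-synonymous or promoter indel) *in both contrasts at the same
    position*; genes with only synonymous changes or changes confined to a
    single contrast are excluded, with per-gene reasons.  When a
    ``region`` (:class:`~hifmap.genetics.GenomicInterval`) is given, only
    variants inside it count — polymorphisms excluded from a candidate
    interval by recombination cannot explain the trait.
    """
    c1, c2 = contrast_cols
    if region is not None and not table.empty:
        inside = table["pos_bp"].apply(
            lambda p: region.start_bp <= p <= region.end_bp
        )
        outside_genes = set(table.loc[~inside, "gene_id"]) - set(
            table.loc[inside, "gene_id"]
        )
        table = table[inside]
        if table.empty:
            return CandidateFilterResult(
                [], table,
                {g: "all variants outside the candidate region"
                 for g in outside_genes},
            )
    if table.empty:
        return CandidateFilterResult([], table, {})
    hits = table[
        table[c1].isin(FUNCTIONAL_CLASSES) & table[c2].isin(FUNCTIONAL_CLASSES)
    ]
    candidates = sorted(hits["gene_id"].unique())
    exclusions = {}
    for gene, sub in table.groupby("gene_id"):
        if gene in candidates:
            continue
        both = sub[
            sub[c1].isin(POLYMORPHIC_CLASSES) & sub[c2].isin(POLYMORPHIC_CLASSES)
        ]
        if len(both):
            exclusions[gene] = (
                "polymorphic in both contrasts but never with a functional "
                "change in both"
            )
        elif (sub[c1].isin(FUNCTIONAL_CLASSES) | sub[c2].isin(FUNCTIONAL_CLASSES)).any():
            exclusions[gene] = "functional change in a single contrast only"
        else:
            exclusions[gene] = "no functional change in either contrast"
    return CandidateFilterResult(
        candidates=candidates, supporting=hits.copy(), exclusions=exclusions
    )


# ---------------------------------------------------------------------------
# Marker amplicon arithmetic
# ---------------------------------------------------------------------------

def predict_amplicon_size(
    base_size_without_indel: int, indel_len: int, allele_has_indel: bool
) -> int:
    """PCR fragment size for an indel assay.

    ``base_size_without_indel`` is the fragment amplified from a deletion
    carrier; non-carriers add the indel length back (e.g. 210 bp for P-
    accessions vs 210 + 115 = 325 bp for P+).
    """
    if base_size_without_indel <= 0 or indel_len < 0:
        raise ValueError("sizes must be positive")
    return base_size_without_indel + (0 if allele_has_indel else indel_len)
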