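"""Published coordinates and diagnostic definitions for the wheat 7AL SNS locus.

Curated reference data (RefSeq v1.0 physical coordinates) for the
spikelet-number-per-spike locus on chromosome arm 7AL and its candidate
gene *WAPO-A1* (*TraesCS7A02G481600*, the wheat ortholog of rice *APO1*):
marker positions used in the two high-resolution maps (Berkut x RAC875 and
Ning7840 x Clark), the candidate intervals they delimited, the diagnostic
polymorphisms that define the *WAPO-A1* a-d alleles, the published
per-panel allele/haplotype counts, and the screening sizes of the
recombinant screens.  These are the worked inputs for the arithmetic
stages of the pipeline; everything population-level is simulated by
:mod:`hifmap.simulate`.
"""

from __future__ import annotations

import pandas as pd

from .genetics import GenomicInterval, Marker

CHROM = "7A"

#: Marker physical positions on 7AL (RefSeq v1.0, bp).
MARKERS_7AL: dict[str, int] = {
    "IWB713": 670_767_495,
    "IWB7435": 671_218_901,
    "IWA4911": 671_417_177,
    "IWB6693": 672_032_033,
    "Traes1400-I4V": 673_779_017,
    "AX-109397893": 673_854_124,
    "AX-111159341": 674_019_191,
    "AX-109360122": 674_106_327,
    "IWB7632": 674_272_225,
    "IWA5912": 674_276_849,
    "IWA5913": 674_276_906,
    "IWA7409": 674_279_667,
    "IWB5961": 674_801_909,
    "IWB53096": 679_896_953,
    "IWA5167": 679_955_879,
}


def marker(name: str) -> Marker:
    return Marker(name=name, chrom=CHROM, pos_bp=MARKERS_7AL[name])


def marker_interval(left: str, right: str) -> GenomicInterval:
    return GenomicInterval(
        CHROM, MARKERS_7AL[left], MARKERS_7AL[right], kind="marker_bounded"
    )


#: Candidate intervals from the two high-resolution maps.
CANDIDATE_87KB = marker_interval("AX-111159341", "AX-109360122")
BXR_PHASE1_498KB = marker_interval("Traes1400-I4V", "IWA5913")
NXC_ROUND1_423KB = marker_interval("AX-109397893", "IWA5913")
NXC_INITIAL_WINDOW = marker_interval("IWB7435", "IWA5167")   # the 8.7-Mb screen
BXR_INITIAL_WINDOW = marker_interval("IWB713", "IWB53096")   # the 9.1-Mb screen
#: The ~2.3-Mb haplotype block, approximately 672.0-674.3 Mb.
HAPLOTYPE_BLOCK = GenomicInterval(CHROM, 672_000_000, 674_300_000)

#: Promoter deletion of the WAPO-A1a allele, positions relative to the
#: start codon (1-based inclusive feature coordinates; upstream negative).
PROMOTER_DELETION_SPAN = (-599, -485)
#: PCR assay for the promoter indel: fragment size with the deletion (P-)
#: and the deletion length added back for P+ accessions.
PROMOTER_AMPLICON_PMINUS_BP = 210
#: dCAPS fragment sizes distinguishing F47 from C47 after HpyCH4V digestion.
DCAPS_F47_BP = 200
DCAPS_C47_BP = 180

#: Recombinant-screen sizes: (recombinants found, plants screened).
BXR_PHASE1_SCREEN = (74, 617)
BXR_PHASE2_SCREENED = 1208          # zero new recombinants found
NXC_SCREEN_ROUNDS = (4219, 2277)    # progeny screened in the first two cycles
NXC_RECOMBINANTS = 93
NXC_RECOMBINANT_CLASSES = 31
NXC_EXTRA_SCREENED = 3948           # final-round screen, zero new recombinants

#: Spring-wheat panel haplotype counts within the 2.3-Mb block.
SPRING_PANEL_HAPLOTYPES = {"H1": 40, "H2": 198}
#: Exome-capture hexaploid accessions per haplotype group.
EXOME_HEXAPLOID_HAPLOTYPES = {"H1": 13, "H2": 33, "H3": 3}
EXOME_TETRAPLOID_H1 = 4

#: Grain-yield effect rows (kg/ha): (H2 - H1 difference, H1 baseline LS mean).
GRAIN_YIELD_BXR = (289.5, 4141.0)
GRAIN_YIELD_GWAS = (90.8, 4350.0)
#: SNS homozygote gap (H2 - H1) in the Berkut x RAC875 RILs.
SNS_GAP_BXR = 2.10

CANDIDATE_GENE = "TraesCS7A02G481600"


def gene_polymorphism_table() -> pd.DataFrame:
    """Coding/promoter polymorphisms of the high-confidence genes around the
    87-kb candidate region, scored in the two informative crosses.

    Each record carries the variant position and its predicted effect in
    the H2-vs-H1 contrast (Berkut vs RAC875) and the H2-vs-H3 contrast
    (MPV57 vs LA95135): ``non_synonymous``, ``synonymous``,
    ``promoter_indel``, ``intron`` or ``not_polymorphic``.
    """
    rows = [
        ("TraesCS7A02G481400", 673_779_017, "non_synonymous", "non_synonymous",
         "I4V; CYTOCHROME C OXIDASE SUBUNIT 6A"),
        ("TraesCS7A02G481500", 674_018_426, "not_polymorphic", "non_synonymous",
         "R207G; AMIDOHYDROLASE"),
        ("TraesCS7A02G481500", 674_019_603, "synonymous", "not_polymorphic", ""),
        ("TraesCS7A02G481500", 674_019_951, "synonymous", "synonymous", ""),
        ("TraesCS7A02G481500", 674_020_022, "non_synonymous", "not_polymorphic",
         "V456A"),
        ("TraesCS7A02G481600", 674_080_862, "promoter_indel", "not_polymorphic",
         "P+/P- 115-bp promoter deletion; ABERRANT PANICLE ORGANIZATION 1"),
        ("TraesCS7A02G481600", 674_081_601, "non_synonymous", "non_synonymous",
         "C47F; within conserved F-box (aa 36-74)"),
        ("TraesCS7A02G481600", 674_082_745, "non_synonymous", "not_polymorphic",
         "D384N"),
        ("TraesCS7A02G481700", 674_091_310, "synonymous", "not_polymorphic",
         "MAJOR POLLEN ALLERGEN OLE E 10-LIKE"),
        ("TraesCS7A02G481700", 674_091_312, "not_polymorphic", "non_synonymous",
         "L177H"),
        ("TraesCS7A02G481800", 674_106_471, "synonymous", "not_polymorphic",
         "SYNTAXIN"),
        ("TraesCS7A02G481900", 674_115_185, "not_polymorphic", "non_synonymous",
         "E46A; CASP-LIKE PROTEIN 5B3"),
        ("TraesCS7A02G482000", 674_272_225, "non_synonymous", "not_polymorphic",
         "E252*; HYDROLASE"),
        ("TraesCS7A02G482100", 674_274_282, "synonymous", "not_polymorphic",
         "DETOXIFICATION 34-LIKE"),
        ("TraesCS7A02G482100", 674_274_822, "not_polymorphic", "synonymous", ""),
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "pos_bp", "contrast_h2_h1", "contrast_h2_h3",
                 "annotation"],
    )


#: Diagnostic genotypes of the four WAPO-A1 alleles and the ancestral
#: consensus, as (promoter, codon47, codon384, linked SNPs).
ALLELE_DEFINITIONS: dict[str, dict] = {
    "WAPO-A1a": {"promoter": "P_minus", "codon47": "C", "codon384": "N",
                 "linked_snps": {}},
    "WAPO-A1b": {"promoter": "P_plus", "codon47": "F", "codon384": "D",
                 "linked_snps": {"g460": "A", "a244": "G", "g134": "T",
                                 "t842": "C"}},
    "WAPO-A1c": {"promoter": "P_plus", "codon47": "C", "codon384": "D",
                 "linked_snps": {"c397": "T", "c787": "T", "c974": "G"}},
    "WAPO-A1d": {"promoter": "P_plus", "codon47": "C", "codon384": "D",
                 "linked_snps": {"g764": "A", "cneg66": "T"}},
    "consensus": {"promoter": "P_plus", "codon47": "C", "codon384": "D",
                  "linked_snps": {}},
}
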