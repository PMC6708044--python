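# Methods

This note documents the models, conventions and numerical choices behind
`hifmap`, and what its synthetic-data validations do and do not show.

## Coordinates and interval arithmetic

Physical positions are 1-based inclusive (RefSeq v1.0 convention). Two
width conventions coexist and are kept explicit: marker-bounded candidate
intervals report `end − start` (this reproduces every published interval
size, e.g. 674,019,191–674,106,327 → 87,136 bp → "87 kb"), while sequence
features report `end − start + 1` (the −599..−485 promoter deletion →
115 bp). Printed sizes round half-up: integer kb below 1 Mb, one decimal
Mb above. Genetic distances use the Kosambi map function by default (with
Haldane available); selfed-RIL analyses use the expanded recombination
fraction R = 2r/(1+2r).

## The synthetic-data generator

The generator is the package's study population; its defaults are fixed
once and define what the tests mean.

**Meiosis.** Crossover counts per chromosome are Poisson in the map length
(Morgans) with positions uniform on the cM scale — a no-interference
model, so the simulator's cM are Haldane cM. Populations: F2 (two
independent F1 gametes), selfed RILs by single-seed descent (expected
residual heterozygosity (1/2)^(g−1) at generation g), and HIFs (sister
lines selfed from one RIL source plant, optionally conditioned to be
heterozygous at the target). Sister lines are genotypically identical
outside the source's residual heterozygous segments — an exact property,
asserted exactly in tests.

**cM↔bp calibration.** A single cM-per-Mb scalar (default ≈ 0.737) is
chosen so that an F2 screen of the 9.13-Mb IWB713–IWB53096 window has
expected discordant-flank fraction 74/617 ≈ 12.0%. The screen expectation
is the exact enumeration P(discordant) = 1 − (1−r)² − r²/2; the r²/2 term
covers complementary double-recombinant gamete pairs, which are H at both
flanks and hence invisible to the screen. The observed count is a
calibration anchor, not a validation claim.

**Phenotypes.** value = μ + Σ_q a_q·x_q + d_q·[het] + polygenic(line) +
environment + N(0, σ²), with dosage x ∈ {−1, 0, +1}; no epistasis.
Defaults: μ = 18 SNS, a = 1.05 at the 7AL locus (homozygote gap 2.1
spikelets), background QTLs on 2BS (a = 0.5) and 7AS (a = 0.6), four
environments with offsets −1, −0.3, 0.3, 1. HIF-level residual SD is 1.2
SNS per plant (greenhouse scale); RIL-level analyses add a per-line
polygenic term with SD 1.2·√15, making the RIL pooled SD four times the
HIF pooled SD — the variance contrast that motivates HIFs, encoded as a
tunable default rather than a measured value. Genotyping-assay noise
corrupts a call to one of the two *wrong* visible codes with the given
error rate (so the expected mismatch among observed calls equals the rate
exactly) and masks calls independently at the missing rate.

**What the generator does not emulate:** crossover interference,
segregation distortion, genotype×environment interaction, epistasis, and
pedigree errors. Passing tests therefore certify the inference machinery
under a clean Mendelian model, not robustness to those features of real
data.

## Interval mapping

Conditional genotype probabilities come from the nearest informative
flanking markers through the population's transition matrices (Markov
under no interference; verified against exhaustive two-locus gamete
enumeration to < 1e-10). RILs use the two-state {A, B} support with
expanded R; residual heterozygous calls are uninformative there. The scan
grid is every marker plus pseudo-positions each 1 cM. Haley–Knott
regression fits phenotype on expected additive dosage (plus a dominance
term for F2); at any position with constant dosage the LOD is exactly 0;
the LOD/PVE identity holds by construction and is asserted everywhere.
Peaks are per contiguous supra-threshold run (LOD ≥ 2.0, the fixed
threshold; ties toward the smaller bp coordinate) with 1.5-LOD support
intervals — a common default, as the drop amount is a free choice. The
multi-QTL fit is a joint additive regression at the peak dosages with
drop-one PVE; each drop-one PVE is bounded by the total model PVE (the
algebraic nesting bound), with equality of drop-one and marginal PVE under
an orthogonal design. The genome-wide type-I rate of the fixed LOD 2.0
cutoff is estimated by null simulation and *reported*, not asserted
against any external value.

Field-trial adjustment uses fixed-effects least-squares means with
environments as blocks (type-II F for the group factor, equal to type III
in the additive model; LS means average the block predictions with equal
weight). A mixed-model/BLUP adjustment was deliberately not used: the
fixed-block LS means are deterministic, dependency-light, and match how
the package's effect tables are defined. Disconnected level×block designs
are rejected rather than silently extrapolated.

## Fine-mapping and Mendelization

A line is a recombinant iff its calls at the two flanking markers are
non-missing and different (any of A/H, H/B, A/B). Breakpoint classes are
connected components of the missing-tolerant compatibility graph (two
vectors compatible iff equal wherever both observed); lines over 50%
missing in the region are flagged unclassifiable. Progeny tests classify a
family heterozygous iff the combined blocked ANOVA of its two homozygous
sister-line classes is significant at α = 0.05 (two-sided; the
significance level is a fixed convention).

Segment conventions: the *maximal* heterozygous segment extends to, but
excludes, the nearest flanking non-H non-missing markers; the *minimal*
segment spans the outermost H calls inclusive. Because a founder can carry
more than one residual heterozygous segment, the family also records its
maximal contiguous H *runs*; a homozygous classification excludes each
run, not the span between runs (excluding the span would wrongly veto the
region between two separate segments).

Deduction: a between-marker gap is viable iff it lies inside every
heterozygous family's open maximal segment and intersects no homozygous
family's H run. The candidate interval is the widest contiguous run of
viable gaps, marker-bounded. When exclusions split the viable region into
disjoint pieces the evidence is genuinely ambiguous — the locus could be
in any piece — so the remaining pieces are returned as
`alternative_intervals` rather than silently dropped; in practice another
marker or family resolves the split. Inconsistent constraint sets trigger
greedy conflict removal (the family whose removal reopens the most gaps
goes first), always reported, with a full constraint dump if nothing
viable remains.

The Mendelization validation simulates 500 F2-style screens of the 9.1-Mb
window (80 plants each, the locus placed uniformly at random), classifies
each recombinant family from the simulated truth, and checks that the true
locus lies in the deduced viable region in 100% of runs and that the
candidate equals a brute-force check of every gap against every
constraint. The simulation map densifies the region to ≤ 0.03-Mb gaps —
the in-silico analog of saturating the region with KASP markers — so that
a double heterozygosity switch inside one gap (which would make a family's
constraint unsound at any marker density) has negligible probability.
Problem sizes throughout (500 logic simulations, 500 progeny-test power
simulations at 25 plants/class × 2 experiments, 200 null scans of 100
lines) are the package's chosen trade-off between Monte-Carlo resolution
and a single-CPU run of the suite.

## Haplotypes and alleles

Haplotype blocks are delimited by the four-gamete test between adjacent
sites (the block-detection method is this package's choice; published
block figures are typically drawn from LD heatmaps by eye). Group
assignment is missing-tolerant exact matching (connected components, as
for breakpoint classes) with H1..Hk labels in descending group size,
lexicographic consensus tie-break; the numbering is frequency-based, not
ancestral, and an anchor mapping (e.g. RAC875 → H1) can rename groups.

The *WAPO-A1* classifier encodes the diagnostic definitions: a = P−/C47
(N384 confirmatory), b = P+/F47, c and d = the P+/C47/D384 consensus
resolved by linked SNPs (c: C397T, C787T, C974G; d: G764A, C−66T); the
consensus without informative linked SNPs is `ancestral_unresolved`.
Contradictory evidence (P− with F47, N384 without the deletion, c- and
d-diagnostics together) yields `inconsistent` as a value, never an
exception; missing fields are permissive, matching the two-marker PCR
assay that types only the promoter and codon 47. The candidate-gene filter
keeps genes with a functional change (non-synonymous or promoter indel) in
*both* haplotype contrasts at the same position, restricted to variants
inside the candidate interval — changes excluded by recombination cannot
explain the trait.

qPCR quantification is plain 2^ΔCT fold-ACTIN; an efficiency-corrected
mode ((1+e)^ΔCT) exists but is off by default since the standard reporting
is the plain form. Group comparisons use Tukey's HSD at α = 0.05 with an
insert-and-absorb compact letter display.

## Known limitations

- The conditional-probability engine conditions on the nearest flanking
  informative markers only (no full-chromosome HMM); with heavy
  missingness an HMM would use more information.
- The RIL transition model composes expanded R values between adjacent
  markers; the RIL process is not exactly Markov, a standard approximation.
- Greedy conflict removal is not guaranteed minimal for adversarial
  constraint sets; it is reported, never silent.
- Percentages and printed sizes use half-up rounding; any published table
  rounded differently could differ in the last digit.
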