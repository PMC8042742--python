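# Methods

`dupincompat` detects genetic incompatibilities caused by reciprocally
pseudofunctionalized duplicated genes and maps the extra gene copies that
rescue them. This note documents the models behind each stage, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish about real data.

## The genetic model

A duplicated essential gene has copies at unlinked loci. In one lineage
copy 2 loses function (premature stop, frameshift, promoter
hypermethylation, deletion); in another lineage copy 1 does. Each parent is
healthy, but an offspring homozygous for both nonfunctional haplotypes
carries zero functional copies and dies — a Bateson–Dobzhansky–Muller
incompatibility between duplicate copies. Two signatures follow:

* in an intercross population, the doubly homozygous nonfunctional
  allele-pair class is depleted or absent (segregation distortion at an
  unlinked locus pair);
* in a natural panel, accessions that carry no functional copy of the known
  loci must be rescued by an additional copy elsewhere, so "no functional
  known copy" works as a binary phenotype for association mapping of the
  modifier locus.

## RIL simulator (`sim_ril`)

The crossing design is the eight-founder diallel intercross: a
subpopulation starts from two F1* hybrids (each a cross of two inbred
founders), crossed to give F1 individuals, each advanced by single-seed
descent to F4 or F6. Meiosis draws a Poisson crossover count per chromosome
with mean equal to its genetic length (no interference), places crossovers
uniformly in genetic distance, and converts to physical coordinates by
linear bp↔Morgan interpolation. Residual heterozygosity arises naturally
from the finite number of selfing generations (expected fraction 2^-(g-1),
≈ 3% at F6); nothing extra forces it.

Lethality acts at selection time in every generation (embryo lethality): an
offspring whose functional-copy total over an essential family is zero dies
with probability `penetrance` and is replaced by redrawing a sibling from
the same parents, with bounded retries (error if no viable offspring can be
produced). Partial penetrance models incompatibilities that reduce rather
than eliminate a class.

Observed markers are biallelic dosages (0/1/2) with a symmetric per-allele
flip error (default 0.5%) and uniform missingness (default 10%), RAD-seq
-like sparsity; both rates are configurable because no authoritative values
exist for the emulated data.

For a single unlinked gene pair the simulator also offers an exact fast
path (`simulate_gene_pair_genotypes`): unlinked loci segregate
independently through every meiosis, so transmission reduces to independent
coin flips per locus. This is an exact marginalization of the chromosome
model, not an approximation, and is what the calibration and power analyses
use. `simulate_f1_cross` applies the same machinery to fixed parental
diplotypes for complementation-cross fixtures.

## Founder-haplotype HMM (`hmm`)

The hidden state at a marker is the unordered founder pair on the two
homologs — 10 states for four founders (4 homozygous + 6 heterozygous).

* **Emission**: each of the two allele observations flips independently
  with error ε (default 0.005). At ε = 0.5 the emission distribution is the
  same for every state, so the posteriors collapse to the prior — a useful
  diagnostic identity. Missing observations contribute likelihood 1.
* **Prior**: homozygous states share weight 1 − h, heterozygous states
  share h, with h defaulting to the F6 expectation 2^-5.
* **Transition** over an inter-marker gap of d Morgans: stay with
  probability exp(−k·d), otherwise jump to a state drawn from the prior
  (k = `switch_scale`, default 1). The prior-weighted jump kernel was
  chosen over a uniform redistribution because it keeps the
  homozygosity-enriched prior stationary along the chromosome; a uniform
  kernel lets the chain's marginal drift toward uniform between informative
  markers and breaks the ε = 0.5 identity above.

Decoding is a scaled forward–backward pass (per-marker normalization
constants rather than log-space, so posteriors are directly comparable to a
brute-force path-sum oracle to ~1e-10). MAP states (ties to the lowest
canonical state index) are merged into runs; runs shorter than
`min_markers` are absorbed into the flanking run with higher adjacent
posterior; markers whose MAP posterior falls below `min_posterior` inherit
the nearest confident state to the left. Block boundaries sit at the
midpoint between the two markers flanking a state switch (BED, 0-based
half-open).

Two physical limits cap breakpoint localization: a breakpoint is localized
only to the gap between the nearest flanking markers *informative for the
switching founder pair* (with iid random founder alleles, half the markers
are uninformative for any given pair), and truth blocks shorter than
`min_markers` are invisible to the caller. Accuracy properties are
therefore measured on a panel cycling the three balanced founder
bipartitions (every pair informative at two of three consecutive markers,
as real panels are selected for informativeness) and restricted to
breakpoints whose flanking truth runs meet the caller's resolution; under
those conditions the suite requires ≥ 99% marker-state accuracy and ≥ 95%
breakpoint recall within one marker interval at 0.5% error and 10%
missingness.

## Distortion scan (`distortion`)

Each individual contributes exactly two allele-pair counts at a gene pair:
a double homozygote `aabb` adds 2 to o[a,b]; any genotype with
heterozygosity sorts each locus's alleles canonically and pairs them
positionally (`abbc` → o[a,b] += 1, o[b,c] += 1; true phase is unknowable
at unlinked loci). The per-population statistic is χ² = Σ (o−e)²/e over
cells with positive expectation; the population-wide statistic sums
observed and expected tables cell-wise over the union of all founders
before forming the same quantity (df = positive-expectation cells − 1).

**Expected counts.** Two constructions are implemented. `design` (the
default) uses the crossing-design expectation — uniform 1/16 over a
four-founder subpopulation table — which is exact for a neutral unlinked
pair under the balanced intercross and captures the full incompatibility
deficit, including the marginal allele-frequency shift the lethality itself
causes. `marginal` uses the product of observed marginals (the classical
independence test), which is robust when a locus is distorted for reasons
unrelated to the tested pair (e.g., linkage to an independent viability
locus) but sacrifices the marginal component of the signal. The founder
functional-state confirmation step is the structural guard against
confounding in either mode: a distorted pair is kept only if some founder
is nonfunctional at copy 1 and some founder at copy 2, so a cross could
actually produce a zero-functional genotype.

**Calibration.** Because the two counts of a double homozygote are
identical, the count table is approximately twice an individual-level
multinomial at high homozygosity (F6 ≈ 94% double homozygotes), and the raw
χ² is inflated by a factor near 2 under the null — measured type-I error
~0.42 at α = 0.05. The scan therefore applies a first-order clustered-counts
correction by default: the statistic is divided by the estimated design
effect c = 1 + m/n (m = individuals contributing two identical counts)
before the p-value. Under neutral simulation this restores calibration
(type-I ≈ 0.04–0.06; p-values consistent with uniform). The uncorrected
statistic and p are always available (`correction=None`) since published
worked examples report the raw quantity. Benjamini–Hochberg FDR is applied
within each population's scan family; a pair is retained when any q < α.

Cells remain non-independent even after correction, so p-values are
approximate; conclusions should rest on the two-step screen (distortion
*and* founder evidence), as the workflow prescribes.

## Functional-allele calling (`functional`)

* **Effect classifier** over single-gene models (1-based inclusive
  coordinates, strand-aware): precedence start_lost, stop_lost, cds_loss
  (deletion spanning a whole CDS segment), splice_damage (±2 bp of an
  intron boundary — the canonical donor/acceptor dinucleotides), then the
  variant is applied to the genomic sequence, the CDS re-spliced through
  the indel shift, and classified frameshift (CDS length change indivisible
  by 3) or stop_gained (premature stop in the translated mutated CDS), else
  none. This is deliberately minimal — one transcript per gene, no NMD
  rules; alternative-splicing rescue of a frameshift is an input override,
  not an inference.
* **Methylation profiles**: percent methylated cytosines per 100-bp
  non-overlapping window and context (CG/CHG/CHH) from 500 bp upstream of
  the TSS to 300 bp downstream of the TES, windows running in transcription
  direction. Windows with no covered cytosine are missing and imputed as
  the accession-wise context mean before clustering. Profiles are
  Ward-clustered (Euclidean distance) and the tree cut at two groups, per
  cohort when data come from different processing pipelines; the group with
  higher mean promoter (TSS−500…TSS) CG methylation is labelled
  hypermethylated. Forcing two groups mislabels a cohort that genuinely
  contains one class — all-identical profiles are caught (single group,
  warning), but near-uniform cohorts are a known limitation.
* **Pseudoheterozygous variants** (apparent heterozygous calls from reads
  of two near-identical copies stacking on one locus) are assigned by
  expression contrast: present in DNA and absent in RNA with exactly one
  silenced copy → the silenced copy; present in both → the expressed copy;
  otherwise unassigned.
* **Functional matrix** precedence per accession × copy: absent (by
  coverage; demoted to unknown if RNA nevertheless shows expression) → lof
  → silenced → functional. Accessions without methylation data are assumed
  expressed. The binary phenotype is 1 iff any copy (or the designated
  reference copy, for single-reference-copy families) is functional.

## Mixed-model GWAS (`gwas`)

Markers are filtered to MAF > 0.05 and missing rate < 0.1, with remaining
missing dosages imputed to the marker mean. Kinship is the VanRaden genomic
relationship matrix K = ZZ′/Σ2p(1−p) on centered dosages. The binary
phenotype is fitted as quantitative under y = μ + g + e, g ~ N(0, σg²K),
e ~ N(0, σe²I) — a linear, not logistic, mixed model, a documented
simplification standard in this setting. After a spectral decomposition of
K the restricted likelihood is one-dimensional in δ = σe²/σg²; REML
profiles δ on a log10 grid over [1e−5, 1e5] refined by bounded scalar
minimization (tolerance 1e-8 on log10 δ). Markers are then tested by
weighted least squares in the eigenspace with the null variance components
held fixed (the EMMAX single-fit approximation), Wald p-values from a t
reference with n − 2 degrees of freedom — with K = I the scan reproduces
OLS exactly, which the suite asserts to 1e-8 relative. Constant markers get
p = 1 and are logged. Significance is Bonferroni: the threshold is reported
as −log10(α/m) to two decimals (full precision internally).

## Copy number (`copynum`)

Copy number is the mean depth over the focal region divided by the
genome-wide mean depth, scaled by the reference's known copy count
(baseline 2 when measured over the union of a two-copy family's reference
loci), rounded to the nearest integer with ties to even. Presence of a
non-reference copy is called when mean regional depth ≥ 5× (inclusive) on
the assembly carrying it. No GC or mappability correction is applied; all
aligned depth counts. Coverage I/O uses BED conventions (0-based,
half-open).

## Accession-panel simulator (`sim_panel`)

Accessions are fully inbred (one haplotype per copy; dosages 0/2). Copy
states are drawn per accession from configurable frequencies; an accession
with zero functional copies over the family is viable only through a
modifier and is therefore always a carrier, while others carry the modifier
at a background frequency (default 0.10). Relatedness is discrete
subpopulations with Balding–Nichols allele-frequency drift (default F =
0.1, 3 groups) — the simplest structure that exercises kinship correction.
Methylation classes are two Beta distributions over per-window methylated
fractions (defaults: means 0.8 vs 0.05, concentration 50, 20 reads per
window). Each copy carries one tag LoF variant: present in DNA for `lof`
accessions (and for half of the `silenced` carriers, who show the
DNA+/RNA− pseudoheterozygous contrast), present in RNA only when the
carrying copy is expressed. Coverage tracks are Poisson depths scaled by
the accession's total family copy count against a single-copy reference
(default 30×).

What the generator does *not* emulate: linkage disequilibrium beyond block
structure, realistic site-frequency spectra, read-level artifacts
(mapping-quality bias, bisulfite conversion failure), shared ancestry
between the modifier haplotype and the genome-wide background, or
selection acting on the panel itself. Passing tests therefore establish
the correctness and calibration of the algorithms under their stated
models, not their robustness to every artifact of consortium data.

## Problem sizes

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen to keep the full suite and the script each within a few minutes on
one CPU: F6 subpopulations of 90 lines (exact two-locus path) for
calibration (500–1,000 neutral pairs) and power (30–100 replicates);
8–12 full-chromosome RILs at 2,000 markers for HMM accuracy; accession
panels of 300 × 3,000–5,000 markers over 20–100 association replicates;
500 accessions for copy-number recovery. Sizes are parameters, not limits.

## Known limitations

* The χ² scan's clustered correction is first-order; heterozygous
  individuals' two counts are treated as independent, making the corrected
  test slightly conservative at low homozygosity (early generations).
* The linear mixed model on a binary trait mis-calibrates under extreme
  case/control imbalance.
* The effect classifier is single-transcript and does not model NMD or
  splice-isoform rescue.
* Ward clustering forces two methylation groups per cohort.
* Copy-number ratios assume uniform mappability across the focal region.
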