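# Methods

This note documents the models, estimators, conventions and deliberate
design choices behind `promvar`, and what the synthetic-data tests do and do
not establish about real data.

## Coordinates and variant calling

Input is a pre-aligned multi-FASTA (gap `-`); the package never aligns.
Coordinates are 1-based negative and ATG-relative: the coordinate of an
alignment column is minus the number of non-gap *reference* bases between it
and the ATG column, so −1 is the base immediately 5′ of the A of ATG and a
2000-bp gap-free promoter starts at −2000. Insertions absent from the
reference are anchored at the first reference base 3′ of the gap, which
makes an 8-bp insertion "at −1377" mean: inserted immediately 5′ of the
reference base at −1377.

A maximal run of columns gapped in at least one accession is merged into a
single indel event whose alleles are the gap-stripped per-accession strings;
this counts a multi-column indel as one event, the way published variant
tallies count "3 indels". `N` is missing data, never an allele: a column
varying only through N is not a site, and an accession with N anywhere in an
indel run has a missing call there. There is no minor-allele-frequency
filter — any observed variation is a site. Case is normalized on input;
characters outside `{A,C,G,T,N,-}` are an error rather than being masked,
because silent masking hides upstream data corruption.

## Haplotypes

Accessions sharing an identical fully-observed allele vector form a
haplotype; accessions with any missing call are reported unassigned, not
imputed (homozygous-line Sanger data has no principled imputation rule).
Numbering is by descending member count with ties by first occurrence, so
the partition is order-invariant and the numbering deterministic. Phenotype
summaries use accession means as the unit (mean ± SE over member accession
means); SE is undefined for single-member haplotypes and zero-phenotyped
haplotypes are kept with n = 0 rather than dropped.

## Per-site association

At each site, phenotyped accessions split by exact allele-string comparison
with the reference accession's allele (string equality works identically for
SNP and indel alleles). Groups are compared with the pooled-variance
(equal-variance) Student statistic; Welch is deliberately not used because
the reference analysis is a plain Student *t*. A site where either group
has fewer than two accessions, or where the pooled variance vanishes with
unequal means, is flagged degenerate and excluded from the null and from
significance tallies.

The empirical null shuffles the accession-mean phenotype vector `n_perm`
(default 1000) times; one shuffle is shared by all sites per iteration,
preserving the inter-site correlation structure, and T is recomputed at
every non-degenerate site with the observed group memberships. The permuted
T values are **pooled across sites** into a single null by default — this
reads the singular "empirical null distribution" literally and stabilizes
tail estimates at 1000 permutations; a per-site null is available via
`pooled=False`, and neither mode is claimed to be the original study's.
The two-tailed adjusted p-value is add-one smoothed,
p = (1 + #{|t*| ≥ |T|}) / (1 + N), keeping p ∈ (0, 1].

The `differentiates_subspecies` flag is majority-allele based: the site's
majority allele among *indica* accessions differs from that among temperate
*japonica* accessions. This is one concrete reading of "sites whose
difference matches the indica/japonica difference"; it is a flag, not a
test.

## Phylogeny

Distances use pairwise deletion (positions with gap or N in either sequence
of a pair are dropped) — complete deletion would discard most of an
indel-rich promoter alignment. Default model is the p-distance, with JC69
(d = −¾ ln(1 − 4p/3), undefined at p ≥ 0.75) as an option; both knobs are
exposed because the original tool's settings are not recorded.

Neighbor joining is the Saitou–Nei algorithm implemented directly: join the
pair minimizing Q(i,j) = (r−2)d(i,j) − Σd(i,·) − Σd(j,·); pendant lengths
ℓᵢ = d/2 + (rᵢ−rⱼ)/(2(r−2)); new distances by the standard reduction. Two
determinism rules: Q ties are broken by the lexicographically smallest label
pair (internal nodes carry their smallest leaf label as sort key), and
negative branch lengths are clamped to zero with the total deficit recorded
on the tree (`clamped_deficit`). The Q minimum is taken over the strict
upper triangle so that sub-ulp floating asymmetries in Q cannot hide ties.
Trees are dendropy-backed; Newick round-trips through dendropy.

## Diversity and the sweep scan

Site diversity uses the unbiased estimator π = n/(n−1)(1 − Σₐpₐ²) on called
allele counts, computed with integer arithmetic (n² − Σc²)/(n(n−1)) so it
equals the mean pairwise difference exactly. This operates on called
counts, not genotype likelihoods: the estimator is the same statistic the
low-coverage pipelines estimate, applied to desk-scale input. Window π
divides the site sum by the full window length (20-kb default, BED-style
0-based half-open windows; input positions 1-based), which is the common
window-π convention; a callable-sites denominator would need a mask input
and is out of scope. Sites with fewer than two called chromosomes are
skipped and tallied.

"Above the top 1% of the empirical ratio distribution" is implemented as
strictly exceeding the nearest-rank (1 − f) quantile of the defined ratios.
Windows with π_D = 0 and π_W > 0 have an unbounded ratio: they are flagged
and reported significant but excluded from the cutoff computation. Windows
with both zero are undefined and excluded entirely. Consequence worth
knowing: when a genuinely swept window draws zero domesticated diversity,
the defined-ratio set shrinks by one and the next-ranked neutral window can
slip over the cutoff; this is rare (~1 in 20 default-scale simulations) and
inherent to the rule.

## Color scoring, growth, yield

The four-class pixel classifier works in HSV. The published assay's
thresholds are not available, so the bins here are this package's documented
convention: brown if v < 0.35 (dark) or hue ∈ [0°, 35°); yellow
[35°, 60°); green-yellow [60°, 75°); green [75°, 170°); any hue ≥ 170°
(blues/purples, not leaf colors) falls back to brown. Boundaries are
left-closed/right-open and all live in `ColorThresholdConfig`; the bins
partition the full gamut, so classification is total. An explicit
foreground mask is required — background removal is a segmentation problem
this package does not solve.

RGR is the textbook (ln W₂ − ln W₁)/(t₂ − t₁) in g g⁻¹ day⁻¹. Percent
yield change is 100(NIL − parent)/parent; the function returns the exact
value (so applying it to the parent mean recovers the NIL mean to machine
precision) and reporting rounds decimal half-up to one decimal. Note that
recomputing gains from *printed, already-rounded* per-plant yields can
differ from a published gain in the last digit (the published values were
evidently computed from unrounded data); tests therefore compare printed
gains at one unit in the last printed digit. Group comparisons reuse the
same pooled-variance t as the association module with the Student
two-sided p. Grain-filling rate has no published formula and is accepted
only as a pre-computed column. Trajectory summaries (trapezoid AUC, linear
interpolated time to half the initial value) are conveniences for
chlorophyll time courses, not published statistics.

## Motif scanning

Patterns are IUPAC consensus strings; all overlapping occurrences are
counted by default (`overlapping=False` gives left-to-right non-overlapping
counts) because the original counting convention is unknown — outputs state
the mode. The Dof default scans AAAG and CTTT on the forward strand, which
covers both strands by symmetry; the WRKY default is the W-box core
TTGAC/GTCAA, shipped as a labeled convention, not a claim about the
original database query. `N` in a sequence never matches.

## Synthetic data: what it emulates, what it does not

The panel generator plants, by default: 105 accessions
(30 indica / 41 temperate japonica / 16 tropical japonica / 8 aromatic /
10 aus), a 2000-bp promoter, 21 sites (3 indels) collapsing into exactly
8 haplotypes (4 indica-like, 4 japonica-like), a 15-site differential block
carried by the indica-like half (including the AAAAGCTC insertion at −1377
and one 2-bp deletion), and 6 neutral sites whose carriers are balanced
across the two halves so they are orthogonal to phenotype. Phenotype is
baseline 300 units plus −10 units per causal allele (indica-like expected
mean 150) plus accession-level Gaussian noise of SD 40 — a group separation
of about 3.75 within-group SDs, consistent with the clearly separated
haplotype means the study design presumes; replicate-level noise is off by
default. Wild outgroups are the two founder promoters plus five private
substitutions each. All planted SNPs/deletions are chosen motif-neutral in
an 11-bp window (Dof and W-box patterns), so the founder pair differs in
Dof count by exactly the insertion's +1. The reference accession is the
first japonica-like panel member (whose sequence is the japonica founder),
satisfying the "reference is in the panel" contract without a 9th
haplotype.

Deliberately not emulated: admixture between subgroups (haplotypes are
block-structured by subgroup, as the study's haplotype table shows),
recombination within the promoter, sequencing error, population structure
confounding in the association (no kinship correction exists here either),
and linkage to sites outside the amplicon. Passing tests therefore show the
estimators and algorithms are correct under the stated model — not that the
association design is robust to structure confounding in arbitrary real
panels.

The calibration null uses a dedicated generator (independent random site
splits, iid phenotypes): the haplotype-structured panel makes per-site
outcomes strongly dependent, which is the wrong instrument for checking the
marginal size of the test.

The diversity generator draws the per-window number of segregating sites as
Poisson with mean λ = π·W / E[2p(1−p)], p ~ U(0.1, 0.9), and allele counts
binomially — under the unbiased estimator E[π̂_site | p] = 2p(1−p) exactly,
so window estimates are unbiased for the target without any conditioning.
Problem sizes in tests (202 windows × 20 chromosomes, 20 seeds; 1000-site
null panels at 1000 permutations; 100 random trees of 4–8 taxa) were chosen
as the smallest scales at which the binomial/Poisson noise bounds in the
acceptance properties are comfortably met.

## Determinism

Every stochastic routine takes a seed and uses an isolated
`numpy.random.Generator`; generators are pure functions of
(config, seed), pipeline reruns are byte-identical, and the association
output header records n_perm, alpha and seed.
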