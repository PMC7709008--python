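# Methods and design notes

## The analysis model

The package treats a crop germplasm panel as a two-level population:
accessions (seed lots collected at individual sites — landraces,
cultivars or breeding populations) nested in an overall gene pool, with
individual plants sampled per accession and genotyped at biallelic SNP
loci. All statistics are computed on unphased diploid calls
(hom-ref / het / hom-alt / missing) relative to each locus's
reference and alternate alleles; multi-allelic loci are outside the
model (and are removed by the marker filter before assay design).

## Marker filtering

The candidate filter encodes the constraints a fluorescence-based
allele-specific PCR assay puts on a SNP discovered between two
sequenced parents: reliable parental calls (depth ≥ 6 in both
parents, both homozygous), a clean biallelic contrast (exactly one
parent diverging from the reference transcript), clean flanking
sequence (no second varying site and no parental indel within 10 bp on
either side), and locus uniqueness in the genome (the contig must have
a homolog hit in the related reference genome, and that homolog must
not be shared with another contig — a paralogy signal).

Three reading choices were genuinely open and are fixed as follows:

* **Indel exclusion is site-proximal, not contig-wide**: a parental
  indel disqualifies a SNP only when it falls within the proximity
  window. Rationale: the stated purpose of the rule is clean assay
  flanks, which only the local neighbourhood affects.
* **The proximity rule counts only varying non-indel rows**; indel
  records are handled exclusively by the indel rule, so the two rules
  partition the "dirty neighbourhood" failures.
* **Proximity is evaluated on the pre-filter row set**: a nearby
  variant disturbs the assay whether or not it itself survives
  filtering.

Rules 1–4 and 6 are per-row predicates, so the surviving set is
invariant to their order (a tested property); the proximity rule
(row-set based) and the shared-homolog rule (map based) are anchored at
their cascade positions. Coordinates are 1-based and fully closed
throughout, and the flank extractor raises on any reference-allele
mismatch to catch off-by-one conventions early.

## Genotype QC

Loci are classified failed (no calls at all), monomorphic (calls but a
single observed allele) or polymorphic; the success rate is the
non-failed fraction. The missingness filter keeps polymorphic loci
with missing fraction ≤ 10% — a strict reading of "more than 10%
missing": exactly 10% is kept. The filter is idempotent and the ladder
telescopes (assayed = failed + monomorphic + dropped + analysis loci).

## Diversity statistics

Closed forms per locus, with p the reference-allele frequency over
called genotypes and N the called individuals: He = 2pq,
uHe = 2N/(2N−1)·He, Ho = n_het/N, I = −(p ln p + q ln q),
Ne = 1/(p²+q²), PIC = 1 − (p²+q²) − 2p²q² (= He − 2p²q², so PIC ≤ He
and PIC ≤ 0.375 with the maximum at p = ½).

The Hardy–Weinberg test is the exact conditional test: given the
observed allele counts, every compatible heterozygote count h (same
parity as n_A, 0 ≤ h ≤ min(n_A, n_B)) receives its Levene–Haldane
probability ∝ n! 2^h / (n_AA! h! n_BB!), and the two-sided p sums
the probabilities of configurations no more probable than the observed
one. The excess/deficit direction compares the observed h with its
conditional expectation n_A n_B / (2n − 1), independent of the
p-value. Significance tiers are p ≤ 0.01 (highly significant) and
0.01 < p ≤ 0.05; no multiple-testing correction is applied by default
because per-locus raw significance is the reporting convention for
such panels (a Bonferroni pass can be layered on the returned
p-values).

Per-accession summaries average I, Ho, He, uHe over *all* analysis
loci, so within-accession-monomorphic loci contribute zeros — the
convention that makes accessions with different polymorphic subsets
comparable. The fixation index F is the mean of per-locus (He−Ho)/He
over loci with He > 0 (mean-of-ratios, the GenAlEx convention);
`f_convention="ratio_of_means"` gives the alternative. θ(SMM) is the
Ohta–Kimura back-transform ½[(1/(1−h))² − 1] applied to the
accession's mean unbiased heterozygosity. Note this transform applied
to typical SNP heterozygosities (~0.28) yields θ ≈ 0.44; published
Theta(H) columns of order 2 imply a different (unrecoverable)
heterozygosity input, so θ here is defined by the formula, not by any
published column. Gene flow Nm = ¼(1−F_ST)/F_ST is undefined (NaN)
for F_ST ≤ 0 rather than infinite.

## F-statistics

Nei's heterozygosity decomposition is the default: per locus, Ho is
the mean observed heterozygosity, Hs the within-accession expected
heterozygosity averaged with called-sample-size weights, Ht the
expected heterozygosity of pooled frequencies; F_IS = 1−Ho/Hs,
F_ST = 1−Hs/Ht, F_IT = 1−Ho/Ht, with overall values from sums of the
components across loci so the identity (1−F_IT) = (1−F_IS)(1−F_ST)
is exact. By default Hs and Ht carry the Nei–Chesser small-sample
corrections (the 2n/(2n−1) factor and the Hs/(2ñr) total-diversity
term): the raw plug-in G_ST is biased upward by roughly 1/(2n), which
at 12 individuals per accession would overstate F_ST ≈ 0.045 panels
by nearly a factor of two. `corrected=False` restores the plug-in
forms. Weir–Cockerham θ (per-locus a/b/c components, ratio-of-sums
overall) is provided as an independent estimator; the two agree in
rank per locus and the suite checks it.

## AMOVA

Genotypic AMOVA with an intra-individual level: each individual is
expanded into two allele vectors, and the squared distance between two
allele vectors is the count of loci with differing alleles (missing
loci excluded pairwise; phase is irrelevant because a heterozygote
contributes symmetrically). Sums of squares partition as within
individuals / among individuals within accessions / among accessions,
plus an among-groups level in the hierarchical design. Variance
components come from the expected mean squares with the standard
unequal-sample-size coefficients on haplotype counts (every individual
contributes exactly two haplotypes, so the individual-level
coefficient is exactly 2). Negative components are reported as
computed and flagged, never clamped.

Permutation tests use level-appropriate schemes — individuals among
accessions for F_ST, haplotype re-pairing within accessions for F_IS,
global re-pairing plus reassignment for F_IT, whole accessions among
groups for F_CT, individuals among accessions within groups for
F_SC — with p = (#{permuted ≥ observed} + 1)/(n_perm + 1), floored at
1/(n_perm+1). The default n_perm is 1023. Pairwise F_ST runs the flat
two-accession AMOVA per pair (F_ST scheme only) and reports each
accession's mean off-diagonal F_ST on the matrix diagonal, the common
reporting convention.

## Distances, trees, ordination, ΔK

Pseudo-sequences map calls to one character per locus (reference base,
alternate base, IUPAC two-base code, or N). The Tajima–Nei distance
uses pair-averaged base frequencies g_i and pair-mismatch frequencies
x_ij: h = Σ_{i<j} x_ij²/(2 g_i g_j), b = ½(1 − Σg_i² + p̂²/h),
d = −b ln(1 − p̂/b); at uniform composition it reduces exactly to
Jukes–Cantor (a 1e−12-level test). Ambiguous characters are excluded
pairwise by default — heterozygous sites therefore do not enter the
distance, matching the common default treatment of ambiguity codes in
distance software; saturation (p̂ ≥ b) and empty comparisons yield
flagged NaN rather than numbers.

EAED (within-accession average pairwise divergence) first drops
samples with more than 7% missing calls, then averages Tajima–Nei
distances within each accession over three locus sets: all loci,
MAF ≥ 0.3, and MAF < 0.3 (a partition). Accessions left with fewer
than two samples are reported not-computable.

Neighbor joining is delegated to scikit-bio's implementation (exact on
additive matrices — verified in the suite against a path-length oracle
on random trees and a four-point-condition oracle on four taxa); ids
are sorted lexicographically first so Q-criterion ties break
deterministically, tip labels are whitespace-sanitized, and negative
branch lengths are kept but flagged (optional clamp to zero).
Accession-level distances are plain averages of inter-accession
individual distances; the net-divergence variant (subtracting half the
within-accession means) is an option. Individual-level trees use only
complete-data individuals.

PCoA is the classical Gower double-centering of −d²/2 followed by a
symmetric eigendecomposition; axes are ordered by eigenvalue, percent
variance uses the sum of positive eigenvalues as denominator, negative
eigenvalues are reported but excluded from axes, and requested axes
beyond the positive spectrum are truncated with notice.

ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / sd(K) over interior K of a
mean/SD log-likelihood table; sd = 0 rows are excluded from the argmax
with a warning, and fewer than three consecutive K values is an error.

## The simulators

`simulate_genotype_matrix` implements the Balding–Nichols island
model: per locus an ancestral frequency is drawn uniformly from the
minor-allele band (default 0.05–0.5) and randomly labeled (so the MAF
spectrum includes rare and common alleles); each population draws
p_k ~ Beta(p(1−F_ST)/F_ST, q(1−F_ST)/F_ST), whose among-population
variance is exactly F_ST·pq — giving a closed-form differentiation
truth for parameter-recovery tests; genotypes follow
inbreeding-adjusted proportions P(AA) = p_k² + F_IS p_k q_k, P(AB) =
2p_k q_k (1−F_IS); missingness is independent per call. A negative
F_IS that would drive a probability negative at a realized p_k is an
error, not a clamp. All randomness derives from one seed through a
counter-based stream per locus, so results are independent of
iteration order and reproducible to the byte. Defaults mirror a
realistic germplasm campaign: 24 accessions × 12 individuals × 202
loci, F_ST 0.045, F_IS 0.06.

What the generator does *not* emulate: linkage disequilibrium between
loci (loci are independent), assay-level artifacts (null alleles,
cluster-calling errors), sample-level missingness correlation (a
failed DNA extraction knocks out whole rows, not random cells), or
ascertainment bias from a two-parent discovery panel. Passing
recovery tests therefore demonstrates estimator correctness under the
island model, not robustness to those real-data features.

`simulate_variant_call_table` packs clean SNPs (spaced > 2 windows
apart) and planted failure rows — each violating exactly one cascade
rule — onto dedicated contigs, and returns a ledger mapping every
candidate row to its class, so filter tests can assert exact
class-by-class attrition. Proximal-variant and shared-homolog
failures necessarily come in groups of ≥ 2 (a row needs a neighbour
to be proximal to); an odd request beyond 2 is laid out as one triple.
`parent_indel` failures pair a clean SNP with a companion indel record
inside the window; companion records are part of the table but are not
filter candidates and so sit outside the ledger partition.

`simulate_loglik_table` draws a piecewise-linear mean log-likelihood
(steep slope 600 per K before the elbow, 60 after, Gaussian noise
SD 10, run-to-run SDs uniform in 10–30) for K = 1..k_max, 20 runs per
K — the shape of a clustering-program summary whose ΔK argmax is the
planted elbow by construction.

## Problem sizes and numerical choices

The suite and the acceptance script run everything at the sizes the
analyses are designed for: recovery experiments use 24 × 12 × 202
panels over 20 replicate seeds (with 199 permutations where p-values
are needed; 1023 is the interactive default), HWE calibration uses
1500 panmictic loci at 200 individuals, and tree/ordination oracles
use ≤ 12-leaf random trees — a full run completes in a few minutes on
one CPU. Tolerances: PIC and the scalar transforms are exact closed
forms; AMOVA/Nei recovery is judged at ±0.015 on F_ST (3-ish Monte
Carlo SEs at these sizes); the Tajima–Nei/Jukes–Cantor identity at
1e−12 relative; HWE calibration at 3 binomial SEs. Ties in the exact
HWE tail sum use a 1+1e−12 relative tolerance on the observed
configuration's probability, the standard guard against
floating-point ties in exact tests.

## Known limitations

* The exact HWE test is conservative at small samples (discreteness),
  so its realized type-I error sits below the nominal level.
* Plug-in (uncorrected) Nei G_ST is exposed but biased at small n;
  the corrected default should be used for inference.
* AMOVA distances use pairwise deletion; under extreme, non-random
  missingness the sums of squares are no longer an exact ANOVA
  decomposition (percentages still sum to 100 by construction).
* Accession-level NJ trees average individual distances; with very
  uneven within-accession diversity the net-divergence option can
  reorder close accessions.
* The clustering log-likelihood table is consumed, not produced: the
  admixture inference itself (the MCMC) is out of scope.
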