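# Methods

## Morphometrics

**Generalized Procrustes analysis.** Each landmark configuration (k
landmarks in d ∈ {2,3} dimensions) is translated to the origin and scaled
to unit centroid size `CS = sqrt(Σ ||x_i − x̄||²)`; configurations are then
rotated onto the current consensus by the orthogonal Procrustes solution
constrained to proper rotations (det = +1; reflections are never
introduced, and the generator never plants them, so chirality resolution
is not required). The consensus is the re-centred, re-scaled mean of the
aligned configurations, iterated until its RMS change falls below `tol`
(default 1e-10, max 100 iterations; non-convergence is flagged, not
raised). Because the consensus orientation is otherwise arbitrary (it
inherits the initialisation specimen's frame), the converged solution is
rotated onto the consensus' principal axes with a data-driven sign
convention on the first d−1 axes and the last axis fixed by det = +1;
alignment output is then invariant to specimen order and to arbitrary
similarity transforms of any input. Pre-alignment centroid sizes are the
size phenotypes.

**Allometry.** Shape depends on size; the correction regresses all aligned
shape coordinates jointly on a positive size predictor. The predictor is
an explicit argument because the appropriate proxy is a modelling choice —
in the skull application the *neurocranium* centroid size is used as a
body-size proxy when correcting *viscerocranium* shape. The predictor is
used as supplied (no log transform). The percentage of shape variance
explained is pooled over coordinates, `100·SS_explained/SS_total`, and its
significance comes from random permutations of the predictor
(`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, default 10,000 permutations,
seed mandatory). Residuals retain the grand mean and feed the PCA.
Object-symmetry averaging ("symmetric coordinates") is not applied: it
requires a left/right landmark pairing map that is dataset-specific; the
regression operates on the aligned coordinates as given.

**Shape PCA.** SVD of the centred residual matrix; scores are the centred
residuals projected on the loadings, variance fractions are normalised
singular values squared, and each component's sign is fixed so its
largest-magnitude loading is positive. PCA is applied to the covariance
structure of the residuals (not to an inter-specimen distance matrix).
Because the sign remains a convention, `orient_pc` flips scores so a
designated reference group is negative — brachycephaly corresponds to
negative facial PC1 only after orientation.

## Mixed-model association

Per marker, `y = Wα + xβ + u + ε` with `u ~ N(0, σ²_g K)`,
`ε ~ N(0, σ²_e I)`. `K` is the centred genomic relationship matrix
`ZZᵀ/m` (column-centred, mean-imputed dosages). `K` is eigendecomposed
once; in the rotated basis the variance ratio λ = σ²_g/σ²_e is profiled by
Brent search over log λ ∈ [log 1e-5, log 1e5] with 1e-6 tolerance,
maximising the restricted likelihood
`−2l ∝ Σ log(λs_i + 1) + log|XᵀV⁻¹X| + (n−c) log RSS`.
At the optimum, β̂ and its standard error come from weighted least squares
and the Wald statistic is referred to t(n−c); with `K = I` the procedure
reduces *exactly* to the ordinary-least-squares t test, which is a unit
test. REML (not ML) and the Wald test are the conventional defaults for
this model class. Monomorphic markers get missing p. QC order: samples
with missing fraction strictly above 0.1 are dropped first, then markers
with MAF strictly below 0.05 (computed on retained samples).

Calibration at desk scale: with 200 samples and 2,000 markers in LD
blocks, generalized least squares at the *true* variance ratio is exactly
calibrated (measured type-I ≈ 0.049), while estimating the ratio per
marker adds roughly one percentage point (≈ 0.057) — the familiar
finite-sample cost of plugging in a variance estimate, which shrinks with
n. Because markers within a block are strongly correlated, a single scan
measures the rejection rate with an effective sample size far below the
marker count; the acceptance checks therefore pool several replicate
scans at the same size.

λ is the median of the χ²(1)-quantile-transformed p-values divided by the
χ²(1) median (0.4549364). The Bonferroni threshold is α/m. LD pruning
removes, per chromosome, the most significant marker at or below the scan
threshold together with every marker whose r² with it strictly exceeds
0.2 (r² = squared Pearson correlation of dosages over pairwise-complete
samples).

## Haplotype fine-mapping

**Sliding-window test.** Each 10-marker window's distinct haplotypes form
the classes of a one-way ANOVA of the per-copy phenotype (each diploid
sample contributes its phenotype once per chromosome copy). Classes with
fewer than 5 copies are pooled into a single rare class — an omnibus test
needs some rare-class policy, and 5 copies is the smallest class that
contributes a usable within-group variance. Windows with fewer than two
classes after pooling return missing p.

**Cases, consensus, interval.** Cases are the phenotype tail
(`≤ threshold` by default; `lt`/`ge`/`gt` available because the inclusive
boundary is a reporting convention, not a biological one). The consensus
haplotype is the per-marker majority allele over case chromosome copies;
exact ties break toward the copy with the most extreme (most negative)
phenotype. For the critical interval, each case copy that matches the
consensus at the index marker contributes the maximal consensus-matching
run containing the index; the gaps just outside that run are its left and
right recombination breakpoints (copies mismatching at the index are
non-carriers, excluded and reported — they carry a variant haplotype, not
a recombined one). Walking outward from the index, each boundary is the
first gap at which the cumulative count of *distinct recombining copies*
reaches `min_recomb` (default 3), counted per side — both boundaries must
be independently supported. Chromosome copies, not individuals, are the
counting unit. The interval is the markers strictly inside the two
boundary gaps; its length is `end_pos − start_pos`, the convention under
which the published-style coordinates 55,850,299–56,037,676 give
187,377 bp. If a side never accumulates enough breakpoints the interval
is clipped to the panel edge and flagged.

**Carriers.** A copy carries the core haplotype iff it matches at every
defining marker; frequencies are exact count ratios rendered to one
decimal. A pooled two-sided t test compares phenotypes of carrier samples
(≥ 1 carrying copy) against non-carriers. `select_core_markers` reduces
the interval consensus to the reported signature: markers whose
single-marker p passes the genome-wide threshold or whose r² with the
index exceeds the pruning threshold.

## Identity-by-descent variant filtering

The five assumptions: (1) haplotype-homozygous cases carry the causal
variant; (2) identity-by-descent means they all carry the *same* causal
allele, hence uniform homozygosity; (3) the candidate allele may be REF —
reference assemblies can derive from a haplotype-fixed animal; (4) the
causal allele is derived, absent from wild canids; (5) haplotype-free
controls cannot carry it. Assumptions 1–3 collapse into candidate-allele
assignment; 4–5 are carrier screens. Missing genotypes never eliminate a
record (absence of a call is not absence of the allele — sequencing depth
varies across cohorts); a strict mode additionally requires at least one
non-missing wild and control call. Eliminations are tallied by first
failing rule; the report mirrors the SNV/INDEL-vs-SV two-column layout.
The filter is monotone (adding screening samples can only shrink the
survivor set) and independent of record and sample order, both property-
tested. Conservation-based ranking of survivors is out of scope; survivors
are reported unranked.

## Effect modelling

* Genotype classes are coded 0/1/2 (homozygous ancestral / het /
  homozygous derived). Pairwise Mann-Whitney-Wilcoxon (exact null for
  combined n ≤ 20 without ties, tie-corrected normal approximation
  otherwise) and Kolmogorov-Smirnov tests; additive trend via least-squares
  regression on dosage.
* Stepwise PVE: each locus's standalone `100·R²` is its *maximum potential*
  contribution (not additive); forward selection by AIC (BIC and adjusted
  R² are options) with a minimum-improvement stop gives the joint model and
  joint PVE. Raw (unadjusted) R² is reported.
* Pfaffl ratio: `E_t^(ΔCt_t) / E_r^(ΔCt_r)` with per-assay efficiencies in
  (1, 2] (fold per cycle), calibrator minus sample.
* Allelic-imbalance percentages round by largest remainder so the printed
  pair always totals 100.
* Splice-acceptor scan: flags the AG dinucleotide immediately 5' of each
  junction and enumerates all AG-preceded positions.
* `naive_fold_change` is a transparent descriptive statistic
  (median-of-ratios size factors, ratio of group means), not a
  differential-expression inference; dispersion modelling is deliberately
  out of scope.

## Synthetic-data generator

The generator defines the study conditions the tests and acceptance checks
run under.

**Genotypes.** Balding-Nichols structure: each LD block draws an ancestral
frequency p0 ~ U(0.1, 0.9) shared by its markers; breed frequencies are
Beta(p0(1−F)/F, (1−p0)(1−F)/F), giving variance F·p0(1−p0). Within a
block, each chromosome copy inherits one of a per-breed founder-haplotype
pool (alleles Bernoulli(breed frequency)) with a 1% per-site copying error
— realistic within-block r² without a coalescent simulator. The founder
pool size defaults to ~1/F (clipped to [2, 500]): drift and frequency
divergence share the bottleneck as their common cause, so F → 0 recovers a
panmictic population. The planted causal haplotype is a *derived sweep*: a
contiguous run of `causal_markers` (default 12) all-alt markers whose
block's ancestral frequency is drawn low (U(0.02, 0.1)), overwritten on
each chromosome copy with probability 0.9 in case breeds and 0.04
elsewhere — mirroring observed case/control haplotype frequencies of
roughly 85% and 4%. Dosages are the sums of the two copies by
construction.

**Landmarks.** Specimen i is
`s_i · R_i (M + log(s_i)·A + d_i·q·V + E_i) + t_i`: unit-centroid-size
mean shape M, allometric direction A scaled by `allometry_slope` per
log-size unit, unit-norm QTL displacement V confined to the facial
(viscerocranium) landmark subset dosed by causal dosage × `qtl_effect`,
iid Gaussian landmark noise, and a random similarity transform (uniform
proper rotation; log-normal size, SD 0.3 around a 100-unit mean; Gaussian
translation) so that Procrustes alignment is genuinely exercised. Landmark
counts split ~18/25/30 across neurocranium/viscerocranium/mandible,
mirroring the real landmarking scheme.

**Variant tables.** Exactly the planted records satisfy all five filter
assumptions (the first planted SNV uses the REF allele as its candidate,
exercising the reference-assembly path); every other record violates at
least one assumption, with first-violated rules cycled across all five,
plus ~1% of records with no case data. Group sizes and the 1-based region
default to the application's interval coordinates.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: recombination maps and coalescent LD decay
(blocks have sharp edges), genotyping and imputation error, phasing error
(panels are perfectly phased), measurement error structure of manual
landmarking (noise is iid and isotropic), shared environment, and
selection beyond the single planted sweep. Recovery rates on synthetic
cohorts are upper bounds on real-data performance.

## Problem sizes and numerics

Test and acceptance runs use desk-scale cohorts chosen to leave the
statistical structure intact: end-to-end recovery uses 150 dogs, 6 breeds,
400 markers and 24 landmarks over 50 seeds; null calibration uses the full
200 × 2,000 prescription pooled over six replicate scans; the variant
filter rehearses the full 3,674 + 162 record table. All randomness flows
through explicit seeds (numpy `SeedSequence` substreams); fixed seeds give
byte-identical outputs. Degenerate inputs (all-identical landmark
configurations, constant predictors, monomorphic markers, empty case
sets, empty groups) raise informative errors or are recorded as missing,
as documented per function.
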