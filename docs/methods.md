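# Methods

## The admixture model and its estimator

`helihybrid` fits the standard unlinked-loci admixture model. Each
individual *i* carries an ancestry vector **q**ᵢ on the K-simplex
(K = 2 here: *H. armigera*, *H. zea*); population *k* has an
alt-allele frequency f₍ₖⱼ₎ at site *j*. Conditional on (Q, F) the two
allele copies of a genotype are i.i.d. Bernoulli(pᵢⱼ) with
pᵢⱼ = Σₖ qᵢₖ f₍ₖⱼ₎, so the dosage gᵢⱼ ∈ {0, 1, 2} is
Binomial(2, pᵢⱼ) and the log-likelihood is the binomial form given in
the README. Missing genotypes are skipped term-wise, with each
individual's called-site count Jᵢ entering its own q update.

The fit is plain EM (the FRAPPE-style updates) rather than
block-relaxation quasi-Newton: at desk scale (tens of samples, a few
thousand sites) EM converges in well under a second per hundred
iterations, and its ascent property gives a free invariant — the
log-likelihood trace must be non-decreasing — that the test suite
checks on every fit. The E-step attributes each allele copy to a
population in proportion to qᵢₖf₍ₖⱼ₎ (alt copies) or qᵢₖ(1−f₍ₖⱼ₎)
(ref copies); the M-step renormalises. Because the F update maximises
a concave minorizer coordinate-wise, projecting F onto
[ε, 1−ε] (ε = 10⁻⁶) preserves monotonicity while preventing log 0 at
fixed species differences.

Tunable parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `n_populations` | 2 | ancestral populations (the species pair) |
| `tol` | 1e-6 | stop when Δ log-likelihood falls below this |
| `max_iter` | 2000 | EM iteration cap |
| `random_state` | none (mandatory in pipeline configs) | Dirichlet(1) init of Q, N(0, 0.1) perturbation of empirical frequencies for F |
| `projection_tol` | 1e-8 | max |Δq| stopping rule for supervised projection |

Supervised projection holds F fixed (empirical, clipped frequencies of
the classified pure panels) and runs the q-only EM per individual;
each row is then an independent 1-D maximisation over the simplex,
which the acceptance suite cross-checks against a brute-force grid
search at step 10⁻⁴. An individual with zero called genotypes has no
likelihood and is reported as NaN.

Label switching: the two fitted frequency rows are matched to species
by Pearson correlation with empirical alt frequencies of
species-labelled anchor samples (the putative labels of the sample
sheet). With no anchors the columns are ordered deterministically by
the first sample's q and named `pop1`/`pop2`, with a warning —
downstream purity classification requires real species labels.

Purity: a sample is an unhybridized reference genome iff its ancestry
fraction for one species is ≥ 0.99. The threshold is deliberately
strict; with a few thousand analysis sites the ML ancestry of a truly
pure individual concentrates within ~10⁻³ of the vertex, while an F1
sits at 0.5.

## Filters, pruning, AIMs

Filtering retains a site iff mean DP across **all** samples ≥ 5
(zero-depth reference calls included — they are genuine caller
output), QUAL ≥ 20, joint MAF ≥ 0.05, and the site is not on chr1
(the Z chromosome; hemizygosity in females distorts autosomal ancestry
fractions). Removal conditions are strict `<`, so thresholds are
inclusive on the keep side; an all-missing site has undefined MAF and
is removed. The report counts each criterion on the unfiltered table
plus the union, so multi-criterion sites appear once per criterion and
once in the union.

LD pruning uses squared Pearson correlation of unphased dosages over
jointly called samples (constant vectors and <2 joint calls give
r² = 0 by convention). Within each 50-SNP window, while any retained
pair has r² > 0.95, the member of the worst pair with the lower MAF is
removed (tie: larger position); the window advances 5 SNPs and never
spans a chromosome. Only the r² ceiling is externally fixed;
window/step and the lower-MAF rule are this package's defaults, chosen
to echo common pairwise-pruning practice and kept configurable.
Removal on an already-pruned table is not guaranteed to be empty in
general — re-windowing can juxtapose previously distant pairs — but on
unlinked data the probability of a new r² > 0.95 pair is negligible,
and the suite asserts idempotence on seeded simulated cohorts.

A site is a zea-diagnostic AIM iff every genome of the pure *H. zea*
panel carries ≥ 1 alt allele — a missing call disqualifies the site,
since missingness cannot certify presence — and at most one pure
*H. armigera* genome carries it (`max_armigera_carriers`, default 1;
0 gives strictly private markers and a 0 % armigera floor). Scoring
offers two codings. Dosage coding (alt copies / 2·AIMs) is the
default because it is the only coding whose ideal-F1 expectation is
exactly 50 %; presence coding (fraction of AIMs with any alt copy)
scores an ideal F1 at 100 % and is retained for comparison. The gap
between the codings is itself informative about heterozygosity.

Reference bias: genomes are mapped to an *H. armigera* reference, and
the joint caller emits the homozygous-reference genotype wherever a
sample has no reads. A low-coverage *H. zea* genome therefore acquires
spurious armigera ancestry. `depth_diagnostics` counts AIMs at DP = 0
and DP < 5 per sample, and `aim_ancestry_proportion(...,
mask_below_dp=5)` recomputes the proportion excluding unreliable AIMs
from numerator and denominator. For a pure zea genome whose only
corruption is zero-coverage reference calls, masking exactly restores
100 % — the acceptance suite checks the full arithmetic at corruption
fractions 0.1–0.3.

## What the simulator emulates — and what it does not

`SimConfig` defaults define the study conditions: 31 chromosomes with
chr1 as the excludable sex chromosome, Balding–Nichols divergence at
F_ST = 0.3 (ancestral frequency Uniform(0.05, 0.95); each population
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)), 2 % of sites forced to fixed
differences so AIM-like sites always exist, 20 + 20 pure individuals,
30× mean depth (the real cohort's genome-wide means span roughly
9–107×, with hybrid validation genomes near 100×), and 5 % of sites
forced below QUAL 20 via the stand-in QUAL = min(99, 3 × mean DP)
model. Depth is Poisson per sample × site; each read draws one of the
individual's two allele copies uniformly; a call is homozygous iff a
single allele was observed, so P(het called het | DP=d) = 1 − 2^(1−d),
and DP = 0 yields the homozygous-reference artifact, never a missing
genotype.

Backcrosses are modelled as unlinked admixed individuals with
q = 0.75/0.25 rather than via recombination maps, matching the
unlinked-loci assumption of the ancestry model itself. Consequences:
passing tests demonstrate correct inference under the model's own
assumptions, not robustness to real-data features the generator omits
— linkage blocks and local-ancestry tracts, base-calling and mapping
error, batch effects between sequencing runs, within-species
population structure, and a realistic caller error model (the
read-draw model here is an explicit stand-in). F_ST estimated from the
simulated pure panels is verified against the configured value with a
Hudson-type estimator.

## Experiment sizing and numerical choices

The acceptance experiments run at the scale a desk machine handles in
seconds to minutes: the F1-recovery experiment uses 6 800 simulated
sites reduced to exactly 5 000 after filtering/pruning (subsampled
seeded if more survive), the purity-classification experiment uses
5 000 sites — sized so the per-sample ancestry sampling error
(∝ 1/√J at fixed F_ST) is far below the 0.01 slack the 0.99 purity
threshold allows — and the grid-search cross-check uses 100 random
20-site instances. Ties in pruning break toward removing the later
position; the worst pair is the first argmax in row-major order;
site order is always (chromosome, position) with chromosomes in
numeric order. All randomness flows through `numpy` Generators seeded
from user-supplied integers; identical seeds give bit-identical
outputs, which the suite asserts down to written files.

## Known limitations

* K is fixed at 2; no model selection, cross-validation error, or
  bootstrap standard errors.
* Global ancestry only — no chromosome-painting/local ancestry, so an
  old introgression tract and recent admixture are indistinguishable.
* The AIM proportion of a real F1 depends on panel size and AIM
  ascertainment; both codings are reported precisely because neither
  reproduces every published summary of the same quantity.
* Full-scale numbers from the original cohort (SNP counts after
  pruning, AIM counts) depend on upstream mapping/calling tools and
  their versions, which are out of scope here; the pipeline starts at
  the VCF.
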