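# Methods

## The problem and the model

Bulk expression profiling averages the transcriptomes of every cell in a
sample. Even in a type-homogeneous cell line, subpopulations executing
different molecular programs — proliferating versus quiescent cells,
surviving versus dying cells — contribute distinct transcriptional
patterns to that average. `mph` estimates, for each sample, the fraction
of the signal attributable to each functional subpopulation, together with
a subpopulation-specific expression profile ("metaprofile"; its values
reflect trends, not absolute transcript counts).

Both estimators share one generative model. With genes i = 1..I, samples
j = 1..J carrying condition labels c(j), and T subpopulations:

    y_ij = sum_t p_tj * x_{t,i,c(j)} + eps_ij,      eps_ij ~ N(0, 1/lambda_i)

where p_j lies on the T-simplex, profiles x are nonnegative, and the noise
precision lambda_i is per-gene (heteroscedastic across genes, shared
across subpopulations and conditions). In matrix form X ≈ W H with W the
I×T profile matrix and H the T×J proportion matrix.

## Stage 1: Bayesian deconvolution (`mph.dsection`)

An unsupervised mixed Gibbs / Metropolis–Hastings sampler:

* profile entries: conjugate Normal conditionals truncated at 0, sampled
  exactly by inverse-CDF (no rejection loop), one component at a time,
  vectorized over genes;
* precisions lambda_i: conjugate Gamma conditionals;
* proportions p_j: Metropolis–Hastings with a Dirichlet proposal centered
  at the current value (precision `proposal_precision`, default 100; the
  asymmetric proposal density is corrected in the acceptance ratio).

Priors: p_j ~ Dirichlet(concentration · p0_j) around user-supplied centers
(default uniform, concentration 10); lambda_i ~ Gamma(1, 1); profile
entries ~ Normal(x_mean, x_var) truncated at 0 with x_mean the empirical
matrix mean and x_var 2.5× the empirical variance by default.

**Partial identifiability and the profile-prior width.** For any mixing
matrix A with unit column sums, (WA, A⁻¹H) reproduces WH exactly, so the
likelihood is flat along a simplex ridge that merges components; data of
any noise level cannot pin the proportions down completely. The posterior
mean of p then carries a prior-geometry bias: with a very diffuse profile
prior the marginal volume factor favors merged components and shrinks
proportions toward the prior center, while an overly tight prior pulls
profiles toward the global mean and pushes proportions outward to
compensate. The 2.5× default balances these opposing pulls; on the default
synthetic conditions it recovers proportions to within ~0.04 per entry
where 10× shows ~0.05 inward bias and 1× overshoots outward. This is why
the workflow has two stages: the hard marker constraints of stage 2
eliminate the ridge entirely.

Defaults n_iter=4000, burn_in=1000, thin=3 keep default-size problems
(500×6) under a few seconds. Component labels are exchangeable; they are
resolved after sampling, never inside it: `match_components` finds the
label permutation maximizing summed Pearson correlation with a reference
(Hungarian assignment, verified against exhaustive search), and with
multiple conditions each condition's posterior-mean profiles are aligned
to the first condition's, since nothing ties labels across conditions
under a symmetric prior.

## Stage 2: marker-guided KL factorization (`mph.sskl`)

Minimizes the generalized Kullback–Leibler divergence

    F(X, W, H) = sum_ij [ X_ij log(X_ij/(WH)_ij) − X_ij + (WH)_ij ]

by the classical coupled multiplicative updates (H half-step then W
half-step, WH recomputed between them; each half-step is monotone in F).
0·log 0 is taken as 0; a cell with X > 0 and (WH) = 0 makes F infinite
(reported as inf, never NaN). Factor entries are floored at 1e-12 after
each update to protect denominators.

Semi-supervision: for every marker gene of component t, W entries in all
other components are clamped to zero after initialization and after every
step. This anchors both the component identities and their labels (no
post-hoc matching needed) and removes the mixing ridge described above.
Hard zeroing can in principle break the per-step monotonicity guarantee;
violations are counted and logged (`monotonicity_violations`), and none
are observed under the default conditions.

Initialization is Uniform(0,1)·mean(X) per entry, drawn keyed to sorted
gene ids so results are invariant to input row order (up to float
summation order); 30 restarts by default, best final divergence wins;
convergence when the relative divergence change per step falls below 1e-6
(max 2000 iterations).

Scale identification: (W D, D⁻¹H) fit identically for diagonal D > 0, so W
columns are rescaled to unit sum with the inverse absorbed into H (WH
exactly preserved), after which reported proportions are the per-column
simplex normalization of H and W is rescaled back to intensity units by
the median per-sample H column sum. The per-column normalization touches
only the reported proportions, not the fit.

A direction check warns when a provided marker's fitted fold-change
direction contradicts its component assignment; markers of inconsistent
direction are a known limitation of the approach and are never
auto-corrected.

## Gene filtering and ranking (`mph.filtering`)

Genes entering the decomposition are those separating two experimental
conditions by a two-sided two-sample t-test at raw p < 0.05 (Welch by
default — safer for microarray-scale groups of three — with a
pooled-variance option; zero-variance equal-mean genes get p = 1, never
NaN). No multiple-testing correction by default, since the workflow treats
the filter as a screening step; a BH-FDR flag exists. Marker candidates
are ranked by symmetric fold change max(a,b)/min(a,b) between two profile
columns on linear scale with a 1e-6 pseudocount, ties broken
lexicographically for reproducibility. The candidate list is input to
manual curation; selecting which candidates are biologically meaningful
markers is deliberately outside the code (the pipeline halts at this point
unless an automatic top-n selection is requested for testing).

## Heterogeneity test (`mph.hettest`)

Nested comparison of the homogeneous model (T = 1: per-condition gene
means, the Gaussian MLE) against the T-component mixture fitted by the
marker-guided factorization, both scored by the Gaussian likelihood with
each gene's variance profiled at its residual MSE. The factorization is a
point fit under a different loss and its family does not strictly contain
every homogeneous fit once markers are clamped, so the H1 likelihood is
taken as the better of the factorization fit and the null fit; this
restores nesting (statistic ≥ 0) at the cost of an atom at 0, making the
test conservative at worst.

The chi-square reference (df = (T−1)(I+J)) is advisory only — NMF-style
fits have no clean asymptotic df. The decision basis is a parametric
bootstrap, with one refinement that matters at small J: per-gene variance
estimates from few samples are far more dispersed across genes than the
true variances, and simulating from them systematically shrinks the
bootstrap null statistic (making the naive test anti-conservative, ~2× at
the 5% level with J = 6). Since the model itself takes precisions as
Gamma-distributed across genes, the bootstrap moment-matches that prior
from the per-gene sums of squared residuals and draws each bootstrap
gene's precision from its Gamma posterior (an empirical-Bayes hierarchical
bootstrap). Measured type-I error under the default synthetic conditions
is ≈ 0.02–0.03 at nominal 0.05 — slightly conservative — with 100% power
against the default strong mixture. Bootstrap noise is drawn keyed to
sorted gene ids, so the bootstrap p-value is invariant to input row order.

## Synthetic data (`mph.simulate`)

The generator draws directly from the model above, so every stage has
ground truth. Defaults define the study conditions used throughout the
tests: I=500 genes, J=6 samples, T=2 subpopulations mixed
(0.7,0.3)/(0.3,0.7) in alternating samples, 12 markers per subpopulation
planted at 10 (own component) versus 0.5 (others), background profile
entries Uniform(1,10) — keeping fold changes between profiles realistic —
and lambda_i ~ Gamma(shape 2, rate 0.5), i.e. per-gene noise sd roughly
0.7–2.5 against intensities 1–10. Negative simulated intensities are
clipped to 0; the count is recorded and is <1% under defaults.
`simulate_null` keeps the designated marker gene ids but draws a single
background profile per condition: the null has no planted contrast and no
mixing, which is what test calibration requires.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, count noise of RNA-seq, correlated genes, or markers whose
expression contrast is condition-dependent. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
performance on any particular real platform.

## Marker-count robustness (`mph.sensitivity`)

`sensitivity_scan` subsamples the marker lists at a grid of sizes, refits
on each subsample, and reports per count the maximum over samples of the
across-replicate standard deviation of the first component's estimated
proportion (one interpretable stability scalar), plus each subsample's
mean marker fold change against its deviation from the full-marker
reference. Each replicate draws its own subsample and fit seed, so at the
full marker count the dispersion isolates run-to-run variability of the
fit itself. On the default conditions dispersion falls monotonically with
marker count (≈0.03 at 3 markers, ≈0 at 12), supporting the rule of thumb
that 10–12 markers per subpopulation suffice for stable percentages.

## Pipeline (`mph.pipeline`)

filter → Bayesian deconvolution (uniform prior) → fold-change candidate
ranking → curated marker GMT (human-in-the-loop halt; `auto_markers` takes
the top candidates per direction for testing) → marker-guided
factorization → per-condition heterogeneity LRT → new-marker ranking on
the fitted profiles with input markers excluded. Every stage writes TSV
artifacts plus a JSON manifest (config echo, hash, seeds, stage wall
times); completed stages are skipped on resume, and reruns with identical
config and seeds are bit-identical. The candidate ranking uses the
across-condition mean of the aligned posterior-mean profiles, giving one
ranked list for curation. The default factorization gene scope is the
union of marker and filtered genes.

## Numerical and validation choices

* All randomness flows through `numpy.random.Generator` seeded explicitly;
  derived seeds come from `SeedSequence.spawn`.
* Expression values are linear-scale nonnegative; an explicit `unlog`
  (2^x) is applied only on request, never auto-detected (the KL functional
  is undefined for negative entries).
* Validation errors always name the offending identifier or cell.
* The validation harness (`mph.evaluation`, driven by
  `scripts/acceptance.py` and `tests/test_acceptance.py`) re-runs the
  estimators on freshly simulated ground truth: kernel checks against
  independent straight-loop oracles (50 random 200×12 matrices × 200
  update steps; 100 random likelihood instances), 20-replicate
  factorization recovery, a 2000-iteration sampler recovery with
  bit-identical rerun, LRT calibration over 100 null datasets × 200
  bootstrap draws and power over 20 mixtures, a marker-count scan at
  {3,6,9,12} × 10 replicates, and a triple pipeline run (rerun + resume)
  compared file-by-file. Problem sizes were chosen so the whole harness
  completes in a couple of minutes on one CPU.

## Known limitations

* The Bayesian stage's proportions are identified only up to the mixing
  ridge; accuracy beyond ~0.02–0.05 per entry should not be expected from
  stage 1 alone, and its role in the workflow is structure discovery, not
  final proportions.
* The LRT is approximate twice over (point fit in H1, bootstrap under an
  estimated null) and slightly conservative at J = 6.
* T > 2 is supported throughout (general simplex machinery) but the
  default tuning targets T = 2; three-component runs should revisit the
  marker counts and chain length.
* No RNA-seq count model; inputs are treated as continuous nonnegative
  intensities.
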