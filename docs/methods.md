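# Methods

## Model and estimator

Every dataset is a samples × variables matrix (m × n, typically m ≪ n).
After per-variable z-scoring (mean 0, sd 1 with the m−1 denominator) the
dataset is treated as zero-mean Gaussian, so its distribution is fully
described by its correlation matrix. Because m ≪ n that matrix is rank
deficient; it is modelled as low-rank plus isotropic noise,
Σ = P Λ Pᵀ + σ I, estimated by truncated PCA from the thin SVD of the
standardized matrix (the n × n covariance is never materialized; cost
O(m²n)).

Component count: c is the smallest integer whose leading covariance
eigenvalues sum to at least α·n (ties included; eigenvalues below 1e−10
are treated as numerical zeros and never retained; if the positive
spectrum never reaches α·n, all positive eigenvalues are kept). The
retained eigenvalues are then rescaled by a single constant to sum to
exactly α·n, and σ = 1 − α. Two conventions deserve a note:

- **Normalization target α·n, not α.** The eigenvalue sum is normalized
  to α·n, reading the compression level as a *per-variable* variance
  fraction. This is the only convention under which the divergence of a
  representation with itself is exactly zero and the orthogonal-subspace
  maximum is α·n/(1−α); both identities are asserted in tests.
- **m−1 denominator.** The standard deviation and covariance use the
  unbiased denominator. The choice is immaterial to the divergence —
  any global eigenvalue rescaling is undone by the α·n renormalization —
  but it keeps z-scored columns at sd exactly 1 under re-standardization
  (idempotence, tested).

The divergence between two compressed representations with a shared α is

c-SKL(Σ_P, Σ_Q) = 1/(2(1−α)) [2αn − Σᵢⱼ λᵢ^P (Pᵢ·Qⱼ)² − Σᵢⱼ λⱼ^Q (Pᵢ·Qⱼ)²],

computed from the c_P × c_Q cross-projection matrix G = PᵀQ. The second
double sum weights each Q-eigenvalue by its own projection column (the
symmetric reading; it is the only one that makes the expression
symmetric in P and Q and zero at P = Q, and it matches the coefficient
λᵢ^P + λⱼ^Q of the explanation objective). Values in (−1e−6, 0) —
floating-point residue of the normalization — are clamped to zero;
anything more negative raises, since it indicates a violated upstream
invariant. A single α for the whole collection makes all pairwise values
comparable; α = 0.5 is the default operating point, supported by the
sibling-split validation below, and representations can be computed once
and cached (`save_representation` / `load_representation`).

The exact symmetric KL for zero-mean Gaussians,
½·tr(Σ_P⁻¹Σ_Q + Σ_Q⁻¹Σ_P) − n, is provided as `exact_skl_gaussian` for
small-n testing only. The compressed estimator tracks it faithfully when
the data's true structure is low-rank with an isotropic noise share
matching 1 − α (the estimator's σ ≈ σ_P ≈ σ_Q assumption); the test
suite verifies Spearman ≥ 0.9 in exactly that regime (n=5, m=500,
α=0.99, noise share 0.01). Outside it — e.g. generic full-rank
correlation matrices where c reaches n — the estimator degenerates
(square orthogonal G makes the bracket identically zero), which is the
expected behaviour of a subspace-overlap statistic, not a defect.

## Significance

Tested hypothesis: the pair is more similar to each other than either
member is to the *pooled background* J (all standardized profiles on the
platform). Exact equality of distributions is deliberately not tested —
two independent studies never sample identical populations. For each of
B iterations (default 199) a pseudo-dataset is drawn uniformly without
replacement from the pool, re-standardized, compressed at the same α,
and its divergence to each member recorded. Choices the literature
leaves open, surfaced as configuration:

- **Draw size**: the mean of the two datasets' sample counts
  (`mean_of_pair`, default) or each side's own count (`per_side`).
- **Exclusion**: draws for side P exclude P's own profiles (so a null
  draw cannot partially reproduce the dataset under test) but not Q's.
- **Combination**: p = max(p_P, p_Q), the intersection–union test for
  the conjunctive alternative; conservative by construction.

Each one-sided p uses the add-one correction, so p ≥ 1/(B+1). BH
q-values (statsmodels) are computed across all pairs of a platform and
thresholded at q < 0.05.

Calibration note: under unrelated *structured* datasets the null
p-values are strongly conservative (they concentrate near 1), because a
pooled mixture draw has a broad, diffuse principal subspace that
overlaps any single study's axes more than an independent structured
study does. The test is therefore a relative-similarity screen with
conservative error control, not a uniformly calibrated test; even in the
exchangeable regime the max-combination keeps p stochastically above
uniform. Power is unaffected where it matters: pairs sharing planted
structure reach the minimal attainable p. When interpreting q-values,
note the p floor 1/(B+1): with k true links among N tested pairs, the
smallest achievable q is N/(k(B+1)), so B (and the number of pairs
tested jointly) bounds the attainable significance.

## Explanation

The restricted objective replaces the cross-projections with
Pᵀ diag(S) Q for a 0/1 selector S with k ones; coefficients
C_ij = λᵢ^P + λⱼ^Q. B(k) minimizes it (the variables through which the
two covariances agree most), W(k) maximizes it. The solver alternates on
the bilinear relaxation: with one selector fixed the objective is linear
in the other, solved by a top-k (bottom-k for W) of per-variable
coefficients; each step is optimal given the other selector, so the
bilinear value is monotone along iterations (recorded in the result's
trace and asserted in tests). Determinism and robustness:

- start from the top-k of the unary score Σᵢⱼ C_ij (P_vi Q_vj)², plus 3
  seeded random restarts by default (more help on small, rugged
  instances: the exhaustive-search test uses 10);
- ties in the top-k break by coefficient then ascending variable index;
- convergence on a repeated selector; a period-2 cycle returns the
  better of its two selectors; iteration cap 100.

Set explanations optimize the summed objective over several pairs by
summing the per-variable coefficients; the reported objective is the sum
of the pairwise restricted objectives. Recovery at desk scale: on
fixtures with a planted shared factor over s variables, B(s) recovers
≥ 80% of the planted set; on instances small enough for exhaustive
search (n=12, k=3) the alternating solution matches the global optimum
on ≥ 90% of instances and never beats it.

## Networks

Significant pairs become edges of a per-platform dataset graph
(attributes cskl, p, q). Edge significance ranking — for `top_edges`
views — is ascending q, then ascending c-SKL, then lexicographic IDs.
Disease networks count, for each unordered label pair, the significant
cross-disease dataset pairs supporting it; within-disease and unlabeled
edges are dropped (the latter logged), edges below `min_weight` removed.
Merging across platforms sums weights; no variable alignment is needed
at the label level. One label per dataset (first wins, with a warning).
GraphML export preserves attribute types and round-trips losslessly.

## Sibling-split validation

Every dataset is randomly partitioned over samples into two halves
(⌈m/2⌉/⌊m/2⌋); each half is re-standardized on its own samples (its own
means and sds — standardization is a per-dataset operation), compressed,
and ranked against all other halves. The recovery fraction is the share
of halves whose nearest neighbor is their sibling; ties break by dataset
ID. On the standard synthetic collection the recovery is 100% at
α = 0.5 and is robust across the sweep {0.3, 0.5, 0.7}.

## Synthetic collections

The generator realizes the model class the estimator assumes: zero-mean
Gaussian samples with covariance L Lᵀ + σ²I, loadings optionally
restricted to an *active* variable subset. Defaults, chosen once as the
desk-scale study conditions:

| parameter | default | rationale |
|---|---|---|
| variables n | 500 | keeps m ≪ n while running in seconds |
| planted rank | 5 | a handful of dominant biological factors |
| structured variance | 60% of total | strong but not noise-free structure |
| noise variance | 1.0 per variable | unit scale; standardization removes it anyway |
| samples m | 60 | the low end of real study sizes |
| groups × datasets | 4 × 5 | enough pairs for FDR behaviour |
| loading jitter | 0.5 (relative) | see below |

Group members share the group covariance up to a per-dataset loading
jitter: Gaussian perturbation of the active rows at 0.5× the RMS loading
scale, renormalized to preserve the structured-variance split, i.e. the
jitter rotates factor directions without changing signal strength. The
value sits deliberately between two regimes that the collection must
separate: datasets within a group must remain far more similar to each
other than to other groups (at the defaults, mean within-group c-SKL
≈ 253 vs ≈ 496 between, bound 500), yet every dataset must be a distinct
distribution so that a dataset's own sibling half — not a group mate —
is its nearest neighbor (recovery 1.0 at the defaults; at jitter 0.3
group mates become near-indistinguishable at half-size and recovery
drops to ≈ 0.78, and at jitter 0 it collapses toward chance, which the
suite asserts). Cross-links append one shared factor, supported on a
stated variable subset and carrying a stated fraction of total variance,
to both groups' loadings — the ground truth for cross-disease edges and
explanation recovery.

What the generator does *not* emulate: platform-specific intensity
distributions, batch effects, missing values, probe-level annotation, or
heavy-tailed non-Gaussian expression noise. Passing tests demonstrate
correct behaviour of the statistics under their own model assumptions,
not robustness to those real-data complications.

## Numerical and degenerate-input conventions

- Zero-variance variables have no z-score; they are dropped with a
  warning by default (or raise, per policy).
- Constant datasets (all eigenvalues zero) raise rather than return a
  degenerate representation.
- Missing or non-numeric entries are load-time errors; no imputation.
- Bootstrap pseudo-datasets with an (astronomically unlikely) constant
  column keep the column as zeros instead of dividing by zero.
- Problem sizes in the test suite (n = 100–500, m = 40–60, B = 99–199,
  200 null pairs) are the package's desk-scale study conditions; all
  statistics they exercise are size-free fractions, ranks or error
  rates.
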