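# Methods

## Model

The premise is that genes with similar expression profiles are likely to
interact. Rather than thresholding a pairwise distance, each pathway
gene is regressed on every gene outside both pathways at once, and
"neighbor" is defined by support in a sparse model: the predictors that
*jointly* explain the gene's profile, not merely correlate with it.

For pathway gene aᵢ with z-scored profile yᵢ over T samples and the
pool design X (T × |Π|, columns z-scored upstream, not re-standardized
by the solver), the elastic net is solved with an intercept over a
penalty-strength path

    f(ω, b; s) = ‖yᵢ − Xω − b‖²/(2T) + s·( λ‖ω‖₁ + (1−λ)/2 ‖ω‖₂² ).

The mixing λ balances sparsity (ℓ1) against the grouping/stability of
correlated predictors (ℓ2); with λ = 1 (pure lasso) at most T
predictors can be selected, which is why a mixed penalty (default
λ = 0.5) is used when |Π| ≫ T. A plain penalized objective with unit
strength has no way to realize a fit target, so the strength s sweeps a
geometric grid of `n_penalties` = 100 values from

    s_max = max_j |x_jᵀ(y − ȳ)| / (T·λ)

(the smallest strength whose unique solution is identically zero — the
path's all-zero start) down to `s_max · penalty_ratio` (ratio 10⁻³).

### Model selection: the variance-explained target

For each modeled gene the reported coefficients are those of the
**largest** penalty whose training variance explained, 1 − RSS/TSS,
reaches `variance_target` (default 0.75) — i.e. the *sparsest*
qualifying model, consistent with sparsity being the method's premise.
The alternative reading (densest/best-fitting qualifying model) is one
`select_coefficients` call away since the full path is retained. If no
path point reaches the target the densest model is used and flagged
(`met_target=False` on its edges) rather than dropping the gene, which
would silently shrink Γ; downstream consumers can filter on the flag.
This fallback fires routinely for knockout conditions, where a gene
whose driver was ablated is genuinely unpredictable — its fallback
neighbors are overfit noise, which is precisely why the per-condition
*shared* sets (an intersection) and the Venn set algebra, not raw Γ
sets, are the quantities compared across conditions.

### Solver and numerics

Coordinate descent (scikit-learn's path solver) with convergence
tolerance 10⁻⁹ and warm starts along the grid. Solutions are verified
in the test suite against the subgradient stationarity conditions of
f: for active coordinates x_jᵀr/T = s(λ·sign ω_j + (1−λ)ω_j), for
inactive ones |x_jᵀr/T| ≤ sλ, to within 10⁻⁶ (observed residuals
~10⁻⁹), and against closed forms on orthonormal designs,
soft-threshold shrinkage ω_j = S(x_jᵀy/T, sλ)/(1 + s(1−λ)). Neighbor
calling uses |ω_j| > `zero_tol` = 10⁻¹⁰, separating solver-exact zeros
from numerically tiny coefficients. Training variance explained of the
all-zero model is set to exactly 0. Within a pathway run, the path for
each gene is solved in warm-started chunks and stops at the first
target crossing; this is an exact shortcut (same grid, same solutions,
and selection never inspects later points), asserted against the full
path in tests. The whole core is deterministic — identical inputs give
bit-identical neighbor sets.

## Preprocessing conventions

* Dynamic-gene filter: keep a gene iff in ≥ 1 condition max > `floor`
  (5, FPKM scale) and max > `fold`·min (fold 2). Strict inequalities;
  the product form is well defined at min = 0 with no pseudocount.
* Z-scoring uses sample sd (denominator T−1); population vs sample sd
  is not identifiable from the workflow being emulated, so one
  convention is fixed and tested (idempotence to 10⁻⁸). Zero-variance
  genes must be dropped first (helper provided, logs a warning).
* Upper-quartile count normalization divides each sample by the 75th
  percentile — linear interpolation between order statistics at
  position 0.75·(n−1), the common statistical-software default — of
  that sample's non-zero counts. Zeros stay zero; the result is
  invariant to per-sample count scaling.

## Correlation-distance baseline

d(p, a) = 1 − r with signed Pearson r by default ("correlation
distance" in its most common sense); p is a neighbor of χ iff
min over a ∈ χ of d ≤ μ (default 0.1, i.e. r ≥ 0.9). Spearman and an
absolute-value variant (d = 1 − |r|) are flags. The baseline emits the
same result type as the elastic net so the comparison downstream is
mechanical. Note the signed default deliberately misses perfect
anti-correlation (d = 2).

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per term, with the
predictor pool Π as background — the test asks "enriched among called
neighbors relative to the genes eligible to be called", not relative to
the genome. Term sets are intersected with the background; zero-overlap
terms are kept so the FDR denominator is reproducible. FDR is
Benjamini–Hochberg (the specific procedure behind reported "FDR" values
in this literature is rarely stated; BH is the documented stand-in).

## Synthetic worlds and what a green test establishes

The generator plants: two latent activity signals z₁ ⊥ z₂ (unit
variance; a smooth random spline over ordered samples emulating a
time course, or an AR(1) with persistence 0.8 emulating population
samples); pathway-k genes = loading·z_k + N(0, noise_sd²);
intermediaries loading on one signal (loading·z_k) or on both
(loading·(z₁+z₂)/√2); and independent N(0,1) noise genes. Knockouts
abolish a signal *per gene*: every occurrence of the ablated z_k in a
gene's construction is replaced by a fresh independent normal vector,
so the coordinated activity collapses (keeping one common replacement
vector would leave the co-expression intact and make the knockout
undetectable). Each condition is an independent sample set. Defaults:
T = 30, 10+10 pathway genes, 15 both-signal and 5+5 single-signal
intermediaries, 300 noise genes, loading 1, noise_sd 0.25, seed 1.

Known structural limits of this world, which the test suite documents
rather than hides:

* A gene loading equally on two orthogonal signals correlates at most
  √2/2 ≈ 0.707 with either pathway's genes, so the correlation
  baseline at μ = 0.1 can *never* call it — by construction, not by
  implementation fault.
* The single-signal intermediaries are (near-)copies of the pathway
  genes they share a signal with. They saturate the 75% variance
  target before the weaker both-signal predictors activate (KKT entry
  analysis: at the target crossing the residual correlation of a
  both-signal gene, ≈ 0.35, is below the activation threshold
  s·λ ≈ 0.45), so the elastic net's shared set misses the planted
  both-signal intermediaries whenever stronger single-signal
  predictors exist. Recovery of the *single-signal* intermediaries in
  Γ, and their branch localization via enrichment, is the reliable
  readout (see the README example).
* Because a single-signal intermediary is never a neighbor of the
  other pathway, it does not enter the per-condition shared sets, and
  knockout Venn regions over shared sets cannot localize it; regions
  over Γ sets or enrichment of Γ differences can.

The generator does not simulate read-count (negative-binomial) noise,
library-size artifacts, batch effects, or gene-gene interactions beyond
the two-signal linear structure; a green recovery test establishes
correctness of the pipeline's mechanics on linear co-expression
structure, not performance on real RNA-Seq.

## Recovery scoring

`evaluate_recovery` reports precision/recall/F1 with explicit empty-set
conventions: empty prediction has precision 1 against an empty truth
set and 0 otherwise; recall of an empty truth set is 1.

## Condition comparison

Venn regions are keyed by canonical membership signatures built from
the user's condition names (sorted members ∩-joined, then \-separated
non-members), with accessors for "in A and B but not C" and "only A".
Disjointness and coverage of the union are asserted on every
construction.
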