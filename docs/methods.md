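# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Clone extraction

Reads are kept when both mates have mean phred ≥ 30 (mean over all bases of
the mate).  The sgRNA is the 20-nt window at offsets 24–43 — read as 1-based
inclusive positions after the last base of the invariant forward anchor
`TCTTGTGGAAAGGACGAAACACCG`; this convention is what yields exactly the guide
length.  Anchor matching is exact and the first occurrence wins; the
mismatch tolerance (default 1, up to 3) applies only to guide and UMI
matching.  A window matching two library guides at the same smallest
distance is discarded rather than assigned.  The UMI is the leftmost 27-nt
window inside the 50-nt region after the reverse anchor
`AGCCTCACTGGCCGTCGTTTTACA` whose fixed positions match the
reverse-complement template (S positions accept C/G) exactly, else within
the mismatch budget; it is stored reverse-complemented to forward
orientation, verbatim, including any mismatched fixed positions — the
directional merge downstream absorbs such errors.

Extracted reads are downsampled to at most 2×10⁶ (uniform, without
replacement, seeded) before tallying clones, so deeply sequenced samples are
not rewarded with spurious extra clones.

Directional merging operates per guide on the pre-merge counts: nodes are
UMI clones, edges connect pairs at Hamming distance exactly 1 with
nₐ > 2n_b − 1 (nₐ the larger), and each connected component collapses in one
pass to a single clone carrying the summed count and the UMI of its largest
member (ties broken to the lexicographically smallest UMI, for determinism).
Edges are not recomputed iteratively from merged counts.  Total reads are
conserved by construction.

## Diversity

"Per million reads" is realized as one seeded multivariate-hypergeometric
subsample to 10⁶ reads, not a linear rescaling: under heavy-tailed clone
sizes the clone count is far from proportional to depth.  The Shannon index
uses natural logs (values near ln of the clone count).  The Lorenz curve
sorts clones ascending and reports the trapezoidal area under the cumulative
read share, so 0.5 means perfectly even clones and smaller values mean
heavier tails; the orientation is the classic one and only the deviation
from the diagonal carries meaning.

## The hierarchical fitness model

Per guide t (with plasmid count I_t > 0; guides with I_t = 0 are excluded
with a warning, as fitness is undefined without initial representation) and
replicate j:

* library proportions: plug-in π_t = I_t / Σ I;
* clone counts: K^j_t ~ Poisson(c_j · π_t · ε_t);
* clone sizes: iid zero-truncated counts from the chosen family with the
  guide scale φ_t on the location parameters (negative-binomial component
  means φ_t μ_{j,c}; Poisson mean; BNB size n; for Yule–Simon, which has no
  scale parameter and possibly no mean, the guide factor acts inversely on
  the shape, ρ_t = ρ_j / φ_t, the only monotone handle that family offers);
* priors: log φ_t ~ N(0, τ_φ²), log ε_t ~ N(0, τ_ε²), τ ~ half-Normal(1)
  (configurable scale); sample nuisances (log c_j, family parameters) get
  weak Normal priors on the log scale (sd 5; sd 20 for log c); mixture
  weights are Beta(1, 1); `mix_bnb_local` carries one weight per guide.

Fitness per posterior draw is f_t = ε_t · W_t with W_t the winsorized mean
of the fitted guide distribution — the top `winsor_upper_fraction` (default
2%) of the distribution revalued to its upper quantile q, the smallest
integer with CDF ≥ 0.98 (discrete distributions have no exact centile, so
the conservative integer quantile is used deterministically).  Winsorization
acts on the fitted distribution per draw, not on the raw data.  In grouped
fits φ_t, ε_t and the τ's are shared; W_t averages the per-dataset
winsorized means weighted by dataset clone totals.

For NB-based families W_t is evaluated in closed form: integer bisection on
the mixture CDF for q plus the partial-expectation identity
Σ_{k≤q} k·f(k; r, p) = μ·F(q−1; r+1, p), vectorized over draws and guides.
The beta-negative-binomial pmf is evaluated directly from gamma/beta
log-functions (the textbook form is defined for real size n, which the
guide-scaled hierarchy requires), and in the hierarchical fit its first
shape is parametrized a = 1 + eᵃ′ so the law always has a finite mean; W_t
then comes from an explicit pmf grid bounded by the Markov bound
q ≤ mean/fraction, on thinned draws (`slow_w_draws`).  The Yule–Simon
winsorized mean uses the tail-sum identity W = Σ_{j<q} sf(j) with the
closed-form survival sf(j) = j·B(j, ρ+1), summed exactly to 4096 terms and
continued with the power-law asymptote beyond (relative error below 10⁻³),
so heavy tails never require large grids.  Infinite-mean BNB laws remain
available through the public pmf menu; the generic winsorized-mean routine
carries a 2²⁴ support cap and raises rather than grinding on a tail it
cannot sum.

### Sampling

No probabilistic-programming backend is used; the sampler is an adaptive
Metropolis-within-Gibbs on log parameters: vectorized elementwise updates
for ε_t and φ_t (valid because guides are conditionally independent given
the sample-level block), a joint random-walk block per sample
(family parameters + log c_j), scalar updates for the τ's, and two
scale-decorrelation moves along the likelihood-invariant directions
(φ ↓, component means ↑; ε ↓, c ↑) that break the multiplicative
non-identifiability which otherwise throttles mixing.  Step sizes adapt by
Robbins–Monro during warmup only (targets 0.44 elementwise, 0.28 joint).
Clone-size likelihoods are evaluated on per-guide unique-value/weight
compressions.  Defaults: 4 chains, 1000 warmup + 1000 draws; convergence is
split-chain R-hat on the fitness draws, and a fit with R-hat > 1.05 on more
than 5% of guides is flagged `converged=False` rather than silently
returned.

### Goodness of fit

The GOF statistic is a posterior-predictive check: per posterior draw, a
replicate dataset (K^j_t clone sizes per guide from the fitted distribution)
is simulated and its per-guide mean recorded; coverage is the percentage of
guides whose observed mean clone size falls in the equal-tailed 90% interval
of these replicate means.  The parameter-mean interval alone would be far
too narrow — it shrinks with the pooled data while observed guide means
carry their own sampling noise — so only the predictive reading makes ≈90%
the well-specified benchmark.  Like all posterior-predictive checks that
reuse the data, it is mildly conservative (observed coverages typically
90–95 under the truth).

A caveat discovered while validating: because every likelihood family
carries the free per-guide scale φ_t, even a badly misspecified family
(zero-truncated Poisson on heavy-tailed sizes) can track each guide's
observed mean, so misspecification surfaces as over-coverage (≈100%, an
over-adaptive, underdispersed predictive) rather than under-coverage.
Family comparison should therefore lean on the marginal likelihood
(stepping-stone estimator below), which ranks mix-NB far above Poisson on
heavy-tailed data, consistent with mix-NB being the working model.

### Marginal likelihood

`log_marginal_likelihood` is a stepping-stone estimate over power posteriors
with a cubic temperature ladder β_s = (s/S)³ and one adaptive random-walk
chain per rung.  The reported MC standard error sums per-rung delta-method
variances under an independence approximation and is optimistic when chains
mix slowly; the estimator is intended for small-guide-set family comparison,
not for publication-grade Bayes factors.  The generic routine is validated
against the closed-form Poisson–gamma marginal.

## Frequentist comparator

The delta-method estimate is (S_t/I_t)/Z with S_t the per-guide sum of clone
sizes winsorized at the empirical 98th centile (linear-interpolation
quantile) and Z the 70th centile of targeting-guide ratios.  Variance:
Var(S_t) ≈ winsorized sample variance × K_t, Var(I_t) = I_t (Poisson),
first-order expansion of the ratio; the 95% CI is symmetric on the log scale
to respect positivity.  Note the 1/I_t term puts a floor under the relative
CI width that does not shrink with clone number.  Guides with zero clones
get estimate 0 and a flagged one-sided interval.

## Normalization, calls, comparisons

Normalization divides all draws by the 70th centile (linear interpolation)
of the targeting-guide posterior medians, so that centile becomes the
neutral level 1; controls are rescaled but never enter the scalar, and the
operation is idempotent.  Neutrality p-values are posterior tail masses,
p_t = 2·min(Pr(f_t ≤ 1), Pr(f_t ≥ 1)), floored at 1/#draws, BH-adjusted
across targeting guides only (controls are reported unadjusted).

Between two screens, draws are paired by index (chains are independent, so
draw order is an arbitrary but seed-stable pairing).  Criteria: (c1) the
95% equal-tailed interval of the normalized fitness differential excludes 0;
(c2) the guide's median differential lies outside the central 95% empirical
range of the control-guide median differentials — a distribution-free
operationalization of "significant relative to the variability in neutral
guides" using the designed controls (fewer than 5 controls degrades the
comparison and disables c2); (c3) the 95% interval of the rank differential
(ranks computed within each dataset per draw) excludes 0.  A gene is an
outlier when at least two of its guides pass c1 ∧ c2 ∧ c3.

The fitness partial order connects guides a → b when hi95(a) < lo95(b);
the Hasse diagram is the transitive reduction (networkx) of this strict
interval order, which is acyclic by construction, and the resolved-pair
count is the size of the unreduced relation.

Percentile convention everywhere: linear interpolation between order
statistics.

## Synthetic screens

The generator emulates the screen's statistical structure, not its biology:

* plasmid skew: log-normal proportions with σ = 0.55, giving a 90th/10th
  guide-count ratio in the 3–5 range typical of pooled cloning;
* bottleneck: K_t ~ Poisson(B · T · π_t · ε*_t) with B the clones-per-guide
  baseline (default 500);
* sizes: zero-truncated mix-NB, component means (5, 60), dispersions
  (1.0, 0.25), weight 0.3 on the small component.  The small-component
  dispersion 1 matches a modestly overdispersed population of small clones;
  the large component's dispersion 0.25 is what lets ~10⁵ clones span 3–4
  orders of magnitude, as transplant tumours do — with both dispersions at 1
  the NB tail is too light by about a factor of three at the maximum;
* optional FASTQ with fixed pads around the real anchors, constant phred 37,
  and per-base substitution errors confined to the UMI.

True fitness in the truth table is ε*_t times the winsorized mean of the
scaled size family — the same functional the model estimates.  Everything is
reproducible from the single config seed, byte-identically.

What the generator does **not** emulate: PCR amplification noise and
chimeras, guide-sequence errors beyond the mismatch budget, clone-size
correlations between guides sharing a tumour microenvironment, multiple
viral integrations per cell (the model assumes single infection), and
contamination between samples.  Passing tests therefore demonstrate
correctness of the inference under the model's own assumptions and
robustness to UMI-level sequencing error, not robustness to every artifact
of real amplicon data.

## Problem sizes and calibration experiments

The calibration experiments are desk-scale by design: goodness-of-fit uses
200 guides at 300–500 clones/guide with 2 chains of 900 warmup + 500 draws
(coverage lands at 90–95 under the truth); the false-discovery experiment
uses 200 (60 in the quick suite) all-neutral screens of 60 guides × ~30
clones fitted with the single-NB family, where the hierarchical shrinkage
makes BH calls conservative (mean false-discovery proportion well under
0.05); parameter-recovery uses ~500 clones/guide, where the posterior
median rank-correlates with truth at ρ ≥ 0.9.  Larger problems change
runtime, not code paths.

## Known limitations

* The sampler is a random-walk scheme; posteriors with thousands of guides
  or strongly multimodal mixture likelihoods will need longer chains than
  the defaults and should be checked via the R-hat flag.
* Mixture component labels are not identified; all reported functionals
  (winsorized mean, fitness, GOF) are label-symmetric, so this is harmless,
  but raw component parameters should not be interpreted individually.
* The stepping-stone SE underestimates when rung chains autocorrelate.
* BNB and Yule–Simon winsorized means are computed on thinned draws for
  speed; their fitness draws are correspondingly coarser.
* The frequentist comparator treats I_t as Poisson; a multinomial treatment
  would couple guides and was not pursued.
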