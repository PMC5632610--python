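# Methods

This note records the statistical conventions, parameter choices and known
limitations of the package. Nothing here reports an empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

The unit of analysis is the **genus-level taxon**: a named clade of
roughly genus rank sitting at a tip of the phylogeny. From a species-level
host-record table (moth species, genus-level taxon, host plant family,
host plant order) we derive per taxon:

- **host diversity (HD)** — the number of distinct plant orders recorded
  across all the taxon's species, a proxy for cumulative past and present
  host breadth;
- **maximum polyphagy** — the largest number of distinct orders recorded
  for any single species;
- binary codings **"3+ orders"** / **"7+ orders"** — whether any single
  species reaches that polyphagy level;
- **species richness (R)** — supplied externally, since counting described
  species is editorial work.

Records are de-duplicated on the (species, order) pair; order names are
matched case-insensitively after trimming, with no synonym resolution.
Non-angiosperm host orders count toward HD like any other. Records lacking
an order assignment are rejected at load time rather than silently dropped
or up-mapped.

## Phylogenetic signal (Mk rate + permutation)

Binary traits are modelled by the symmetric two-state Markov chain with a
single rate q per unit branch length; along a branch of length t,
P_switch = (1 − e^(−2qt))/2. Likelihoods use Felsenstein pruning with a
flat (½, ½) root prior — for the ER model the flat prior equals the
stationary distribution, so the choice is inert. Missing tip states enter
as partial likelihood (1, 1) rather than tip deletion, keeping the tip set
fixed under permutation.

**Optimisation.** The rate is profiled on a copy of the tree rescaled to
unit depth, with bounds q ∈ [10⁻⁸, 10³] (conditioning), by a coarse
log-spaced grid bracket followed by golden-section refinement; results are
mapped back to the original branch-length scale. The same estimator is
applied to observed and permuted data, so the permutation comparison is
method-consistent. The estimator agrees with an independent ML
implementation (`ape::ace`, ER model) to seven significant digits on test
datasets, and with a 10⁻⁴ grid search to within grid spacing.

**Permutation test.** Tip states are shuffled over observed tips (state
counts preserved) and the rate refitted; p is the raw fraction of permuted
rates ≤ the observed rate, ties counted as ≤ (conservative for a low-tail
test). A raw fraction can legitimately print as 0; the (k+1)/(n+1) bound
is exposed alongside. Constant traits short-circuit to p = 1 with a
warning. In batch runs, each trait column receives a sub-seed derived
deterministically from the master seed.

Rates are interpretable only relative to the depth of the tree at hand;
rates fitted on trees with different branch-length units must not be
compared directly.

## Parsimony tracing

Binary characters are traced by unit-cost Sankoff dynamic programming
(postorder costs plus a rerooting pass), which reproduces Fitch's
algorithm exactly on binary trees and remains exact on polytomies; per
node the full set of MPR-compatible states is reported. Host diversity is
traced as a continuous character by squared-change parsimony: internal
values minimise the sum of squared changes over edges (each internal node
at the mean of its neighbours; sparse linear solve). Branch lengths are
ignored by default — the trace is a descriptive visual aid, not a model
fit — with a 1/length-weighted variant behind a flag. Squared-change is
this package's convention for continuous tracing; no claim is made about
what other software draws.

## Sister-clade contrasts

Contrast construction is a deterministic greedy post-order sweep with a
minimum HD difference (default 3 orders; 1 gives the "any sister pair"
variant): at each binary node whose two daughter clades contain no
already-used taxon, the daughters form a candidate; if the HD difference
(computed on the union of host-order sets per side) meets the threshold
the pair is emitted, otherwise the daughters merge at the next ancestor.
Merging proceeds strictly by tree adjacency — never by diversity-sorted
cherry-picking — so pair selection cannot be steered by the outcome
variable. Emitted pairs never share taxa (phylogenetic independence).
Polytomous candidates are skipped with a warning.

Statistics: exact two-tailed binomial sign test on direction (ties
dropped); one-sample t on log10(R1/R2) against zero, reporting mean, SD
and SE separately (note that mean/(SD/√n) is the t statistic — summaries
that print "mean ± SE" while quoting the SD conflate the two); and a
concordance sign test on whether side 1 also holds the most polyphagous
single species. Log base 10 is used for the reported ratio column; the t
statistic is base-invariant.

## Phylogenetic regressions

**PGLS.** Error covariance is the Brownian shared-path-length matrix with
off-diagonals scaled by Pagel's λ ∈ [0, 1]. λ is profiled by full ML
(0.01 grid + bounded refinement); coefficients by GLS at λ̂. R² is defined
as 1 − RSS(model)/RSS(intercept-only), both in the λ̂-whitened coordinates,
and F is the corresponding model comparison with (1, n−2) df. λ = 0
reproduces OLS to machine precision. Both variables are log10-transformed
in the pipeline (slope and R² are base-invariant when both share the
base). Singular covariances (zero-length twin tips at λ = 1) receive a
1e−10 ridge with a warning.

**MacroCAIC.** The predictor trait is propagated by Felsenstein's
weighted-average recursion with branch-length standardisation (verified
against `ape::pic`); at each binary node the response is ln(N1/N2) with N
summed over each daughter clade's richness, oriented so daughter 1 has the
larger reconstructed trait value (trait contrasts thus non-negative). The
regression is forced through the origin (expected response zero under no
effect); df = n_contrasts − 1, with uncentred R² and its through-origin
adjustment. Polytomies are refused by default; an explicit option resolves
them pectinately with zero-length edges.

## Synthetic universes

The generator emulates the statistical structure the analyses assume —
not the taxonomy or the record-collection noise of a real compilation:

- **Tree:** pure-birth (Yule) grown to n tips (default 60, the scale of a
  genus-level compilation), ultrametric, binary.
- **Host diversity:** log breadth evolves by Brownian motion (variance 1.0
  accumulated root-to-tip, root at log 6), exponentiated, rounded, and
  clipped to a 46-order pool; order identities are drawn with rank-skewed
  weights so a handful of orders are widely shared.
- **Maximum polyphagy:** the most polyphagous species receives about 60%
  of the taxon's orders, with scatter controlled by `coupling`
  (default 0.9 gives HD vs max-polyphagy r² ≈ 0.9); leftover orders are
  spread over further species, so re-deriving traits from the emitted
  records reproduces the generator's ledgers exactly.
- **Richness:** log10 R = 0.7 + 0.77·log10 HD + ε with ε multivariate
  normal under the λ-scaled Brownian covariance (λ = 0.70, SD 0.35),
  rounded and floored at 1. The defaults are the empirical point estimates
  for slope and λ; the residual SD was set so the PGLS fit on generated
  data lands near the empirically observed F/R² regime. Correlated (not
  iid) residuals are essential: with iid noise, λ recovery would be
  vacuous.

All generators are bit-reproducible under a fixed seed; experiment drivers
fan per-replicate seeds out of one master seed.

### What passing tests do and do not show

The generator draws host orders independently of the tree given HD, uses a
single richness model with homogeneous diversification, and contains no
record-dropout, misidentification, or taxonomic noise. Calibration and
recovery results therefore validate the statistical machinery under its
own assumptions; they do not certify behaviour under the sampling biases
of real host-record compilations (an optional dropout flag is deliberately
out of scope).

## Numerical conventions

- Rate bounds [10⁻⁸, 10³] on the unit-depth scale; a fitted rate within a
  factor 3 of a bound is flagged (`bounds_hit`).
- Impossible data at q = 0 return −∞, never an exception.
- Permutation tie comparison uses a 10⁻⁹ relative tolerance.
- Missing branch lengths default to 1.0 with a warning (parsimony is
  length-free; Mk and PGLS need lengths).
- Degenerate inputs (constant traits, all-tied contrasts, zero variance)
  raise a dedicated error class, mapped to CLI exit code 3 (input errors
  exit 2).

## Known limitations

- **Permutation-test power at weak clustering.** When a low-rate trait
  leaves only one or two tips in the minority state, the fitted ER rate is
  nearly invariant to where those tips sit (for a singleton the MLE is
  approximately 1/(2·total tree length) regardless of placement), so
  permutation carries no information and those replicates cannot reject.
  At rate 0.1 per unit depth on 100-tip trees roughly a fifth of
  non-constant traits are of this kind, which caps the test's power near
  0.75–0.85 (computed by `analysis/02_signal_calibration.py`). Power
  simulations condition on non-constant traits; constant draws are
  redrawn.
- **ML-λ anticonservatism.** Profiling λ inflates the PGLS F-test's type-I
  error (≈0.10 at n = 40–60 versus ≈0.04 with λ fixed at the generating
  value) — a finite-sample cost of estimating the covariance, worth
  remembering when p-values sit near the threshold.
- **Richness-contrast regression power.** The ln(N1/N2) response is not
  variance-standardised and richness is integer and floored, so the
  MacroCAIC design is substantially noisier than PGLS on identical data
  (its power under the default effect is near 0.7 where PGLS is near 1.0;
  computed by `analysis/05_richness_contrasts.py`). It is retained as the
  robustness check it is meant to be, not as the primary fit.
- **Clade-size confound in sign tests.** When contrast sides contain
  unequal numbers of taxa, the larger side tends to have both more pooled
  host orders and more summed species, biasing the direction of
  multi-taxon contrasts positive even under no effect. Tip-vs-tip
  contrasts are free of this; interpret merged-clade contrasts with care.
- Branch-length units are whatever the input tree carries; no dating or
  calibration is attempted, and rates/λ are only comparable within one
  tree.
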