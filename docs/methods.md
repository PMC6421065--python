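# Methods

This note documents the models, numerical choices and design decisions
behind `divclock`, and what its tests do and do not establish.

## Tree simulation: the conditioned reconstructed process

Chronograms are samples of the reconstructed (extinct-lineage-pruned)
constant-rate birth–death process conditioned jointly on the crown age `t`,
the number of extant tips `n`, and survival of both crown lineages.  With
speciation λ, extinction μ, r = λ − μ and

    g(s) = (1 − e^{−rs}) / (λ − μ e^{−rs}),

the `n − 2` post-root speciation ages are, under this conditioning, i.i.d.
with CDF `F(s) = g(s)/g(t)` on `[0, t]`.  `F` inverts in closed form
(`x = e^{−rs} = (1 − cλ)/(1 − cμ)` at `c = u·g(t)`), so simulation is O(n)
inverse-transform sampling.  The ranked topology of the reconstructed
process is uniform, so the sampled ages are attached by joining two
uniformly chosen extant lineages at each event age, youngest first.  Extinct
lineages are never materialized; only the reconstructed tree is observed by
any downstream stage.  A forward Gillespie simulator with rejection
(`simulate_forward_rejection`) exists solely as a test oracle; the test
suite verifies distributional agreement by two-sample KS at α = 0.01 with
2000 replicates for (n, t) ∈ {(5, 1), (8, 2)} under both models.

Design rates come from the tip-count expectation `E[N_t] = N₀ e^{rt}` with
`N₀ = 2`: r = 0.5051 (n = 25) and r = 0.7824 (n = 100) at crown age 5, with
ε = μ/λ fixed at 0.5 for birth–death generation.  The crown age is treated
as exactly fixed (simulation frameworks that "fix" it by a near-degenerate
prior differ only infinitesimally).

Reproducibility contract: every stochastic function takes a seed; an
experiment derives per-stage, per-replicate generators as
`SeedSequence([root_seed, stage, condition, replicate])`, so any replicate
can be regenerated in isolation and full runs are bit-reproducible.

## Clock models

Lognormal distributions are parameterized throughout by their **real-scale
mean** m and **log-scale standard deviation** σ (log-mean ln m − σ²/2).
Under this convention the branch-rate coefficient of variation is
√(e^{σ²} − 1), which for the low-heterogeneity preset (σ ~ U(0.17, 0.18))
predicts CV ∈ [0.171, 0.182] — inside the empirical bracket
[0.157, 0.1948] this preset is meant to realize, corroborating the
convention.  The strict clock's "mean 0.01, sd 0.5" is read the same way;
the alternative (log-scale mean) reading would only rescale absolute rates,
which the later root-height rescaling removes.

UCLN hyperparameters (m, σ) are drawn once per tree from their uniform
ranges — low (0.17, 0.18), medium (0.25, 1), high (0.25, 1.75), mean bounds
(0.005, 0.015) substitutions/site/time — then one continuous lognormal rate
per branch, i.i.d.  Continuous draws are used rather than the discretized
lognormal of MCMC implementations: with independent per-branch draws the
discretization converges to the continuous law and the continuous form has
closed-form moments for testing.

## Sequence simulation

GTR rate matrix `q_ij = exch_ij π_j`, scaled so the stationary substitution
rate is 1 (branch lengths are expected substitutions/site).  The default
parameter set is a nuclear-rRNA GTR+Γ fit (its published frequencies sum to
1.009 and are renormalized to 1, as sequence simulators conventionally do).
Among-site rate variation in *simulation* is continuous Gamma(α, mean 1);
*inference* uses a 4-category discrete gamma (median rule, renormalized to
mean 1).  The mismatch is deliberate: it mirrors the relationship between
standard simulators and standard inference tools.  Transition matrices come
from the eigendecomposition of the π-symmetrized rate matrix.  Sites are
i.i.d.; no invariant-site class, indels or ambiguity codes.

## The dating surrogate

The package deliberately replaces Bayesian MCMC tree estimation with a
deterministic point-estimate pipeline — this is its single largest departure
from the workflow it emulates:

1. **Topology**: neighbor-joining on pairwise maximum-likelihood GTR+Γ
   distances (distances capped at 20 substitutions/site with a warning when
   a pair is saturated).  NJ is implemented locally with a fixed scan order
   and canonical child rotation so ties (identical sequences) resolve
   deterministically.
2. **Branch lengths**: pruning-algorithm likelihood with per-pattern
   scaling; coordinate-wise Brent updates (Gauss–Seidel message refresh)
   iterated to relative log-likelihood change < 1e−6.  The two root-adjacent
   edges are individually non-identifiable under a reversible model; only
   their sum is meaningful before rooting.
3. **Rooting**: the strict-clock least-squares objective (variance of
   root-to-tip path lengths) minimized in closed form over a root position
   on every edge; ties break to the lexicographically smallest bipartition.
4. **Dating**: node ages (root fixed at 1; ages parameterized as nested
   proportions through a logistic transform) and rates optimized jointly by
   L-BFGS-B with the *exact* gradient, obtained from the per-edge
   log-likelihood derivatives of the pruning engine by the chain rule.
   Strict mode fits one global rate.  Relaxed mode fits one rate per branch
   and subtracts the penalty `smoothing · Σ (ln rᵢ − mean ln r)²` — the
   penalized-likelihood (MAP-like) analogue of an uncorrelated lognormal
   prior on rates — and is warm-started from the strict solution, which also
   makes the smoothing → ∞ limit collapse exactly onto strict dating.
5. **Rescaling**: the dated tree is scaled so its root age equals the known
   crown age, removing absolute-rate/age confounding; all comparisons are
   about relative branching structure.

The tree-prior condition label (`yule` vs `bd`) is carried through the
experimental design but does not enter the objective: no branching-process
prior term exists in the surrogate.  The four prior × clock inference cells
therefore collapse pairwise onto the two clock modes; the pipeline computes
each clock mode once and reports it under both prior labels.

**Smoothing.**  There is no principled mapping from a UCLN prior's sd
hyperprior to a penalty weight.  The default is 1.0; on simulated data the
fitted log-rate spread under this default tracks the generating σ across
presets (≈0.15 for low, ≈0.4–0.8 for high at n = 25, L = 5000), and
results can be re-run across a smoothing grid (e.g. {0.1, 1, 10}) via the
config.  Substitution-model parameters are fixed at their generating values
during all inference: the study isolates prior/clock effects, not
substitution-model misspecification.

## Diversification estimation

The likelihood of branching times is the Nee-type reconstructed-process
form.  Conditioned on crown age and survival of both crown lineages the
number of tips is a convolution of two geometrics,
`P(N = n) = (n−1)(1−u)² u^{n−2}` with `u = λ g(t)`, and given `N = n` the
ages are i.i.d. `f(s) = r² e^{−rs}/(λ − μ e^{−rs})² / g(t)`.  The default
log-likelihood is `log P(N=n) + Σ log f(xᵢ)` (`conditioning="survival"`);
`conditioning="n"` drops the tip-count term, i.e. additionally conditions on
n.  Ages are internally rescaled to crown age 1, making time-rescaling
equivariance of the MLEs exact.  Yule is the ε = 0 boundary of the same
expressions.  `bd_mle` runs five Nelder–Mead starts around the Yule
estimate with r ∈ (1e−6, 10] (scaled units) and ε ∈ [0, 0.999) via a
logistic transform; ε estimates within 1e−4 of a bound are flagged as
boundary solutions.  ε is freely estimated, and is reported but known to be
weakly identified.

**Which conditioning, and what it implies.**  The survival-conditioned
estimator is the field's default (it matches `ape::birthdeath` to four
decimals in mean over 200 trees in this package's cross-check test).  But on
trees simulated *conditioned on n* — exactly this study's generating
design — it is mis-centred: `E[N | survival]` greatly exceeds n, so the
tip-count term drags r̂ down (mean r̂ ≈ 0.31 against a generating 0.5051 at
n = 25) and the estimator is not consistent as n grows.  The
conditioning-on-n variant is correctly specified here and consistent, but
still carries substantial small-sample upward bias with ε free (≈ +13% mean
at n = 25).  The package keeps "survival" as the default because it is what
the emulated workflow uses and because it reproduces that workflow's
qualitative signatures (Yule λ̂ on birth–death trees rising with n while
staying below 2r).  The practical consequence: **absolute** r̂ values from
small fixed-n trees should not be read against the generating r; the study
design's comparisons are **relative** (re-estimated trees vs original
trees), where the shared bias cancels.

## Orchestration and reporting

Experiments are declarative YAML (conditions × inference grid × root seed)
with CLI verbs `simulate`, `infer`, `estimate`, `report`, `all`.  Each
replicate's artifacts are plain text: Newick chronograms, branch-rate CSV,
FASTA alignments, long-format estimate CSV, a median/quartile comparison
table always containing the original-trees reference column, and LTT
overlay plots (natural-log lineage counts; plots are a convenience layer —
no number is ever read back from a figure).  Stage failures are recorded
per replicate and the run continues; the CLI exits nonzero iff any failure
occurred.  Default replication is 10 original trees per condition.

## Problem sizes used by the test suite

Simulation-heavy checks run at deliberately chosen desk scales: the
KS oracle comparisons use 2000 replicates at n ∈ {5, 8}; parameter-recovery
means use 200 trees; the full-pipeline headline checks use 25 replicates at
n = 25, L = 5000; the taxon-number trend uses 150 trees per n; module-level
recovery tests use 4–8 replicates.  These sizes make the qualitative
assertions statistically stable while keeping the whole suite in the
tens-of-minutes range on one CPU.

## Known limitations

- **No posterior**: point estimates replace posterior distributions; nothing
  here measures credible-interval behavior, MCC-tree supports, or posterior
  CVs of rates under medium/high heterogeneity.
- **Topology is not co-estimated with the clock.**  NJ from ML distances is
  shared by both clock modes.  Under high rate heterogeneity this shared
  topology error dominates diversification-rate error, so the relaxed
  clock's advantage — clear in paired node-age accuracy on a fixed
  topology — does not propagate into a clear r̂ advantage through the full
  pipeline, as it does for Bayesian co-estimation.
- **Absolute diversification rates from small conditioned trees are
  unreliable** for both conditioning conventions (see above); relative
  comparisons are the supported use.
- The rejection-sampling oracle is practical only for small n; the
  inverse-CDF sampler is the production path at all sizes.
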