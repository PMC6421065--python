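# divclock

Does the choice of tree prior and molecular clock change the
diversification rates you infer from a phylogeny?  `divclock` is a
simulation-study toolkit for phylogeneticists that answers this the long way
round: it simulates dated trees and sequence data under known conditions,
re-estimates the trees under mismatched prior/clock assumptions, and
measures how the mismatch propagates into estimates of speciation and net
diversification rates.

## What it computes

**Tree simulation.**  Chronograms are drawn from the constant-rate
birth–death process (speciation λ, extinction μ, reparameterized as net
diversification r = λ − μ and relative extinction ε = μ/λ) conditioned on
the crown age t, on exactly n extant tips, and on survival of both crown
lineages.  Under this conditioning the n − 2 post-root speciation ages are
i.i.d. with distribution function

    F(s) = g(s) / g(t),   g(s) = (1 − e^{−rs}) / (λ − μ e^{−rs}),

so simulation is exact inverse-transform sampling attached to a uniform
ranked topology — no rejection.  The design sets r from the expectation
E[N_t] = N₀ e^{rt} (N₀ = 2): r = 0.5051 for 25 tips and r = 0.7824 for
100 tips at crown age 5.

**Clocks.**  A strict clock draws one global substitution rate; the
uncorrelated-lognormal (UCLN) relaxed clock draws an independent lognormal
rate per branch, parameterized by real-scale mean m ~ U(0.005, 0.015) and
log-scale standard deviation σ with three named heterogeneity presets
(low σ ~ U(0.17, 0.18); medium U(0.25, 1); high U(0.25, 1.75)), implying a
rate coefficient of variation √(e^{σ²} − 1).

**Sequences.**  Alignments evolve under GTR+Γ (continuous gamma site rates)
along the rate-scaled tree, with a nuclear-rRNA parameter set as default.

**Dating surrogate.**  Re-estimation is deterministic maximum /
penalized likelihood rather than Bayesian MCMC: neighbor-joining on pairwise
maximum-likelihood GTR+Γ distances, pruning-algorithm branch-length ML with
analytic gradients, least-squares clock rooting, then clock-constrained
dating — strict (one rate) or relaxed (per-branch rates with the lognormal
penalty smoothing·Σ(ln rᵢ − mean ln r)²).  Estimated chronograms are
rescaled to the true root height, so only relative node ages matter.

**Diversification estimation.**  From branching times, maximum likelihood
under the Yule model (λ̂) and the birth–death model (r̂, ε̂) using the
Nee-type reconstructed-process likelihood conditioned on crown age and
survival (a conditioning-on-n variant is available; see
`docs/methods.md` for why this matters).

## Worked example

```python
from divclock import (
    BDParams, GTRParams, InferenceConfig, UCLNClockParams,
    apply_rates, bd_mle, branching_times, draw_branch_rates,
    expected_net_diversification, infer_chronogram, rate_cv,
    simulate_alignment, simulate_chronogram,
)

r = expected_net_diversification(25, 2, 5)
print(f"design net diversification r = {r:.4f}")

tree = simulate_chronogram(BDParams(r, epsilon=0.5), n=25, crown_age=5.0, seed=1)
rates = draw_branch_rates(tree, UCLNClockParams.preset("low"), seed=2)
print(f"realized branch-rate CV = {rate_cv(rates):.4f}")

gtr = GTRParams.nuclear_rrna()
aln = simulate_alignment(apply_rates(tree, rates), gtr, length=5000, seed=3)

est = infer_chronogram(aln, gtr, InferenceConfig(clock_mode="relaxed"), root_age=5.0)
fit_true = bd_mle(branching_times(tree))
fit_est = bd_mle(branching_times(est.chronogram))
print(f"r-hat from the true tree      = {fit_true.r_hat:.4f} (eps-hat {fit_true.eps_hat:.3f})")
print(f"r-hat from the re-estimated tree = {fit_est.r_hat:.4f} (eps-hat {fit_est.eps_hat:.3f})")
```

Output:

```
design net diversification r = 0.5051
realized branch-rate CV = 0.1712
r-hat from the true tree      = 0.2847 (eps-hat 0.760)
r-hat from the re-estimated tree = 0.2020 (eps-hat 0.861)
```

The realized clock CV (0.171) sits inside the low-heterogeneity design
bracket.  Both r̂ values fall well below the generating r = 0.5051 — a
single 25-tip tree carries little information about r, and the
survival-conditioned MLE is additionally mis-centred on fixed-n simulations
(`docs/methods.md` quantifies both effects).  What the study design compares
is the *estimate from the re-estimated tree against the estimate from the
original tree*, where this shared bias cancels.

Full experiment grids run from the command line:

```bash
divclock all --seed 1 --outdir out/          # default 2x2 grid, 10 replicates
divclock simulate --config my.yaml --outdir out/   # or stage by stage
```

emitting Newick trees, FASTA alignments, long-format CSV estimate tables,
a median/quartile comparison table, and lineage-through-time overlay plots.

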