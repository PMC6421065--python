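"""Branch-rate simulation: strict and uncorrelated-lognormal (UCLN) clocks.

A clock model turns a chronogram (branch durations in time units) into a
phylogram (branch lengths in expected substitutions per site) by assigning a
substitution rate to every branch.  The strict clock draws one global rate;
the UCLN relaxed clock draws an independent lognormal rate per branch.

Lognormal convention (throughout): distributions are specified by their
*real-scale mean* m and *log-scale standard deviation* sigma, so the log-rate
mean is ln(m) - sigma^2/2 and the theoretical coefficient of variation of
rates is sqrt(e^{sigma^2} - 1).  Under the low-heterogeneity preset
(sigma ~ U(0.17, 0.18)) that CV is 0.171-0.182.

The three named heterogeneity presets draw the UCLN hyperparameters once per
tree: m ~ U(0.0050, 0.015) substitutions/site/time and sigma uniform on
(0.17, 0.18), (0.25, 1) or (0.25, 1.75) for low, medium and high
among-lineage rate heterogeneity respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import branch_id, branch_nodes, clone_tree, rng_from

#: hyperparameter ranges of the named UCLN heterogeneity presets
UCLN_PRESETS: dict[str, tuple[float, float]] = {
    "low": (0.17, 0.18),
    "medium": (0.25, 1.0),
    "high": (0.25, 1.75),
}
UCLN_MEAN_BOUNDS: tuple[float, float] = (0.0050, 0.015)


@dataclass(frozen=True)
class StrictClockParams:
    """Global clock: one rate, lognormal(mean ``rate_mean``, sdlog ``rate_sdlog``)."""

    rate_mean: float = 0.01
    rate_sdlog: float = 0.5

    def __post_init__(self):
        if not self.rate_mean > 0:
            raise ValueError("rate_mean must be > 0")
        if self.rate_sdlog < 0:
            raise ValueError("rate_sdlog must be >= 0")


@dataclass(frozen=True)
class UCLNClockParams:
    """UCLN clock with per-tree uniform hyperpriors on (mean, sdlog)."""

    mean_low: float = UCLN_MEAN_BOUNDS[0]
    mean_high: float = UCLN_MEAN_BOUNDS[1]
    sigma_low: float = 0.17
    sigma_high: float = 0.18

    def __post_init__(self):
        if not (0 < self.mean_low <= self.mean_high):
            raise ValueError("require 0 < mean_low <= mean_high")
        if not (0 <= self.sigma_low <= self.sigma_high):
            raise ValueError("require 0 <= sigma_low <= sigma_high")

    @classmethod
    def preset(cls, level: str) -> "UCLNClockParams":
        """Named heterogeneity level: ``low``, ``medium`` or ``high``."""
        try:
            lo, hi = UCLN_PRESETS[level]
        except KeyError:
            raise ValueError(f"unknown preset {level!r}; expected one of {sorted(UCLN_PRESETS)}")
        return cls(*UCLN_MEAN_BOUNDS, lo, hi)


@dataclass(frozen=True)
class BranchRateSet:
    """Per-branch substitution rates, keyed by branch id (see :mod:`.trees`)."""

    rates: dict[str, float]

    def __post_init__(self):
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("all branch rates must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.rates.values()))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("branch,rate\n")
            for b, r in self.rates.items():
                fh.write(f"{b},{r:.12g}\n")


def lognormal_rates(mean: float, sdlog: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with real-scale mean ``mean`` and log-scale sd ``sdlog``."""
    if sdlog == 0.0:
        return np.full(size, mean)
    mulog = math.log(mean) - 0.5 * sdlog**2
    return rng.lognormal(mean=mulog, sigma=sdlog, size=size)


def draw_branch_rates(
    tree: dendropy.Tree, clock: StrictClockParams | UCLNClockParams, seed
) -> BranchRateSet:
    """Draw one substitution rate per branch of ``tree`` under ``clock``.

    Strict: a single lognormal rate shared by all branches.  UCLN: the
    hyperparameters (m, sigma) are drawn once per tree from their uniform
    ranges, then each branch gets an independent lognormal(m, sigma) rate.
    Branch order is preorder, so draws are reproducible given the seed.
    """
    rng = rng_from(seed)
    nodes = branch_nodes(tree)
    ids = [branch_id(nd) for nd in nodes]
    if isinstance(clock, StrictClockParams):
        rate = float(lognormal_rates(clock.rate_mean, clock.rate_sdlog, 1, rng)[0])
        rates = dict.fromkeys(ids, rate)
    else:
        m = rng.uniform(clock.mean_low, clock.mean_high)
        sigma = rng.uniform(clock.sigma_low, clock.sigma_high)
        draws = lognormal_rates(m, sigma, len(ids), rng)
        rates = dict(zip(ids, map(float, draws)))
    return BranchRateSet(rates)


def apply_rates(tree: dendropy.Tree, rates: BranchRateSet) -> dendropy.Tree:
    """Phylogram with branch_length = rate * duration for every branch."""
    phylo = clone_tree(tree)
    for nd in branch_nodes(phylo):
        bid = branch_id(nd)
        if bid not in rates.rates:
            raise ValueError(f"no rate supplied for branch {bid!r}")
        nd.edge.length = (nd.edge.length or 0.0) * rates.rates[bid]
    return phylo


def rate_cv(rates: BranchRateSet) -> float:
    """Sample coefficient of variation (sd/mean, n-1 denominator) of branch rates."""
    x = rates.as_array()
    if len(x) < 2:
        raise ValueError("rate CV requires at least 2 branches")
    return float(np.std(x, ddof=1) / np.mean(x))
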