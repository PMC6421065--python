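"""Simulation of ultrametric chronograms under Yule and birth-death processes.

Trees are drawn from the constant-rate reconstructed birth-death process
conditioned on (i) the crown age ``t``, (ii) exactly ``n`` extant tips, and
(iii) survival of both crown lineages.  Under this conditioning the ``n - 2``
post-root speciation ages are i.i.d. with distribution function

    F(s) = g(s) / g(t),    g(s) = (1 - e^{-r s}) / (lambda - mu e^{-r s}),

for 0 <= s <= t, where r = lambda - mu (the classic conditioned reconstructed
process result), so sampling is by inverse transform in O(n) with no
rejection.  The ranked topology of the reconstructed process is uniform, so
ages are attached by successively joining two uniformly chosen extant
lineages at each event age, youngest first.

The net diversification rate of the study design is set from the expectation
E[N_t] = N_0 e^{r t} of the number of tips: :func:`expected_net_diversification`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import ensure_branch_labels, node_ages, rng_from, validate_chronogram


@dataclass(frozen=True)
class YuleParams:
    """Pure-birth process: a single per-lineage speciation rate (per time unit)."""

    birth_rate: float

    def __post_init__(self):
        if not self.birth_rate > 0:
            raise ValueError("birth_rate must be > 0")

    @property
    def death_rate(self) -> float:
        return 0.0


@dataclass(frozen=True)
class BDParams:
    """Birth-death process parameterized by net diversification and relative extinction.

    ``r = lambda - mu`` (per time unit) and ``epsilon = mu / lambda``
    (dimensionless, in [0, 1)); the implied speciation and extinction rates
    are ``lambda = r / (1 - epsilon)`` and ``mu = epsilon * lambda``.
    """

    r: float
    epsilon: float

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError("net diversification rate r must be > 0")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("relative extinction epsilon must be in [0, 1)")

    @property
    def birth_rate(self) -> float:
        return self.r / (1.0 - self.epsilon)

    @property
    def death_rate(self) -> float:
        return self.epsilon * self.birth_rate


def expected_net_diversification(n_t: float, n0: float, t: float) -> float:
    """Net diversification rate implied by E[N_t] = N_0 e^{r t}.

    Solves for ``r = ln(n_t / n0) / t`` given the expected number of extant
    lineages ``n_t`` at time ``t`` starting from ``n0`` lineages.
    """
    if not t > 0:
        raise ValueError("tree height t must be > 0")
    if not (n_t >= n0 >= 1):
        raise ValueError("require n_t >= n0 >= 1")
    return math.log(n_t / n0) / t


def _rates(model: YuleParams | BDParams) -> tuple[float, float]:
    return model.birth_rate, model.death_rate


def conditioned_age_cdf(model: YuleParams | BDParams, s, crown_age: float):
    """CDF of a single post-root speciation age under the conditioned process."""
    lam, mu = _rates(model)
    r = lam - mu
    s = np.asarray(s, dtype=float)

    def g(x):
        e = np.exp(-r * x)
        return (1.0 - e) / (lam - mu * e)

    return g(s) / g(crown_age)


def sample_branching_times(
    model: YuleParams | BDParams, n: int, crown_age: float, rng: np.random.Generator
) -> np.ndarray:
    """Ages (descending) of the n - 1 speciation events, crown age first.

    The crown age is fixed by conditioning; the remaining ``n - 2`` ages are
    i.i.d. draws from F(s) = g(s)/g(crown_age) by inverse transform.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if not crown_age > 0:
        raise ValueError("crown_age must be > 0")
    lam, mu = _rates(model)
    r = lam - mu
    if n == 2:
        return np.array([crown_age])
    u = rng.random(n - 2)
    gt = (1.0 - math.exp(-r * crown_age)) / (lam - mu * math.exp(-r * crown_age))
    c = u * gt
    x = (1.0 - c * lam) / (1.0 - c * mu)  # x = e^{-r s}
    ages = -np.log(x) / r
    ages = np.sort(ages)[::-1]
    return np.concatenate([[crown_age], ages])


def simulate_chronogram(
    model: YuleParams | BDParams, n: int, crown_age: float, seed
) -> dendropy.Tree:
    """Draw one chronogram with exactly ``n`` tips and root age ``crown_age``.

    Deterministic given ``seed`` (an integer or a Generator).  Tips are
    labelled ``t1..tn`` and internal nodes ``n1..`` in preorder of the built
    tree, so output Newick is bit-reproducible.
    """
    rng = rng_from(seed)
    ages = sample_branching_times(model, n, crown_age, rng)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(n):
        active.append((dendropy.Node(), 0.0))

    # join two uniformly chosen extant lineages at each event age, youngest first
    for age in ages[::-1]:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (a, age_a), (b, age_b) = active[i], active[j]
        parent = dendropy.Node()
        a.edge.length = age - age_a
        b.edge.length = age - age_b
        parent.add_child(a)
        parent.add_child(b)
        active[i] = (parent, age)
        active.pop(j)

    root = active[0][0]
    tree.seed_node = root
    k = 0
    for leaf in tree.leaf_node_iter():
        k += 1
        leaf.taxon = taxon_namespace.new_taxon(label=f"t{k}")
    ensure_branch_labels(tree)
    validate_chronogram(tree)
    return tree


def branching_times(tree: dendropy.Tree) -> np.ndarray:
    """Sorted (descending) internal-node ages of a chronogram.

    The first element is the crown age; length is ``n - 1`` for ``n`` tips.
    Raises ValueError on non-ultrametric input.
    """
    ages = node_ages(tree, validate=True)
    internal = [ages[nd] for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    return np.sort(np.asarray(internal))[::-1]


def lineage_count_at(bt: np.ndarray, x) -> np.ndarray:
    """Number of reconstructed lineages alive at age ``x`` (time before present).

    ``bt`` are branching times sorted descending.  At ages older than the
    crown age there is 1 lineage; each speciation (crossing an age in ``bt``)
    adds one, so at age x the count is 1 + #{ages > x} clipped to [1, n].
    """
    bt = np.asarray(bt)
    x = np.asarray(x, dtype=float)
    counts = 1 + np.sum(bt[None, ...] > np.atleast_1d(x)[..., None], axis=-1)
    return counts if x.ndim else int(counts[0])


def simulate_forward_rejection(
    model: YuleParams | BDParams,
    n: int,
    crown_age: float,
    rng: np.random.Generator,
    max_tries: int = 5_000_000,
) -> np.ndarray:
    """Oracle sampler: forward Gillespie simulation with rejection.

    Simulates a complete birth-death tree from 2 crown lineages for
    ``crown_age`` time units, prunes extinct lineages, and rejects unless
    both crown lineages survive and exactly ``n`` tips remain.  Returns the
    branching times (descending, crown age first) of the reconstructed tree.
    Intended for validating :func:`simulate_chronogram` at small n only.
    """
    lam, mu = _rates(model)
    p_birth = lam / (lam + mu)
    cap = 6 * n + 60  # population beyond this essentially never returns to n
    for _ in range(max_tries):
        # node record: [split_time or None, child_a, child_b, alive_at_present]
        c1 = [None, None, None, False]
        c2 = [None, None, None, False]
        extant = [c1, c2]
        tau = 0.0
        ok = True
        while extant:
            k = len(extant)
            tau += rng.exponential(1.0 / (k * (lam + mu)))
            if tau >= crown_age:
                break
            idx = rng.integers(k)
            if rng.random() < p_birth:
                node = extant[idx]
                a = [None, None, None, False]
                b = [None, None, None, False]
                node[0], node[1], node[2] = tau, a, b
                extant[idx] = a
                extant.append(b)
                if len(extant) > cap:
                    ok = False
                    break
            else:
                extant.pop(idx)
        if not ok or len(extant) != n:
            continue
        for node in extant:
            node[3] = True

        def survivors(node) -> int:
            if node[1] is None:
                return 1 if node[3] else 0
            return survivors(node[1]) + survivors(node[2])

        if survivors(c1) == 0 or survivors(c2) == 0:
            continue  # crown lineage died out: crown age would not be observed

        recon_ages: list[float] = []

        def collect(node) -> None:
            if node[1] is None:
                return
            sa, sb = survivors(node[1]), survivors(node[2])
            if sa > 0 and sb > 0:
                recon_ages.append(crown_age - node[0])
            collect(node[1])
            collect(node[2])

        collect(c1)
        collect(c2)
        recon_ages.sort(reverse=True)
        if len(recon_ages) != n - 2:
            raise AssertionError("reconstructed event count mismatch")
        return np.concatenate([[crown_age], recon_ages])
    raise RuntimeError("rejection sampler exhausted max_tries")
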