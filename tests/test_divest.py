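"""Diversification-rate likelihoods and MLEs from branching times."""

import math

import numpy as np
import pytest

from divclock import divest as dv
from divclock import treesim as ts

from conftest import make_rng


@pytest.fixture(scope="module")
def bd_bt():
    tree = ts.simulate_chronogram(ts.BDParams(0.5051, 0.5), 25, 5.0, 31)
    return ts.branching_times(tree)


class TestLogLik:
    def test_vanishing_rate_drives_loglik_down(self, bd_bt):
        lls = [dv.yule_loglik(bd_bt, lam) for lam in (1e-8, 1e-4, 0.5)]
        assert lls[0] < lls[1] < lls[2]

    @pytest.mark.parametrize("conditioning", ["survival", "n"])
    def test_yule_equals_bd_at_eps_zero(self, bd_bt, conditioning):
        for lam in (0.1, 0.5051, 2.0):
            assert dv.yule_loglik(bd_bt, lam, conditioning) == pytest.approx(
                dv.bd_loglik(bd_bt, lam, 0.0, conditioning), abs=1e-10
            )

    def test_function_of_sorted_ages_only(self, bd_bt):
        rng = make_rng(1)
        shuffled = bd_bt.copy()
        rng.shuffle(shuffled)
        assert dv.bd_loglik(shuffled, 0.4, 0.3) == dv.bd_loglik(bd_bt, 0.4, 0.3)

    def test_domain_errors(self, bd_bt):
        with pytest.raises(ValueError):
            dv.bd_loglik(bd_bt, 0.5, 1.0)
        with pytest.raises(ValueError):
            dv.yule_loglik(np.array([5.0]), 0.5)  # cherry: fewer than 3 tips

    def test_matches_discrete_time_forward_oracle(self):
        """Yule log-likelihood differences equal a small-step forward density.

        For a 4-tip history with known event ages, the probability density of
        the trajectory is built step-by-step (survival factors (1 - k lam dt)
        between events, event density k lam), conditioned on nothing extra
        (a pure-birth tree always survives).  Constants independent of lambda
        cancel in differences.
        """
        t = 2.0
        bt = np.array([t, 1.2, 0.5])

        def forward_logdensity(lam, dt=2e-6):
            # lineage counts on forward-time segments between events
            seg = [(0.0, t - 1.2, 2), (t - 1.2, t - 0.5, 3), (t - 0.5, t, 4)]
            ll = 0.0
            for a, b, k in seg:
                m = round((b - a) / dt)
                ll += m * math.log1p(-k * lam * dt)
            ll += math.log(2 * lam) + math.log(3 * lam)  # event densities
            return ll

        for l1, l2 in [(0.3, 0.7), (0.5, 1.1)]:
            mine = dv.yule_loglik(bt, l1) - dv.yule_loglik(bt, l2)
            oracle = forward_logdensity(l1) - forward_logdensity(l2)
            assert mine == pytest.approx(oracle, abs=2e-3)

    def test_tip_count_term_matches_geometric_forward_simulation(self):
        """P(N = n | survival) factor checked against Gillespie simulation.

        A single lineage run forward for time t leaves, conditional on
        survival, a geometric number of tips with parameter u; the crown
        P(N=n) used in the survival-conditioned likelihood is the
        convolution of two such geometrics.
        """
        lam, mu, t = 1.8, 0.9, 1.0
        r = lam - mu
        u = lam * (1 - math.exp(-r * t)) / (lam - mu * math.exp(-r * t))
        rng = make_rng(2)
        counts = []
        for _ in range(40_000):
            k, tau = 1, 0.0
            while k > 0:
                tau += rng.exponential(1.0 / (k * (lam + mu)))
                if tau >= t:
                    break
                k += 1 if rng.random() < lam / (lam + mu) else -1
            if k > 0:
                counts.append(k)
        counts = np.asarray(counts)
        for n in (1, 2, 4, 8):
            expected = (1 - u) * u ** (n - 1)
            observed = np.mean(counts == n)
            se = math.sqrt(expected * (1 - expected) / len(counts))
            assert abs(observed - expected) < 4 * se + 1e-4


def _grid_refine_yule(bt, lo=1e-4, hi=8.0, rounds=30):
    for _ in range(rounds):
        grid = np.linspace(lo, hi, 41)
        lls = [dv.yule_loglik(bt, g) for g in grid]
        i = int(np.argmax(lls))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 40)]
    return float(grid[i])


def _grid_refine_bd(bt, rounds=40):
    # re-centred shrinking grid: robust to the flat r-eps ridge
    rc, ec = 0.5, 0.5
    rspan, espan = 4.0, 0.5
    for _ in range(rounds):
        rg = np.clip(np.linspace(rc - rspan, rc + rspan, 21), 1e-4, 8.0)
        eg = np.clip(np.linspace(ec - espan, ec + espan, 21), 0.0, 0.999)
        lls = np.array([[dv.bd_loglik(bt, r, e) for e in eg] for r in rg])
        i, j = np.unravel_index(np.argmax(lls), lls.shape)
        rc, ec = float(rg[i]), float(eg[j])
        rspan *= 0.55
        espan *= 0.55
    return rc, ec


class TestMLE:
    def test_yule_mle_matches_grid_oracle_three_tips(self):
        bt = np.array([5.0, 1.0])
        est = dv.yule_mle(bt)
        assert est.converged
        assert est.lambda_hat == pytest.approx(_grid_refine_yule(bt), rel=1e-6)

    def test_yule_mle_matches_grid_oracle_simulated(self, bd_bt):
        est = dv.yule_mle(bd_bt)
        assert est.lambda_hat == pytest.approx(_grid_refine_yule(bd_bt), rel=1e-6)

    def test_time_rescaling_equivariance_exact(self, bd_bt):
        a = dv.yule_mle(bd_bt)
        b = dv.yule_mle(2.0 * bd_bt)
        assert b.lambda_hat == a.lambda_hat / 2.0
        ea = dv.bd_mle(bd_bt)
        eb = dv.bd_mle(2.0 * bd_bt)
        assert eb.r_hat == ea.r_hat / 2.0
        assert eb.eps_hat == ea.eps_hat

    @pytest.mark.parametrize("seed", [31, 77])
    def test_bd_mle_matches_grid_refinement_oracle(self, seed):
        tree = ts.simulate_chronogram(ts.BDParams(0.5051, 0.5), 25, 5.0, seed)
        bt = ts.branching_times(tree)
        est = dv.bd_mle(bt)
        r_oracle, _ = _grid_refine_bd(bt)
        assert est.r_hat == pytest.approx(r_oracle, abs=1e-4 * max(1.0, r_oracle))

    def test_mle_dominates_generating_parameters(self):
        for seed in range(5):
            tree = ts.simulate_chronogram(ts.BDParams(0.7824, 0.5), 25, 5.0, seed)
            bt = ts.branching_times(tree)
            est = dv.bd_mle(bt)
            assert est.loglik >= dv.bd_loglik(bt, 0.7824, 0.5) - 1e-8

    def test_profile_nesting_at_eps_zero(self, bd_bt):
        """sup over lambda of the Yule likelihood = BD profile at eps = 0."""
        yule = dv.yule_mle(bd_bt)
        grid = np.linspace(0.5 * yule.lambda_hat, 2.0 * yule.lambda_hat, 201)
        profile = max(dv.bd_loglik(bd_bt, r, 0.0) for r in grid)
        assert yule.loglik >= profile - 1e-8

    def test_small_tree_warns(self):
        with pytest.warns(UserWarning):
            dv.bd_mle(np.array([5.0, 2.0]))


class TestBiasPatterns:
    def test_yule_rate_biased_below_true_speciation_under_extinction(self):
        """Fitting a pure-birth model to birth-death trees underestimates lambda."""
        r, eps = 0.5051, 0.5
        lam_true = r / (1 - eps)
        vals = []
        for k in range(200):
            tree = ts.simulate_chronogram(ts.BDParams(r, eps), 25, 5.0, make_rng(3, k))
            vals.append(dv.yule_mle(ts.branching_times(tree)).lambda_hat)
        assert np.mean(vals) < lam_true

    def test_yule_rate_bias_shrinks_with_taxon_count(self):
        r = 0.5051
        means = []
        for n in (50, 75, 125):
            vals = []
            for k in range(150):
                tree = ts.simulate_chronogram(ts.BDParams(r, 0.5), n, 5.0, make_rng(4, n, k))
                vals.append(dv.yule_mle(ts.branching_times(tree)).lambda_hat)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2] < 2 * r
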