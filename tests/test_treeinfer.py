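"""Topology estimation, clock rooting, and clock-constrained dating."""

import numpy as np
import pytest

from divclock import clocksim as cs
from divclock import seqsim as ss
from divclock import treeinfer as ti
from divclock import treesim as tsim
from divclock.trees import from_newick, is_ultrametric, node_ages, to_newick

from conftest import make_rng


def _clade_ages(tree, normalize=False):
    ages = node_ages(tree)
    out = {}
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            out[frozenset(l.taxon.label for l in nd.leaf_iter())] = ages[nd]
    if normalize:
        m = max(out.values())
        out = {k: v / m for k, v in out.items()}
    return out


def _splits(tree):
    tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        out.add(min(side, tips - side, key=sorted))
    return out


class TestTopology:
    def test_true_split_recovered_with_long_internal_branch(self, gtr):
        """NJ on ML distances finds the 4-taxon split nearly always."""
        tree = from_newick("((a:0.2,b:0.2):0.12,(c:0.2,d:0.2):0.12);")
        hits = 0
        n_rep = 40
        for k in range(n_rep):
            aln = ss.simulate_alignment(tree, gtr, 5000, make_rng(1, k))
            est = ti.estimate_topology(aln, gtr)
            hits += frozenset("ab") in _splits(est) or frozenset("cd") in _splits(est)
        assert hits >= n_rep - 1

    def test_true_topology_passthrough(self, gtr, strict_clock_dataset):
        tree, _, aln = strict_clock_dataset
        cfg = ti.InferenceConfig(topology_source="true")
        est = ti.estimate_topology(aln, gtr, cfg, true_tree=tree)
        assert _splits(est) == _splits(tree)

    def test_identical_sequences_become_siblings(self, gtr):
        seq = "ACGTTGCA" * 100
        rng = make_rng(2)
        other = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        third = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        aln = ss.Alignment.from_sequences(
            [("a", seq), ("b", seq), ("c", other), ("d", third)]
        )
        est = ti.estimate_topology(aln, gtr)
        assert frozenset("ab") in _splits(est)

    def test_saturated_pair_capped_with_warning(self, gtr):
        # zero shared sites: the pairwise likelihood increases without bound
        rng = make_rng(3)
        s1 = rng.integers(0, 4, 2000)
        s2 = (s1 + 1) % 4
        with pytest.warns(UserWarning):
            d = ti.ml_pairwise_distance(s1, s2, gtr)
        assert d == ti.MAX_PAIRWISE_DISTANCE


class TestMLBranchLengths:
    def test_two_taxon_matches_direct_pairwise_optimum(self, gtr):
        tree = from_newick("(a:0.08,b:0.08);")
        aln = ss.simulate_alignment(tree, gtr, 4000, make_rng(4))
        phylo, ll, conv = ti.ml_branch_lengths(aln, tree, gtr)
        total = sum(nd.edge.length for nd in phylo.seed_node.child_nodes())
        d = ti.ml_pairwise_distance(aln.data[0], aln.data[1], gtr)
        assert conv
        assert total == pytest.approx(d, abs=1e-4)

    def test_identical_sequences_collapse(self, gtr):
        aln = ss.Alignment.from_sequences(
            [("a", "ACGT" * 100), ("b", "ACGT" * 100), ("c", "ACGT" * 100)]
        )
        topo = from_newick("((a:0.1,b:0.1):0.1,c:0.1);")
        phylo, _, _ = ti.ml_branch_lengths(aln, topo, gtr)
        for nd in phylo.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length <= 1e-8


class TestRooting:
    def test_recovers_clock_root_on_exact_data(self):
        # perfectly clock-like phylogram, unrooted: rooting must recover
        # the position equidistant from all tips
        rooted = from_newick("((a:1,b:1):1,(c:1.5,d:1.5):0.5);")
        unrooted = rooted.clone(depth=1)
        unrooted.deroot()
        out = ti.root_by_clock(unrooted)
        depths = {l.taxon.label: None for l in out.leaf_node_iter()}
        ages = node_ages(out, validate=True)  # would raise if not ultrametric
        assert ages[out.seed_node] == pytest.approx(2.0)
        assert _splits(out) == _splits(rooted)


class TestDating:
    def test_strict_clock_age_recovery(self, gtr):
        """Relative node ages recovered within 5% RMSE under a strict clock."""
        rmses = []
        for k in range(8):
            tree = tsim.simulate_chronogram(tsim.BDParams(0.5051, 0.5), 25, 5.0, make_rng(5, k))
            phylo = cs.apply_rates(tree, cs.draw_branch_rates(tree, cs.StrictClockParams(), make_rng(6, k)))
            aln = ss.simulate_alignment(phylo, gtr, 5000, make_rng(7, k))
            est = ti.date_strict(aln, tree, gtr)
            assert est.converged
            assert is_ultrametric(est.chronogram, 1e-9)
            ta = _clade_ages(tree, normalize=True)
            ea = _clade_ages(est.chronogram, normalize=True)
            common = set(ta) & set(ea)
            diffs = np.array([ta[c] - ea[c] for c in common])
            rmses.append(float(np.sqrt(np.mean(diffs**2))))
        assert np.median(rmses) < 0.05

    def test_dated_loglik_never_exceeds_unconstrained(self, gtr, strict_clock_dataset):
        tree, _, aln = strict_clock_dataset
        est = ti.date_strict(aln, tree, gtr)
        assert est.loglik <= est.loglik_unconstrained + 1e-6

    def test_smoothing_limit_recovers_strict_dating(self, gtr):
        tree = tsim.simulate_chronogram(tsim.BDParams(0.5051, 0.5), 10, 5.0, make_rng(8))
        phylo = cs.apply_rates(tree, cs.draw_branch_rates(tree, cs.UCLNClockParams.preset("medium"), make_rng(9)))
        aln = ss.simulate_alignment(phylo, gtr, 2000, make_rng(10))
        strict = ti.date_strict(aln, tree, gtr)
        relaxed = ti.date_relaxed(aln, tree, gtr, smoothing=1e9)
        sa = _clade_ages(strict.chronogram, normalize=True)
        ra = _clade_ages(relaxed.chronogram, normalize=True)
        assert max(abs(sa[c] - ra[c]) for c in sa) < 1e-3

    def test_penalty_shrinks_rate_spread_monotonically(self, gtr):
        tree = tsim.simulate_chronogram(tsim.BDParams(0.5051, 0.5), 10, 5.0, make_rng(11))
        phylo = cs.apply_rates(tree, cs.draw_branch_rates(tree, cs.StrictClockParams(), make_rng(12)))
        aln = ss.simulate_alignment(phylo, gtr, 2000, make_rng(13))
        spreads = []
        for smoothing in (0.1, 10.0, 1000.0):
            est = ti.date_relaxed(aln, tree, gtr, smoothing=smoothing)
            spreads.append(np.var(np.log(list(est.rates.values()))))
        assert spreads[0] >= spreads[1] >= spreads[2]
        assert spreads[2] < 1e-4

    def test_relaxed_beats_strict_under_high_heterogeneity(self, gtr):
        """The paper's core clock contrast as a paired simulation property."""
        wins, diffs = 0, []
        n_rep = 5
        for k in range(n_rep):
            tree = tsim.simulate_chronogram(tsim.BDParams(0.5051, 0.5), 15, 5.0, make_rng(14, k))
            phylo = cs.apply_rates(
                tree, cs.draw_branch_rates(tree, cs.UCLNClockParams.preset("high"), make_rng(15, k))
            )
            aln = ss.simulate_alignment(phylo, gtr, 3000, make_rng(16, k))
            ta = _clade_ages(tree, normalize=True)

            def rmse(est):
                ea = _clade_ages(est.chronogram, normalize=True)
                common = set(ta) & set(ea)
                return float(np.sqrt(np.mean([(ta[c] - ea[c]) ** 2 for c in common])))

            rs = rmse(ti.date_strict(aln, tree, gtr))
            rr = rmse(ti.date_relaxed(aln, tree, gtr))
            diffs.append(rs - rr)
        assert np.median(diffs) > 0


class TestRescale:
    def test_identity_and_doubling(self):
        tree = from_newick("((a:1,b:1):1.5,c:2.5);")
        same = ti.rescale_to_root(tree, 2.5)
        assert to_newick(same) == to_newick(tree)
        doubled = ti.rescale_to_root(tree, 5.0)
        ages = node_ages(doubled)
        assert ages[doubled.seed_node] == pytest.approx(5.0)

    def test_composition_idempotence(self, bd25_tree):
        a = ti.rescale_to_root(ti.rescale_to_root(bd25_tree, 7.0), 5.0)
        b = ti.rescale_to_root(bd25_tree, 5.0)
        assert to_newick(a) == to_newick(b)

    def test_zero_root_age_rejected(self, bd25_tree):
        with pytest.raises(ValueError):
            ti.rescale_to_root(bd25_tree, 0.0)


def test_end_to_end_age_recovery(gtr):
    """Simulate -> strict clock -> sequences -> matched estimation -> rescale:
    estimated node ages correlate strongly with the generating ages."""
    cors = []
    for k in range(4):
        tree = tsim.simulate_chronogram(tsim.BDParams(0.5051, 0.5), 25, 5.0, make_rng(17, k))
        phylo = cs.apply_rates(tree, cs.draw_branch_rates(tree, cs.StrictClockParams(), make_rng(18, k)))
        aln = ss.simulate_alignment(phylo, gtr, 5000, make_rng(19, k))
        est = ti.infer_chronogram(
            aln, gtr, ti.InferenceConfig(topology_source="estimate", clock_mode="strict"),
            root_age=5.0,
        )
        ta = _clade_ages(tree)
        ea = _clade_ages(est.chronogram)
        common = set(ta) & set(ea)
        assert len(common) >= 15  # most clades recovered
        tv = np.array([ta[c] for c in common])
        ev = np.array([ea[c] for c in common])
        cors.append(np.corrcoef(tv, ev)[0, 1])
    assert np.median(cors) >= 0.95
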