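import itertools

import numpy as np
import pytest

from paleoclock import (
    Alignment,
    RateProcess,
    SubstitutionModel,
    compare_reconstructions,
    map_column_to_reference,
    map_reference_site,
    marginal_asr,
    reconstruct_indels,
    simulate_alignment,
    simulate_branch_rates,
    simulate_timetree,
)
from paleoclock.substitution import AA_ORDER
from paleoclock.trees import NO_PARENT


def subs_of(tree):
    out = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if tree.parent[v] != NO_PARENT:
            out[v] = tree.branch_subs(v)
    return out


def brute_force_marginal(aln, tree, subs, model, target, site):
    """Enumeration oracle for the marginal posterior at one node/site."""
    pi = model.equilibrium_frequencies()
    cat_rates = model.category_rates()
    enc = {i: model.encode(s) for i, s in aln.records}
    others = [v for v in tree.internal_nodes if v != target]
    pp = np.zeros(20)
    for target_state in range(20):
        for r in cat_rates:
            p = {
                v: model.transition_matrix(subs[v], r)
                for v in range(tree.n_nodes)
                if tree.parent[v] != NO_PARENT
            }
            for assign in itertools.product(range(20), repeat=len(others)):
                st = dict(zip(others, assign))
                st[target] = target_state
                for leaf in tree.leaves:
                    code = enc[tree.names[leaf]][site]
                    st[leaf] = None if code < 0 else code
                lik = pi[st[tree.root]]
                for v in range(tree.n_nodes):
                    if tree.parent[v] == NO_PARENT or st[v] is None:
                        continue
                    parent_state = st[tree.parent[v]]
                    lik *= p[v][parent_state, st[v]]
                pp[target_state] += lik
    return pp / pp.sum()


class TestMarginalASR:
    def test_concordant_signal_high_pp(self, poisson_model):
        tree = simulate_timetree(3, 1.0, seed=1)
        tree.branch_rate[:] = 0.01
        aln = Alignment([(tree.names[l], "A") for l in tree.leaves])
        rec = marginal_asr(aln, tree, poisson_model, tree.root)
        assert rec.map_sequence == "A"
        assert rec.posterior[0, AA_ORDER.index("A")] > 0.99

    @pytest.mark.parametrize("n_leaves", [3, 4, 5])
    def test_matches_enumeration_oracle(self, n_leaves):
        """Marginal posterior equals brute-force enumeration over the other
        interior nodes' states (tolerance 1e-10)."""
        rng = np.random.default_rng(2)
        for draw in range(6):
            tree = simulate_timetree(n_leaves, 1.0, seed=300 + draw)
            model = SubstitutionModel(
                ["POISSON", "JTT", "LG"][draw % 3],
                gamma_shape=float(rng.uniform(0.4, 1.5)),
                n_categories=1 + (draw % 2),
            )
            tree.branch_rate[:] = 0.6
            aln = simulate_alignment(tree, model, 2, seed=400 + draw)
            subs = np.array(
                [rng.uniform(0.05, 1.0) for _ in range(tree.n_nodes)]
            )
            targets = tree.internal_nodes
            for target in targets[: 2]:
                rec = marginal_asr(aln, tree, model, target, branch_subs=subs)
                for site in range(2):
                    oracle = brute_force_marginal(
                        aln, tree, subs, model, target, site
                    )
                    assert np.max(np.abs(rec.posterior[site] - oracle)) < 1e-10

    def test_symmetric_split_gives_equal_pp(self, poisson_model):
        """2+2 leaves, equal branch lengths, split A/A vs C/C: by
        exchangeability PP(A) == PP(C) at the root."""
        # hand-built symmetric topology
        from paleoclock.trees import TimeTree

        tree = TimeTree(
            parent=[4, 4, 5, 5, 6, 6, NO_PARENT],
            age=[0, 0, 0, 0, 1.0, 1.0, 2.0],
            names=["a", "b", "c", "d", None, None, None],
        )
        subs = np.array([0.3, 0.3, 0.3, 0.3, 0.2, 0.2, 0.0])
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        rec = marginal_asr(aln, tree, poisson_model, 6, branch_subs=subs)
        i_a, i_c = AA_ORDER.index("A"), AA_ORDER.index("C")
        assert rec.posterior[0, i_a] == pytest.approx(rec.posterior[0, i_c],
                                                      abs=1e-12)

    def test_leaf_target_rejected(self, poisson_model):
        tree = simulate_timetree(3, 1.0, seed=3)
        tree.branch_rate[:] = 0.1
        aln = Alignment([(tree.names[l], "A") for l in tree.leaves])
        with pytest.raises(ValueError, match="leaf"):
            marginal_asr(aln, tree, poisson_model, tree.leaves[0])

    def test_recovers_root_sequence_at_low_divergence(self, lg_model):
        """Shallow tree (total depth ~0.3 subs/site): >= 90% of root
        residues recovered as MAP."""
        tree = simulate_timetree(8, 1.0, seed=4)
        rate_tree = simulate_branch_rates(
            tree, RateProcess(root_rate=0.15, sigma2=0.0), seed=5
        )
        aln, states = simulate_alignment(
            rate_tree, lg_model, 500, seed=7, return_states=True
        )
        root_seq = "".join(AA_ORDER[s] for s in states[rate_tree.root])
        rec = marginal_asr(aln, rate_tree, lg_model, rate_tree.root)
        agree = np.mean([x == y for x, y in zip(rec.map_sequence, root_seq)])
        assert agree >= 0.90

    def test_pp_of_truth_higher_at_lower_divergence(self, lg_model):
        """Mean PP of the true root residue increases as branches shorten."""
        wins = 0
        n_pairs = 8
        for seed in range(n_pairs):
            tree = simulate_timetree(6, 1.0, seed=50 + seed)
            means = {}
            for rate in (0.05, 0.5):
                t = tree.copy()
                t.branch_rate[:] = rate
                aln, states = simulate_alignment(
                    t, lg_model, 300, seed=60 + seed, return_states=True
                )
                root_states = states[t.root]
                rec = marginal_asr(aln, t, lg_model, t.root)
                means[rate] = rec.posterior[
                    np.arange(300), root_states
                ].mean()
            if means[0.05] > means[0.5]:
                wins += 1
        assert wins >= 7  # paired comparison, overwhelming majority


class TestIndelReconstruction:
    def _tree_and_aln(self, rows):
        from paleoclock.trees import TimeTree

        tree = TimeTree(
            parent=[4, 4, 5, 5, 6, 6, NO_PARENT],
            age=[0, 0, 0, 0, 1.0, 1.0, 2.0],
            names=["a", "b", "c", "d", None, None, None],
        )
        tree.branch_rate[:] = 0.2
        return tree, Alignment(rows)

    @pytest.mark.parametrize("mode", ["ML", "PARSIMONY"])
    def test_all_gapped_site_absent(self, mode):
        tree, aln = self._tree_and_aln(
            [("a", "-A"), ("b", "-A"), ("c", "-A"), ("d", "-A")]
        )
        mask = reconstruct_indels(aln, tree, 6, mode=mode)
        assert not mask[0] and mask[1]

    @pytest.mark.parametrize("mode", ["ML", "PARSIMONY"])
    def test_all_present_site_present(self, mode):
        tree, aln = self._tree_and_aln(
            [("a", "AA"), ("b", "AA"), ("c", "AA"), ("d", "AA")]
        )
        assert reconstruct_indels(aln, tree, 6, mode=mode).all()

    def test_fitch_hand_trace(self):
        """Gaps in one sister pair only: root set is the union {absent,
        present}; the tie resolves to present.  The gapped cherry's parent
        is unambiguously absent."""
        tree, aln = self._tree_and_aln(
            [("a", "-"), ("b", "-"), ("c", "A"), ("d", "A")]
        )
        assert reconstruct_indels(aln, tree, 6, mode="PARSIMONY")[0]
        assert not reconstruct_indels(aln, tree, 4, mode="PARSIMONY")[0]
        assert reconstruct_indels(aln, tree, 5, mode="PARSIMONY")[0]

    def test_cutoff_validation(self):
        tree, aln = self._tree_and_aln(
            [("a", "A"), ("b", "A"), ("c", "A"), ("d", "A")]
        )
        with pytest.raises(ValueError):
            reconstruct_indels(aln, tree, 6, cutoff=0.0)

    def test_ml_cutoff_monotone(self):
        """Raising the cutoff can only turn present sites absent."""
        tree, aln = self._tree_and_aln(
            [("a", "-A"), ("b", "A-"), ("c", "AA"), ("d", "-A")]
        )
        loose = reconstruct_indels(aln, tree, 6, mode="ML", cutoff=0.3)
        strict = reconstruct_indels(aln, tree, 6, mode="ML", cutoff=0.9)
        assert np.all(strict <= loose)


class TestReferenceMapping:
    def test_hand_count(self):
        aln = Alignment([("ref", "A-CD"), ("x", "ARCD")])
        assert map_reference_site(aln, "ref", 2) == 2
        assert map_reference_site(aln, "ref", 1) == 0

    def test_inverse_and_round_trip(self):
        aln = Alignment([("ref", "A-CD-E"), ("x", "ARCDRE")])
        for pos in range(1, 5):
            col = map_reference_site(aln, "ref", pos)
            residue, back = map_column_to_reference(aln, "ref", col)
            assert back == pos
        assert map_column_to_reference(aln, "ref", 1) is None

    def test_out_of_range(self):
        aln = Alignment([("ref", "A-CD")])
        with pytest.raises(IndexError):
            map_reference_site(aln, "ref", 4)


class TestCompareReconstructions:
    def _rec(self, seq, mask=None):
        from paleoclock.asr import AncestralReconstruction

        n = len(seq)
        post = np.full((n, 20), 1e-4)
        for i, ch in enumerate(seq):
            if ch != "-":
                post[i, AA_ORDER.index(ch)] = 1.0
        post /= post.sum(axis=1, keepdims=True)
        if mask is None:
            mask = np.array([ch != "-" for ch in seq])
        return AncestralReconstruction(0, post, seq, mask, "toy")

    def test_identical_pair(self):
        r = compare_reconstructions([self._rec("ARND"), self._rec("ARND")])
        assert r.mean_identity == 1.0
        assert r.sd_identity == 0.0

    def test_one_of_ten_differs(self):
        a = self._rec("AAAAAAAAAA")
        b = self._rec("AAAAAAAAAT")
        r = compare_reconstructions([a, b])
        assert r.mean_identity == pytest.approx(0.9)

    def test_reference_reduces_to_pairwise_identity(self):
        from paleoclock import pairwise_identity

        a = self._rec("ARND-QE")
        ref = "ARNDCQE"
        r = compare_reconstructions([a], reference_sequence=ref)
        assert r.mean_identity == pytest.approx(
            pairwise_identity("ARND-QE", ref)
        )
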