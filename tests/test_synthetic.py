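import numpy as np
import pytest

from paleoclock import (
    RateProcess,
    SubstitutionModel,
    envelope_r0_for_nu_max,
    exponential_rate_envelope,
    make_duplication_dataset,
    p_distance,
    simulate_alignment,
    simulate_branch_rates,
    simulate_timetree,
    truth_from_tree,
)
from paleoclock.trees import NO_PARENT, TimeTree, TreeStructureError


class TestSimulateTimetree:
    def test_two_taxa_single_internal_node(self):
        tree = simulate_timetree(2, 3.5, seed=0)
        assert tree.n_leaves == 2
        assert tree.age[tree.root] == pytest.approx(3.5)

    def test_reproducible(self):
        a = simulate_timetree(10, 2.0, seed=5)
        b = simulate_timetree(10, 2.0, seed=5)
        assert np.array_equal(a.parent, b.parent)
        assert np.allclose(a.age, b.age)

    @pytest.mark.parametrize("mode", ["coalescent", "uniform"])
    def test_invariants(self, mode):
        tree = simulate_timetree(12, 4.0, seed=7, age_distribution=mode)
        tree.validate(require_rates=False)
        internal_ages = tree.age[tree.internal_nodes]
        assert np.all(internal_ages > 0)
        assert internal_ages.max() == pytest.approx(4.0)
        for leaf in tree.leaves:
            assert tree.age[leaf] == 0.0

    def test_n_taxa_below_two_rejected(self):
        with pytest.raises(ValueError):
            simulate_timetree(1, 1.0, seed=0)


class TestSimulateBranchRates:
    def test_sigma2_zero_gives_root_rate_everywhere(self):
        tree = simulate_timetree(6, 2.0, seed=1)
        out = simulate_branch_rates(
            tree, RateProcess(root_rate=0.7, sigma2=0.0), seed=2
        )
        for v in range(out.n_nodes):
            if out.parent[v] != NO_PARENT:
                assert out.branch_rate[v] == pytest.approx(0.7)

    def test_log_rate_variance_grows_like_sigma2_times_depth(self):
        """Monte Carlo: var(log r at a leaf) ~ sigma2 * time from root."""
        tree = simulate_timetree(2, 1.5, seed=3)
        sigma2 = 0.4
        proc = RateProcess(root_rate=1.0, sigma2=sigma2)
        leaf = tree.leaves[0]
        n_rep = 10_000
        draws = np.empty(n_rep)
        for i in range(n_rep):
            out = simulate_branch_rates(tree, proc, seed=i)
            draws[i] = out.node_log_rate[leaf]
        expected_var = sigma2 * 1.5
        observed = draws.var(ddof=1)
        se = expected_var * np.sqrt(2.0 / (n_rep - 1))
        assert abs(observed - expected_var) < 3 * se

    def test_uncorrelated_rates_positive(self):
        tree = simulate_timetree(6, 2.0, seed=1)
        out = simulate_branch_rates(
            tree, RateProcess(kind="uncorrelated-gamma", shape=2, scale=0.3),
            seed=4,
        )
        out.validate(require_rates=True)


class TestSimulateAlignment:
    def test_zero_rates_copy_root(self):
        tree = simulate_timetree(5, 1.0, seed=2)
        tree.branch_rate[:] = 1e-12
        model = SubstitutionModel("POISSON", n_categories=1)
        aln = simulate_alignment(tree, model, 50, seed=3)
        seqs = {s for _, s in aln.records}
        assert len(seqs) == 1

    def test_poisson_expected_p_distance(self):
        """2 taxa at total distance 0.5 under the 20-state equal-rates chain:
        expected p = (19/20)(1 - exp(-(20/19) * 0.5)) = 0.3771."""
        tree = simulate_timetree(2, 1.0, seed=4)
        tree.branch_rate[:] = 0.25
        model = SubstitutionModel("POISSON", n_categories=1)
        aln = simulate_alignment(tree, model, 100_000, seed=5)
        p, n = p_distance(aln.records[0][1], aln.records[1][1])
        expected = (19 / 20) * (1 - np.exp(-(20 / 19) * 0.5))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(p - expected) < 3 * se

    def test_two_state_pattern_frequencies_match_transition_probs(self):
        """Site-pattern frequencies on a 2-taxon JTT tree agree with the
        analytic joint pi_a P_ab(d)."""
        model = SubstitutionModel("JTT", n_categories=1)
        tree = simulate_timetree(2, 1.0, seed=6)
        tree.branch_rate[:] = 0.15  # d = 0.3
        n_sites = 100_000
        aln = simulate_alignment(tree, model, n_sites, seed=7)
        a = model.encode(aln.records[0][1])
        b = model.encode(aln.records[1][1])
        pi = model.equilibrium_frequencies()
        p = model.transition_matrix(0.3)
        joint = pi[:, None] * p
        counts = np.zeros((20, 20))
        np.add.at(counts, (a, b), 1)
        expected = joint * n_sites
        # chi-square goodness of fit over well-populated pattern cells
        mask = expected >= 5
        chi2 = ((counts[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        from scipy.stats import chi2 as chi2_dist

        dof = mask.sum() - 1
        p_value = chi2_dist.sf(chi2, dof)
        assert p_value > 1e-3

    def test_reproducible(self):
        tree = simulate_timetree(4, 1.0, seed=8)
        tree.branch_rate[:] = 0.5
        model = SubstitutionModel("LG", gamma_shape=1.0)
        a = simulate_alignment(tree, model, 100, seed=9)
        b = simulate_alignment(tree, model, 100, seed=9)
        assert a.records == b.records


class TestDuplicationDataset:
    def _make(self, seed=13, ratio_target=5.0):
        species = simulate_timetree(6, 2.3, seed=seed)
        model = SubstitutionModel("LG", gamma_shape=1.0)
        env = dict(
            r0=envelope_r0_for_nu_max(ratio_target * 0.25, 0.6, 3.0, 0.25),
            decay_rate=3.0,
            plateau=0.25,
        )
        return make_duplication_dataset(
            species, 2.9, RateProcess(), model, 60, seed=seed, envelope=env
        )

    def test_delta_t_is_exact_construction(self):
        _, truth, _ = self._make()
        assert truth.delta_t == pytest.approx(2.9 - 2.3)

    def test_leaf_count_doubles(self):
        aln, _, tree = self._make()
        assert aln.n_sequences == 12
        assert tree.n_leaves == 12
        names = set(aln.identifiers)
        assert any(n.endswith("_A") for n in names)
        assert any(n.endswith("_B") for n in names)

    def test_sigma2_zero_flat_rates_ratio_one(self):
        species = simulate_timetree(5, 2.3, seed=3)
        model = SubstitutionModel("POISSON", n_categories=1)
        proc = RateProcess(root_rate=0.5, sigma2=0.0)
        _, truth, _ = self._make_with(species, proc, model)
        assert truth.nu_max == pytest.approx(0.5)
        assert truth.nu_min == pytest.approx(0.5)
        assert truth.ratio == pytest.approx(1.0)

    @staticmethod
    def _make_with(species, proc, model):
        return make_duplication_dataset(
            species, 3.1, proc, model, 30, seed=1
        )

    def test_truth_recomputable_from_tree(self):
        _, truth, rate_tree = self._make()
        again = truth_from_tree(rate_tree, truth.proterozoic_cutoff)
        assert again == truth

    def test_dup_age_must_exceed_species_root(self):
        species = simulate_timetree(4, 2.3, seed=2)
        with pytest.raises(ValueError):
            make_duplication_dataset(
                species, 2.0, RateProcess(), SubstitutionModel(), 10, seed=1
            )


class TestExponentialEnvelope:
    def test_branch_rates_are_time_averages(self):
        tree = simulate_timetree(4, 2.0, seed=10)
        out = exponential_rate_envelope(tree, r0=5.0, decay_rate=2.0,
                                        plateau=0.2)
        lam, r0, plat = 2.0, 5.0, 0.2
        t_root = out.age[out.root]
        for v in range(out.n_nodes):
            if out.parent[v] == NO_PARENT:
                continue
            a, b = out.age[v], out.age[out.parent[v]]
            grid = np.linspace(a, b, 4001)
            numeric = np.trapezoid(
                plat + (r0 - plat) * np.exp(-lam * (t_root - grid)), grid
            ) / (b - a)
            assert out.branch_rate[v] == pytest.approx(numeric, rel=1e-6)

    def test_r0_inversion_hits_target_nu_max(self):
        species = simulate_timetree(5, 2.3, seed=11)
        target = 1.6
        r0 = envelope_r0_for_nu_max(target, 0.7, 3.0, 0.25)
        _, truth, _ = make_duplication_dataset(
            species, 3.0, RateProcess(),
            SubstitutionModel("POISSON", n_categories=1), 20, seed=2,
            envelope=dict(r0=r0, decay_rate=3.0, plateau=0.25),
        )
        assert truth.nu_max == pytest.approx(target, rel=1e-9)
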