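import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from paleoclock import (
    Alignment,
    Calibration,
    ClockSettings,
    RateProcess,
    SubstitutionModel,
    calibration_logprior,
    pruning_loglik,
    rate_logprior,
    run_mcmc,
    extract_rate_profile,
    simulate_alignment,
    simulate_branch_rates,
    simulate_timetree,
)
from paleoclock.clock import CalibrationError, PruningEngine
from paleoclock.trees import NO_PARENT, TimeTree


def brute_force_loglik(aln, tree, subs, model):
    """Enumeration oracle: sum over all interior-state assignments."""
    pi = model.equilibrium_frequencies()
    cat_rates = model.category_rates()
    enc = {i: model.encode(s) for i, s in aln.records}
    internals = tree.internal_nodes
    total = 0.0
    for site in range(aln.length):
        site_lik = 0.0
        for r in cat_rates:
            p = {
                v: model.transition_matrix(subs[v], r)
                for v in range(tree.n_nodes)
                if tree.parent[v] != NO_PARENT
            }
            for assign in itertools.product(range(20), repeat=len(internals)):
                st = dict(zip(internals, assign))
                ok = True
                for leaf in tree.leaves:
                    code = enc[tree.names[leaf]][site]
                    if code < 0:
                        st[leaf] = None  # missing: summed below
                    else:
                        st[leaf] = code
                lik = pi[st[tree.root]]
                for v in range(tree.n_nodes):
                    if tree.parent[v] == NO_PARENT:
                        continue
                    parent_state = st[tree.parent[v]]
                    if st[v] is None:
                        lik *= 1.0  # marginalises to 1 over missing leaf
                    else:
                        lik *= p[v][parent_state, st[v]]
                site_lik += lik / len(cat_rates)
        total += np.log(site_lik)
    return total


def random_subs(tree, rng):
    subs = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if tree.parent[v] != NO_PARENT:
            subs[v] = rng.uniform(0.01, 1.5)
    return subs


class TestPruningLoglik:
    def test_zero_branches_identical_leaves(self, poisson_model):
        tree = simulate_timetree(2, 1.0, seed=0)
        aln = Alignment([(tree.names[l], "A") for l in tree.leaves])
        subs = np.zeros(tree.n_nodes)
        ll = pruning_loglik(aln, tree, subs, poisson_model)
        assert ll == pytest.approx(np.log(1 / 20))

    def test_all_gap_column_contributes_zero(self, poisson_model):
        tree = simulate_timetree(3, 1.0, seed=1)
        rng = np.random.default_rng(2)
        subs = random_subs(tree, rng)
        aln1 = Alignment([(tree.names[l], "AR") for l in tree.leaves])
        aln2 = Alignment([(tree.names[l], "AR-") for l in tree.leaves])
        ll1 = pruning_loglik(aln1, tree, subs, poisson_model)
        ll2 = pruning_loglik(aln2, tree, subs, poisson_model)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    @pytest.mark.parametrize("n_leaves", [2, 3, 4])
    def test_matches_enumeration_oracle(self, n_leaves):
        """Pruning equals brute-force enumeration over interior states on
        small trees across random parameter draws (tolerance 1e-10)."""
        rng = np.random.default_rng(7)
        for draw in range(16):
            tree = simulate_timetree(n_leaves, 1.0, seed=100 + draw)
            matrix = ["POISSON", "JTT", "WAG", "LG"][draw % 4]
            model = SubstitutionModel(
                matrix,
                gamma_shape=float(rng.uniform(0.3, 2.0)),
                n_categories=1 + (draw % 3),
            )
            tree.branch_rate[:] = 0.5
            aln = simulate_alignment(tree, model, 3, seed=200 + draw)
            if draw % 4 == 0:  # splice gaps in to exercise missing data
                recs = [
                    (i, s[:1] + "-" + s[2:]) if k == 0 else (i, s)
                    for k, (i, s) in enumerate(aln.records)
                ]
                aln = Alignment(recs)
            subs = random_subs(tree, rng)
            ll = pruning_loglik(aln, tree, subs, model)
            oracle = brute_force_loglik(aln, tree, subs, model)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_child_order(self, lg_model):
        tree = simulate_timetree(5, 1.0, seed=3)
        rng = np.random.default_rng(4)
        tree.branch_rate[:] = 0.4
        aln = simulate_alignment(tree, lg_model, 40, seed=5)
        subs = random_subs(tree, rng)
        ll = pruning_loglik(aln, tree, subs, lg_model)
        flipped = tree.copy()
        for v in flipped.internal_nodes:
            flipped.children[v] = list(reversed(flipped.children[v]))
        flipped._postorder = None
        ll_flipped = pruning_loglik(aln, flipped, subs, lg_model)
        assert ll == pytest.approx(ll_flipped, abs=1e-12)

    def test_missing_leaf_sequence_raises(self, poisson_model):
        tree = simulate_timetree(3, 1.0, seed=6)
        aln = Alignment([("unrelated", "A")])
        with pytest.raises(KeyError):
            pruning_loglik(aln, tree, np.zeros(tree.n_nodes), poisson_model)


class TestEngineIncrementalUpdates:
    def test_mixed_proposals_match_fresh_recompute(self, lg_model):
        """Randomised accept/reject sequences leave the cache exact."""
        from paleoclock.substitution import discrete_gamma_rates

        rng = np.random.default_rng(11)
        tree = simulate_timetree(9, 2.0, seed=12)
        rate_tree = simulate_branch_rates(
            tree, RateProcess(root_rate=0.5, sigma2=0.3), seed=13
        )
        aln = simulate_alignment(rate_tree, lg_model, 60, seed=14)
        subs = np.array(
            [
                rate_tree.branch_subs(v) if rate_tree.parent[v] != NO_PARENT
                else 0.0
                for v in range(rate_tree.n_nodes)
            ]
        )
        engine = PruningEngine(aln, rate_tree, lg_model)
        engine.initialise(subs)
        shape = lg_model.gamma_shape
        for _ in range(60):
            if rng.random() < 0.15:
                shape_new = shape * float(np.exp(rng.normal(0, 0.2)))
                ll = engine.propose(
                    {}, discrete_gamma_rates(shape_new, lg_model.n_categories)
                )
                fresh_model = SubstitutionModel(
                    "LG", gamma_shape=shape_new, n_categories=4
                )
                assert ll == pytest.approx(
                    pruning_loglik(aln, rate_tree, subs, fresh_model), abs=1e-8
                )
                if rng.random() < 0.5:
                    engine.accept()
                    shape = shape_new
                else:
                    engine.reject()
                continue
            v = int(rng.integers(0, rate_tree.n_nodes))
            changes = {}
            if rate_tree.parent[v] != NO_PARENT:
                changes[v] = subs[v] * float(np.exp(rng.normal(0, 0.3)))
            for c in rate_tree.children[v]:
                changes[c] = subs[c] * float(np.exp(rng.normal(0, 0.3)))
            if not changes:
                continue
            ll = engine.propose(changes)
            trial = subs.copy()
            for node, t in changes.items():
                trial[node] = t
            fresh_model = SubstitutionModel("LG", gamma_shape=shape,
                                            n_categories=4)
            assert ll == pytest.approx(
                pruning_loglik(aln, rate_tree, trial, fresh_model), abs=1e-8
            )
            if rng.random() < 0.5:
                engine.accept()
                subs = trial
            else:
                engine.reject()


class TestCalibrations:
    def test_hard_bounds(self):
        cal = Calibration("root", 2.0, 3.0, "HARD")
        assert calibration_logprior(2.5, cal) == 0.0
        assert calibration_logprior(1.9, cal) == -np.inf
        assert calibration_logprior(3.1, cal) == -np.inf

    def test_soft_two_sided_tail_masses(self):
        """Quadrature: exactly 2.5% of prior mass sits beyond each bound."""
        cal = Calibration("root", 3.41, 4.52, "SOFT")
        below, _ = quad(cal.density, -30, 3.41, limit=300)
        above, _ = quad(cal.density, 4.52, 100, limit=300)
        inside, _ = quad(cal.density, 3.41, 4.52, limit=300)
        assert below == pytest.approx(0.025, abs=1e-6)
        assert above == pytest.approx(0.025, abs=1e-6)
        assert inside == pytest.approx(0.95, abs=1e-6)

    def test_soft_one_sided_minimum_mass(self):
        cal = Calibration("root", min_age=3.0, bounds="SOFT", span=1.5)
        below, _ = quad(cal.density, -40, 3.0, limit=300)
        total, _ = quad(cal.density, -40, 3.0 + 1.5, limit=300)
        assert below == pytest.approx(0.05, abs=1e-6)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_density_continuous_at_bounds(self):
        cal = Calibration("root", 2.0, 4.0, "SOFT")
        eps = 1e-9
        assert cal.density(2.0 - eps) == pytest.approx(cal.density(2.0 + eps),
                                                       rel=1e-6)
        assert cal.density(4.0 - eps) == pytest.approx(cal.density(4.0 + eps),
                                                       rel=1e-6)

    def test_cdf_matches_quadrature(self):
        cal = Calibration("root", 2.0, 4.0, "SOFT")
        for x in (1.5, 2.0, 2.7, 4.0, 4.4):
            numeric, _ = quad(cal.density, -30, x, limit=300)
            assert cal.cdf(x) == pytest.approx(numeric, abs=1e-7)

    def test_invalid_interval_rejected(self):
        with pytest.raises(CalibrationError):
            Calibration("root", 3.0, 2.0)
        with pytest.raises(CalibrationError):
            Calibration("root")


class TestRatePrior:
    def test_constant_rate_closed_form(self):
        tree = simulate_timetree(5, 2.0, seed=8)
        tree.node_log_rate[:] = np.log(0.7)
        for v in range(tree.n_nodes):
            if tree.parent[v] != NO_PARENT:
                tree.branch_rate[v] = 0.7
        sigma2 = 0.3
        expected = sum(
            -0.5 * np.log(2 * np.pi * sigma2 * tree.branch_duration(v))
            for v in range(tree.n_nodes)
            if tree.parent[v] != NO_PARENT
        )
        got = rate_logprior(tree, "autocorrelated-lognormal", sigma2=sigma2)
        assert got == pytest.approx(expected)

    def test_density_decreasing_in_sigma2_beyond_mode(self):
        tree = simulate_timetree(5, 2.0, seed=9)
        rate_tree = simulate_branch_rates(
            tree, RateProcess(root_rate=0.5, sigma2=0.2), seed=10
        )
        vals = [
            rate_logprior(rate_tree, "autocorrelated-lognormal", sigma2=s)
            for s in (5.0, 50.0, 500.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_uncorrelated_reduces_to_gamma_logpdf_sum(self):
        from scipy.stats import gamma as gamma_dist

        tree = simulate_timetree(4, 1.0, seed=11)
        rate_tree = simulate_branch_rates(
            tree, RateProcess(kind="uncorrelated-gamma", shape=2.0, scale=0.4),
            seed=12,
        )
        rates = [
            rate_tree.branch_rate[v]
            for v in range(rate_tree.n_nodes)
            if rate_tree.parent[v] != NO_PARENT
        ]
        expected = gamma_dist.logpdf(rates, a=2.0, scale=0.4).sum()
        got = rate_logprior(rate_tree, "uncorrelated-gamma", shape=2.0,
                            scale=0.4)
        assert got == pytest.approx(expected)


class TestRunMcmc:
    def test_identical_seeds_bit_identical(self, lg_model):
        tree = simulate_timetree(4, 2.0, seed=20)
        rate_tree = simulate_branch_rates(
            tree, RateProcess(root_rate=0.5, sigma2=0.0), seed=21
        )
        aln = simulate_alignment(rate_tree, lg_model, 30, seed=22)
        cal = [Calibration("root", 1.8, 2.2, "SOFT")]
        settings = ClockSettings(model=lg_model, n_chains=2, n_iterations=60,
                                 burn_in=0.25, thinning=2, seed=31)
        a = run_mcmc(aln, tree, cal, settings)
        b = run_mcmc(aln, tree, cal, settings)
        for name in ("ages", "log_rates", "sigma2", "log_posterior"):
            assert np.array_equal(a.pooled(name), b.pooled(name))

    def test_uniform_prior_needs_root_calibration(self, lg_model):
        tree = simulate_timetree(3, 1.0, seed=23)
        settings = ClockSettings(model=lg_model, likelihood=False,
                                 n_chains=2, n_iterations=10, seed=0)
        with pytest.raises(CalibrationError):
            run_mcmc(None, tree, [], settings)

    def test_infeasible_hard_calibrations_detected(self, lg_model):
        tree = simulate_timetree(4, 2.0, seed=24)
        # leaves below a non-root internal node form a proper sub-clade
        inner = [v for v in tree.internal_nodes if v != tree.root][0]
        sub_clade = [tree.names[l] for l in tree.clade_leaves(inner)]
        cals = [
            Calibration("root", 1.0, 1.5, "HARD"),
            Calibration(tuple(sub_clade), min_age=1.8, max_age=2.5,
                        bounds="HARD"),
        ]
        settings = ClockSettings(model=lg_model, likelihood=False,
                                 n_chains=2, n_iterations=10, seed=0)
        with pytest.raises(CalibrationError, match="feasible"):
            run_mcmc(None, tree, cals, settings)

    def test_stored_states_satisfy_invariants(self, lg_model):
        tree = simulate_timetree(5, 2.0, seed=25)
        rate_tree = simulate_branch_rates(
            tree, RateProcess(root_rate=0.5, sigma2=0.1), seed=26
        )
        aln = simulate_alignment(rate_tree, lg_model, 40, seed=27)
        cal = [Calibration("root", 1.8, 2.2, "SOFT")]
        settings = ClockSettings(model=lg_model, n_chains=2, n_iterations=80,
                                 burn_in=0.25, thinning=4, seed=5)
        chains = run_mcmc(aln, tree, cal, settings)
        ages = chains.pooled("ages")
        rates = chains.pooled("branch_rates")
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p == NO_PARENT:
                continue
            assert np.all(ages[:, p] > ages[:, v])
            assert np.all(rates[:, v] > 0)


class TestExtractRateProfile:
    def test_single_draw_profile_equals_that_draw(self, lg_model):
        tree = simulate_timetree(4, 2.0, seed=28)
        rate_tree = simulate_branch_rates(
            tree, RateProcess(root_rate=0.5, sigma2=0.0), seed=29
        )
        aln = simulate_alignment(rate_tree, lg_model, 20, seed=30)
        cal = [Calibration("root", 1.8, 2.2, "SOFT")]
        settings = ClockSettings(model=lg_model, n_chains=2, n_iterations=4,
                                 burn_in=0.5, thinning=2, seed=6)
        chains = run_mcmc(aln, tree, cal, settings)
        assert chains.n_draws == 1
        profile = extract_rate_profile(chains)
        pooled = chains.pooled("branch_rates")
        for i, v in enumerate(profile.nodes):
            assert profile.rate[i] == pytest.approx(pooled[:, v].mean())
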