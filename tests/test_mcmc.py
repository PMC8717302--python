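"""Sampler plumbing, diagnostics, moment oracle and posterior aggregation.

The heavier statistical validations (prior recovery, parameter recovery,
strong-signal delimitation) live in the acceptance suite; here the chains
are short and check contracts: determinism, constraint maintenance,
trace shapes, and the small closed-form oracles.
"""

import numpy as np
import pytest

from mscdelim.io import IndividualMap, LocusAlignment
from mscdelim.mcmc import (
    DelimitationModel,
    GuideTreeDelimitation,
    McmcConfig,
    MscModel,
    aggregate_model_posteriors,
    ess,
    moment_estimates,
    run_a00,
)
from mscdelim.simulate import Scenario, generate_dataset, scenario


@pytest.fixture(scope="module")
def small_three_species():
    scn = Scenario(
        name="small3", n_species=3, samples_per_species=2, n_loci=20,
        theta=0.005, tau_root=0.01,
    )
    return generate_dataset(scn, seed=17)


SMALL = McmcConfig(
    iterations=2200, thin=2, theta_prior_mean=0.005, tau_prior_mean=0.01, seed=5
)


class TestA00Contracts:
    def test_same_seed_identical_trace(self, small_three_species):
        loci, imap, truth = small_three_species
        a = run_a00(loci, imap, truth.guide_tree, SMALL)
        b = run_a00(loci, imap, truth.guide_tree, SMALL)
        assert np.array_equal(a.tau, b.tau)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.loglik, b.loglik)

    def test_trace_length_and_positivity(self, small_three_species):
        loci, imap, truth = small_three_species
        t = run_a00(loci, imap, truth.guide_tree, SMALL)
        burnin = SMALL.resolved_burnin()
        assert t.n_samples == (SMALL.iterations - burnin) // SMALL.thin
        assert np.all(t.theta > 0)

    def test_tau_ordering_never_violated(self, small_three_species):
        loci, imap, truth = small_three_species
        t = run_a00(loci, imap, truth.guide_tree, SMALL)
        st = t.species_tree
        for v in range(st.n_nodes):
            p = st.parent[v]
            if p >= 0 and not st.is_tip(v):
                assert np.all(t.tau[:, p] > t.tau[:, v])
            if st.is_tip(v):
                assert np.all(t.tau[:, v] == 0)

    def test_multi_run_distinct_streams(self, small_three_species):
        loci, imap, truth = small_three_species
        cfg = McmcConfig(
            iterations=1100, thin=2, theta_prior_mean=0.005,
            tau_prior_mean=0.01, seed=5, n_runs=2,
        )
        res = MscModel(loci, imap, truth.guide_tree, cfg).fit()
        assert len(res.traces) == 2
        assert res.traces[0].seed != res.traces[1].seed
        assert not np.array_equal(res.traces[0].tau, res.traces[1].tau)

    def test_between_run_spread_shrinks_with_length(self, small_three_species):
        """Posterior-mean variability across runs drops as chains lengthen."""
        loci, imap, truth = small_three_species
        spreads = []
        for iters in (600, 9600):
            cfg = McmcConfig(
                iterations=iters, thin=2, theta_prior_mean=0.005,
                tau_prior_mean=0.01, seed=31, n_runs=3, use_likelihood=False,
            )
            res = MscModel(loci, imap, truth.guide_tree, cfg).fit()
            st = res.trace.species_tree
            means = [t.tau[:, st.root].mean() for t in res.traces]
            spreads.append(np.std(means))
        assert spreads[1] < spreads[0]

    def test_species_tree_imap_mismatch_rejected(self, small_three_species):
        loci, imap, truth = small_three_species
        bad = IndividualMap({k: "ZZ" for k in imap.assignments})
        with pytest.raises(ValueError):
            MscModel(loci, bad, truth.guide_tree)

    def test_summary_lists_all_parameters(self, small_three_species):
        loci, imap, truth = small_three_species
        res = MscModel(loci, imap, truth.guide_tree, SMALL).fit()
        df = res.summary_frame()
        st = truth.guide_tree
        # one theta per population, one tau per internal node, plus lnL
        assert len(df) == st.n_nodes + (st.n_tips - 1) + 1
        assert "ess" in df.columns
        assert "theta_A" in df.index

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burnin=200)
        with pytest.raises(ValueError):
            McmcConfig(theta_prior_mean=0.0)


class TestA10Contracts:
    def test_posteriors_normalized_and_closed(self, small_three_species):
        loci, imap, truth = small_three_species
        cfg = McmcConfig(
            iterations=2000, burnin=400, thin=2, theta_prior_mean=0.005,
            tau_prior_mean=0.01, seed=3,
        )
        res = GuideTreeDelimitation(loci, imap, truth.guide_tree, cfg).fit()
        total = sum(m.posterior for m in res.models)
        assert total == pytest.approx(1.0, abs=1e-12)
        # ancestry closure: a split child implies a split parent
        st = truth.guide_tree
        n_tips = st.n_tips
        for m in res.models:
            flags = dict(zip(range(n_tips, st.n_nodes), m.split_flags))
            for v, f in flags.items():
                p = int(st.parent[v])
                if f and p >= 0:
                    assert flags[p]
            assert m.n_species == 1 + sum(m.split_flags)


class TestEss:
    def test_iid_close_to_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        assert 9_000 <= ess(x) <= 11_000

    def test_ar1_autocorrelation_time(self):
        rng = np.random.default_rng(2)
        rho, n = 0.9, 10_000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.normal()
        expected = n * (1 - rho) / (1 + rho)
        assert abs(ess(x) - expected) / expected < 0.30

    def test_agrees_with_arviz_on_correlated_chain(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        rho, n = 0.9, 10_000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.normal()
        theirs = float(arviz.ess(x))
        assert abs(ess(x) - theirs) / theirs < 0.15

    def test_constant_series_warns_n(self):
        with pytest.warns(UserWarning):
            assert ess(np.ones(100)) == 100.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestMomentEstimates:
    def test_recovers_simulated_truth(self):
        theta, tau = 0.01, 0.005
        scn = Scenario(
            name="mo", n_species=2, samples_per_species=4, n_loci=3000,
            theta=theta, tau_root=tau, locus_length=100,
        )
        loci, imap, _ = generate_dataset(scn, seed=23)
        me = moment_estimates(loci, imap, ("A", "B"))
        assert abs(me.theta_a - theta) / theta < 0.10
        assert abs(me.theta_b - theta) / theta < 0.10
        assert abs(me.tau - tau) / tau < 0.10

    def test_identical_sequences_give_zero(self):
        loci = [LocusAlignment("L", {"a1": "ACGT", "a2": "ACGT", "b1": "ACGT"})]
        imap = IndividualMap({"a1": "A", "a2": "A", "b1": "B"})
        me = moment_estimates(loci, imap, ("A", "B"))
        assert me.theta_a == 0.0 and me.tau == 0.0

    def test_introgression_like_clamped_with_warning(self):
        # between-distance smaller than within: tau clamps to 0
        loci = [
            LocusAlignment(
                "L",
                {"a1": "AAAA", "a2": "CCCC", "b1": "AAAA", "b2": "AAAC"},
            )
        ]
        imap = IndividualMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        with pytest.warns(UserWarning, match="clamped"):
            me = moment_estimates(loci, imap, ("A", "B"))
        assert me.tau == 0.0

    def test_singleton_species_warns(self):
        loci = [LocusAlignment("L", {"a1": "AAGG", "a2": "AAGC", "b1": "CCGG"})]
        imap = IndividualMap({"a1": "A", "a2": "A", "b1": "B"})
        with pytest.warns(UserWarning, match="single sequence"):
            me = moment_estimates(loci, imap, ("A", "B"))
        assert me.theta_b is None and me.theta_a is not None


def model(flags, names, p):
    return DelimitationModel(
        split_flags=flags, node_names=names, n_species=1 + sum(flags), posterior=p
    )


class TestAggregation:
    NAMES = ("n1", "n2")

    def test_mean_across_runs(self):
        runs = [
            [model((True, True), self.NAMES, 0.4), model((True, False), self.NAMES, 0.6)],
            [model((True, True), self.NAMES, 0.6), model((True, False), self.NAMES, 0.4)],
        ]
        agg = aggregate_model_posteriors(runs)
        by_key = {m.key: m.posterior for m in agg.models}
        assert by_key[(True, True)] == pytest.approx(0.5)
        assert by_key[(True, False)] == pytest.approx(0.5)

    def test_absent_model_counts_zero(self):
        runs = [
            [model((True, True), self.NAMES, 1.0)],
            [model((True, False), self.NAMES, 1.0)],
        ]
        agg = aggregate_model_posteriors(runs)
        by_key = {m.key: m.posterior for m in agg.models}
        assert by_key[(True, True)] == pytest.approx(0.5)

    def test_single_run_identity(self):
        run = [model((True, True), self.NAMES, 0.7), model((True, False), self.NAMES, 0.3)]
        agg = aggregate_model_posteriors([run])
        assert {m.key: m.posterior for m in agg.models} == {
            (True, True): 0.7,
            (True, False): 0.3,
        }

    def test_count_marginal_sums_to_one(self):
        runs = [
            [model((True, True), self.NAMES, 0.25), model((False, False), self.NAMES, 0.75)],
            [model((True, False), self.NAMES, 1.0)],
        ]
        agg = aggregate_model_posteriors(runs)
        assert sum(agg.species_count_probs.values()) == pytest.approx(1.0, abs=1e-12)
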