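"""Exactness and reproducibility of the SSA simulators."""

import math

import numpy as np
import pytest
from scipy import stats

from txnoise import (
    CellCycleSpec,
    ConfigurationError,
    GeneParams,
    ModelSpec,
    NoiseSpec,
    ParameterError,
    PopulationSample,
    TelegraphParams,
    propensity_table,
    simulate_cell_cycle,
    simulate_population,
    ssa_snapshot,
    telegraph_pmf,
)
from txnoise.simulator import canonical_param, default_t_end


class TestModelSpecAndParams:
    def test_alias_construction(self):
        p = GeneParams.of(Km=50, Kp=2, delta_m=1, delta_p=0.1)
        assert (p.KN, p.KP, p.deltaM, p.deltaP) == (50, 2, 1, 0.1)
        assert canonical_param("lam1") == "lam"
        with pytest.raises(ConfigurationError):
            canonical_param("KX")

    def test_structural_validation(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("M2", maturation="fixed", delay=0.1)   # no nascent species
        with pytest.raises(ConfigurationError):
            ModelSpec("M4", cell_cycle=CellCycleSpec(rate=1.0))
        with pytest.raises(ConfigurationError):
            ModelSpec("M9")
        with pytest.raises(ParameterError):
            GeneParams.of(KN=-5)

    def test_relaxation_horizon_tracks_protein_lifetime(self):
        m4 = ModelSpec("M4")
        slow = GeneParams.of(lam=1, mu=2, KN=150, KM=10, KP=2, deltaP=0.05)
        fast = GeneParams.of(lam=1, mu=2, KN=150, KM=10, KP=2, deltaP=2.0)
        assert default_t_end(m4, slow) == 200.0
        assert default_t_end(m4, fast) == 15.0
        assert default_t_end(ModelSpec("M1"), GeneParams.of(KN=50, KM=10)) == 15.0


class TestPropensities:
    def test_inactive_gene_does_not_transcribe(self):
        a = propensity_table(ModelSpec("M4"), GeneParams.of(lam=1, mu=2, KN=300, KM=20),
                             (0, 3, 10, 0))
        assert a["transcribe"] == 0.0
        assert a["activate"] == 1.0

    def test_first_order_decay(self):
        a = propensity_table(ModelSpec("M1"), GeneParams.of(KN=50, KM=10, deltaM=1.0),
                             (1, 2, 7, 0))
        assert a["mature-decay"] == 7.0
        assert a["mature"] == 20.0

    def test_multiscale_paused_state_channels(self):
        # from S11 both transcription (KN, back to S10) and shut-off (mu) fire
        a = propensity_table(ModelSpec("MS3"),
                             GeneParams.of(lam=1, mu=2, lam2=5, KN=300, KM=10),
                             (2, 0, 0, 0))
        assert a["transcribe"] == 300.0
        assert a["deactivate"] == 2.0
        assert a["pause"] == 0.0


class TestStationaryMoments:
    def test_m1_product_poisson_law(self, m1_fixed_population):
        # joint stationary law is Poisson(KN/KM) x Poisson(KN/deltaM):
        # marginal means match and the species are uncorrelated
        pop = m1_fixed_population
        n, m = pop.counts("nascent"), pop.counts("mature")
        N = len(pop)
        assert abs(n.mean() - 5.0) < 3 * math.sqrt(5.0 / N)
        assert abs(m.mean() - 50.0) < 3 * math.sqrt(50.0 / N)
        assert abs(np.corrcoef(n, m)[0, 1]) < 3 / math.sqrt(N)

    def test_m2_moments(self):
        # stationary means Km/dm, KpKm/(dm dp) and covariance KmKp/(dm(dm+dp))
        pop = simulate_population(ModelSpec("M2"),
                                  GeneParams.of(Km=50, Kp=2, delta_m=1, delta_p=0.1),
                                  None, n_cells=10_000, seed=99)
        x, y = pop.counts("mature"), pop.counts("protein")
        N = len(x)
        cov = np.cov(x, y, ddof=1)[0, 1]
        expected_cov = 50 * 2 / (1 * 1.1)
        se_cov = math.sqrt((x.var() * y.var() + cov**2) / N)
        assert abs(x.mean() - 50.0) < 3 * x.std() / math.sqrt(N)
        assert abs(y.mean() - 1000.0) < 3 * y.std() / math.sqrt(N)
        assert abs(cov - expected_cov) < 3 * se_cov

    def test_m4_means(self):
        # E[nascent] = KN lam / (KM (lam+mu)), E[mature] = KM/deltaM x that,
        # E[protein] = KP/deltaP x E[mature]
        pop = simulate_population(ModelSpec("M4"),
                                  GeneParams.of(lam=1, mu=2, KN=150, KM=10,
                                                KP=2, deltaM=1, deltaP=0.1),
                                  None, n_cells=3000, seed=5)
        assert pop.counts("nascent").mean() == pytest.approx(5.0, rel=0.05)
        assert pop.counts("mature").mean() == pytest.approx(50.0, rel=0.05)
        assert pop.counts("protein").mean() == pytest.approx(1000.0, rel=0.05)

    def test_m4_mature_marginal_matches_telegraph_law(self):
        # with fast maturation the mature marginal is the two-state mRNA law;
        # goodness-of-fit links the simulator and the analytic layer
        pop = simulate_population(ModelSpec("M4"),
                                  GeneParams.of(lam=2, mu=4, KN=60, KM=200, deltaM=1),
                                  None, n_cells=3000, seed=17)
        m = pop.counts("mature")
        nmax = int(m.max())
        expected = telegraph_pmf(np.arange(nmax + 1), TelegraphParams(2, 4, 60))
        observed = np.bincount(m, minlength=nmax + 1).astype(float)
        # pool bins to expected counts >= 5 for a valid chi-square test
        exp_counts = expected * len(m)
        order = np.argsort(-exp_counts)
        obs_p, exp_p = [], []
        acc_o = acc_e = 0.0
        for i in order:
            acc_o += observed[i]
            acc_e += exp_counts[i]
            if acc_e >= 5:
                obs_p.append(acc_o)
                exp_p.append(acc_e)
                acc_o = acc_e = 0.0
        obs_p[-1] += acc_o
        exp_p[-1] += acc_e
        obs_p, exp_p = np.array(obs_p), np.array(exp_p)
        exp_p *= obs_p.sum() / exp_p.sum()
        stat, pval = stats.chisquare(obs_p, exp_p)
        assert pval > 1e-3


class TestMaturationDelays:
    @pytest.mark.parametrize("spec", [
        ModelSpec("M1", maturation="fixed", delay=0.1),
        ModelSpec("M1", maturation="erlang", delay=(4, 40.0)),
    ])
    def test_delayed_maturation_means(self, spec):
        # Little's law: mean nascent = KN * mean delay regardless of delay
        # shape; the mature pool still turns over at deltaM
        pop = simulate_population(spec, GeneParams.of(KN=50, deltaM=1.0),
                                  None, n_cells=3000, seed=23)
        n, m = pop.counts("nascent"), pop.counts("mature")
        assert abs(n.mean() - 5.0) < 3 * n.std() / math.sqrt(len(n))
        assert abs(m.mean() - 50.0) < 3 * m.std() / math.sqrt(len(m))


class TestReproducibility:
    @pytest.mark.parametrize("model,params", [
        (ModelSpec("M4"), GeneParams.of(lam=1, mu=2, KN=150, KM=10, KP=2,
                                        deltaM=1, deltaP=0.3)),
        (ModelSpec("M1", maturation="erlang", delay=(3, 30.0)),
         GeneParams.of(KN=50, deltaM=1)),
        (ModelSpec("MS3", maturation="fixed", delay=0.1,
                   cell_cycle=CellCycleSpec(rate=1.0)),
         GeneParams.of(lam=4, mu=2, lam2=50, KN=300, KP=2.5, deltaM=1, deltaP=0.5)),
    ])
    def test_identical_seed_identical_population(self, model, params):
        noise = {"KN": NoiseSpec.gamma(4.0, params.KN / 4.0)}
        a = simulate_population(model, params, noise, 60, dual_reporter=True,
                                seed=31, n_cycles=4)
        b = simulate_population(model, params, noise, 60, dual_reporter=True,
                                seed=31, n_cycles=4)
        assert a.data.equals(b.data)

    def test_single_cell_population(self):
        pop = simulate_population(ModelSpec("M1"), GeneParams.of(KN=50, KM=10),
                                  None, n_cells=1, seed=0)
        assert len(pop) == 1

    def test_snapshot_deterministic(self):
        m = ModelSpec("M4")
        p = GeneParams.of(lam=1, mu=2, KN=150, KM=10, KP=2, deltaM=1, deltaP=0.3)
        assert ssa_snapshot(m, p, seed=7) == ssa_snapshot(m, p, seed=7)


class TestCellCycle:
    MODEL = ModelSpec("MS3", maturation="erlang", delay=(3, 30.0),
                      cell_cycle=CellCycleSpec(rate=1.0))
    PARAMS = GeneParams.of(lam=4, mu=2, lam2=50, KN=300, KP=2.5,
                           deltaM=1, deltaP=0.5)

    def test_replication_doubles_gene_and_compensates_dosage(self):
        post = simulate_cell_cycle(self.MODEL, self.PARAMS, n_cycles=5, seed=3,
                                   sample_phase="post-replication")
        pre = simulate_cell_cycle(self.MODEL, self.PARAMS, n_cycles=5, seed=3,
                                  sample_phase="pre-replication")
        assert post["gene_copies"] == 2
        assert post["lam_eff"] == pytest.approx(0.7 * 4.0)
        assert pre["gene_copies"] == 1
        assert pre["lam_eff"] == pytest.approx(4.0)

    def test_binomial_partitioning_conserves_half_the_mean(self):
        # every molecule survives division independently with probability 1/2
        pres, posts = [], []
        for s in range(40):
            _, pre, post = simulate_cell_cycle(self.MODEL, self.PARAMS,
                                               n_cycles=4, seed=100 + s,
                                               return_divisions=True)
            pres.append(pre)
            posts.append(post)
        pre = np.vstack(pres).astype(float)
        post = np.vstack(posts).astype(float)
        for j, species in enumerate(("nascent", "mature", "protein")):
            tot = pre[:, j].sum()
            if tot < 50:
                continue
            # post | pre ~ Binomial(pre, 1/2): compare against 3 binomial sd
            sd = math.sqrt(tot * 0.25)
            assert abs(post[:, j].sum() - 0.5 * tot) < 3 * sd, species

    def test_cycle_length_is_erlang24(self):
        from txnoise.simulator import _cc_schedule

        rng = np.random.default_rng(5)
        lengths = []
        for _ in range(400):
            times, kinds = _cc_schedule(CellCycleSpec(rate=1.0), 1.0, 3, rng)
            divs = times[kinds == 2]
            lengths.extend(np.diff(np.concatenate([[0.0], divs])))
        lengths = np.asarray(lengths)
        # Erlang(24, 1): mean 24, sd sqrt(24)
        assert abs(lengths.mean() - 24.0) < 3 * lengths.std() / math.sqrt(len(lengths))
        assert lengths.std() == pytest.approx(math.sqrt(24.0), rel=0.15)

    def test_requires_burn_in_cycles(self):
        with pytest.raises(ConfigurationError):
            simulate_cell_cycle(self.MODEL, self.PARAMS, n_cycles=2, seed=0)


class TestPopulationIO:
    def test_round_trip(self, tmp_path, m1_gamma_population):
        path = tmp_path / "pop.csv"
        m1_gamma_population.write(path)
        back = PopulationSample.read(path)
        assert back.data.equals(m1_gamma_population.data)
        assert back.model == m1_gamma_population.model
        assert back.noise == m1_gamma_population.noise

    def test_parameter_columns_reproduce_draws(self, m1_gamma_population):
        # stored per-cell KN column matches an independent re-draw from the
        # same seed tree
        from txnoise import sample_noise

        ss = np.random.SeedSequence(20260917)
        param_child, _ = ss.spawn(2)
        rng = np.random.default_rng(param_child)
        kn = sample_noise(NoiseSpec.gamma(5.0, 10.0), 500, rng)
        np.testing.assert_array_equal(m1_gamma_population.data["KN"], kn)

    def test_noise_mean_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_population(ModelSpec("M1"), GeneParams.of(KN=50, KM=10),
                                {"KN": NoiseSpec.gamma(5.0, 5.0)}, 10, seed=0)

    def test_unknown_noise_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_population(ModelSpec("M1"), GeneParams.of(KN=50, KM=10),
                                {"KX": NoiseSpec.gamma(5.0, 10.0)}, 10, seed=0)
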