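import numpy as np
import pandas as pd
import pytest

from tsrsweep import (
    DFEConfig,
    SimulationConfig,
    rescale_config,
    run_burnin,
    run_replicates,
    run_selection_phase,
)

from conftest import make_tsr_state


class TestRescaleConfig:
    def test_lambda_20_arithmetic(self):
        cfg = SimulationConfig(N=42_000, mu_site=3e-8, rec_site=7.4e-9)
        r = rescale_config(cfg, 20.0)
        assert r.N == 2_100
        assert r.mu_site == pytest.approx(6e-7)
        assert r.rec_site == pytest.approx(1.48e-7)
        assert r.rescale_lambda == 20.0
        # 4*N*mu invariant
        assert 4 * r.N * r.mu_site == pytest.approx(4 * cfg.N * cfg.mu_site)
        assert r.burnin_generations == 21_000
        assert r.sel_generations == cfg.sel_generations
        assert r.survival_ratio == cfg.survival_ratio  # deliberately unscaled

    def test_identity(self):
        cfg = SimulationConfig(N=1_000)
        assert rescale_config(cfg, 1.0) == cfg

    def test_rejects_too_small_population(self):
        with pytest.raises(ValueError, match="below 50"):
            rescale_config(SimulationConfig(N=500), 20.0)


class TestBurnin:
    def test_no_mutation_no_variation(self, template, dfe):
        cfg = SimulationConfig(N=100, mu_site=0.0, seed=3)
        pop = run_burnin(cfg, template, dfe)
        assert pop.n_segregating == 0
        assert pop.generation == 0

    def test_population_size_is_exact(self, template, dfe):
        cfg = SimulationConfig(N=80, seed=5)
        pop = run_burnin(cfg, template, dfe)
        assert pop.pop_offsets.shape[0] == 2 * cfg.N + 1

    def test_burnin_origins_are_preonset(self, template7, dfe):
        cfg = SimulationConfig(N=200, mu_site=1e-4, seed=11)
        pop = run_burnin(cfg, template7, dfe)
        assert len(pop.tsr_registry) > 0
        assert (pop.tsr_registry["origin_generation"] <= 0).all()
        assert (pop.tsr_registry["origin_phase"] == "burnin").all()


class TestSelectionPhase:
    def test_requires_generation_zero(self, template, dfe):
        cfg = SimulationConfig(N=60, seed=1)
        pop = run_burnin(cfg, template, dfe)
        pop.generation = 5
        with pytest.raises(ValueError):
            run_selection_phase(pop, cfg)

    def test_empty_population_stays_empty_without_mutation(self, template7, dfe):
        cfg = SimulationConfig(N=100, mu_site=0.0, seed=2)
        pop = run_burnin(cfg, template7, dfe)
        final, traj = run_selection_phase(pop, cfg, seed=9)
        assert len(traj) == 0
        assert final.aggregate_tsr_frequency() == 0.0

    def test_neutral_drift_is_a_martingale(self, template7, dfe):
        # one neutral TSR origin at frequency 0.5, survival_ratio=1:
        # the ensemble-mean final frequency stays at 0.5
        cfg = SimulationConfig(N=150, mu_site=0.0, survival_ratio=1.0,
                               sel_generations=30, seed=0)
        freqs = []
        for i in range(400):
            st = make_tsr_state(cfg, template7, dfe, count=150)
            fin, _ = run_selection_phase(st, cfg, seed=i)
            c = fin.mutation_counts()
            freqs.append((c[0] if c.shape[0] else 0) / (2 * cfg.N))
        se = np.sqrt(0.25 / len(freqs))  # variance after 30 gens < p(1-p)
        assert abs(np.mean(freqs) - 0.5) < 3 * se

    def test_dominant_carrier_advantage_sweeps(self, template7, dfe):
        # a 20x dominant advantage takes a 1% TSR frequency to near fixation
        # within 30 generations
        cfg = SimulationConfig(N=500, mu_site=0.0, survival_ratio=20.0, seed=0)
        st = make_tsr_state(cfg, template7, dfe, count=10)
        fin, traj = run_selection_phase(st, cfg, seed=42)
        final_freq = traj[traj.generation == 30]["frequency"].sum()
        assert final_freq > 0.9

    def test_ensemble_mean_tsr_frequency_nondecreasing(self, template7, dfe):
        # under herbicide selection the expected aggregate TSR frequency
        # cannot decrease between consecutive generations (tested on the
        # ensemble mean over replicates, not single paths)
        cfg = SimulationConfig(N=120, mu_site=0.0, survival_ratio=20.0,
                               sel_generations=15, seed=0)
        n_rep = 300
        by_gen = np.zeros(16)
        for i in range(n_rep):
            st = make_tsr_state(cfg, template7, dfe, count=3)
            _, traj = run_selection_phase(st, cfg, seed=5_000 + i)
            agg = traj.groupby("generation")["frequency"].sum()
            by_gen += agg.reindex(range(16), fill_value=0.0).to_numpy()
        by_gen /= n_rep
        se = 0.5 / np.sqrt(n_rep)  # crude bound on the per-generation SE
        assert np.all(np.diff(by_gen) > -3 * se)

    def test_trajectory_table_contract(self, template7, dfe):
        cfg = SimulationConfig(N=200, mu_site=1e-5, sel_generations=10, seed=6)
        pop = run_burnin(cfg, template7, dfe)
        _, traj = run_selection_phase(pop, cfg, seed=8)
        assert set(traj.columns) >= {"generation", "origin_id", "frequency", "origin_phase"}
        if len(traj):
            assert traj["generation"].between(0, 10).all()
            assert (traj["frequency"] > 0).all()
            assert (traj["frequency"] <= 1).all()

    def test_de_novo_origins_are_labelled_selection(self, template7, dfe):
        cfg = SimulationConfig(N=300, mu_site=5e-5, sel_generations=20, seed=1)
        pop = run_burnin(SimulationConfig(N=300, mu_site=0.0, seed=1), template7, dfe)
        final, traj = run_selection_phase(pop, cfg, seed=123)
        new = final.tsr_registry
        assert (new["origin_generation"] >= 1).all()
        assert (new["origin_phase"] == "selection").all()


class TestReplicates:
    def test_bitwise_determinism(self, template, dfe):
        cfg = rescale_config(SimulationConfig(N=6_000, seed=0), 20.0)
        a = run_replicates(cfg, template, dfe, n_reps=3, base_seed=77)
        b = run_replicates(cfg, template, dfe, n_reps=3, base_seed=77)
        for (sa, ta), (sb, tb) in zip(a, b):
            assert sa == sb
            pd.testing.assert_frame_equal(ta, tb)

    def test_herbicide_off_classifies_none(self, template7, dfe):
        cfg = SimulationConfig(N=150, mu_site=1e-5, herbicide_on=False, seed=0)
        res = run_replicates(cfg, template7, dfe, n_reps=20, base_seed=5)
        assert all(s.classification == "none" for s, _ in res)

    def test_no_selection_mutation_blocks_de_novo_class(self, template7, dfe):
        cfg = SimulationConfig(N=200, mu_site=2e-5, seed=0,
                               mutation_during_selection=False)
        res = run_replicates(cfg, template7, dfe, n_reps=40, base_seed=9)
        assert all(s.classification in ("sgv", "none") for s, _ in res)

    def test_summary_invariants(self, template7, dfe):
        cfg = SimulationConfig(N=200, mu_site=2e-5, seed=0)
        res = run_replicates(cfg, template7, dfe, n_reps=25, base_seed=3)
        for s, _ in res:
            assert s.n_origins_ever >= s.n_origins_final
            assert (s.classification == "none") == (s.n_origins_final == 0)
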