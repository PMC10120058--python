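import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsrsweep import (
    DFEConfig,
    ReplicateSummary,
    SimulationConfig,
    aggregate,
    classify_replicate,
    neutral_census,
    run_replicates,
)
from tsrsweep.popstats import harmonic_number


def _registry(origins):
    df = pd.DataFrame(
        {"origin_id": list(origins), "site": 0,
         "origin_generation": [origins[o] for o in origins]}
    ).set_index("origin_id")
    df["origin_phase"] = np.where(df["origin_generation"] >= 1, "selection", "burnin")
    return df


def _traj(rows):
    return pd.DataFrame(rows, columns=["generation", "origin_id", "frequency"])


class TestClassifyReplicate:
    def test_standing_origin_classifies_sgv(self):
        reg = _registry({1: -5})
        traj = _traj([(30, 1, 0.8), (0, 1, 0.001)])
        s = classify_replicate(traj, reg, threshold=1e-4, final_generation=30)
        assert s.classification == "sgv"
        assert s.n_origins_final == 1

    def test_mixed_origins_count_as_sgv(self):
        reg = _registry({1: -5, 2: 12})
        traj = _traj([(30, 1, 0.5), (30, 2, 0.3)])
        s = classify_replicate(traj, reg, threshold=1e-4, final_generation=30)
        assert s.classification == "sgv"
        assert s.n_origins_final == 2

    def test_only_selection_origins_classify_de_novo(self):
        reg = _registry({2: 12})
        traj = _traj([(30, 2, 0.3)])
        s = classify_replicate(traj, reg, threshold=1e-4, final_generation=30)
        assert s.classification == "de_novo_only"

    def test_empty_final_generation_is_none(self):
        reg = _registry({1: -5})
        traj = _traj([(5, 1, 0.01)])  # lost before the end
        s = classify_replicate(traj, reg, threshold=1e-4, final_generation=30)
        assert s.classification == "none"
        assert s.n_origins_final == 0
        assert s.n_origins_ever == 1

    def test_threshold_filters_final_presence(self):
        reg = _registry({1: -5})
        traj = _traj([(30, 1, 0.001)])
        s_lo = classify_replicate(traj, reg, threshold=1e-4, final_generation=30)
        s_hi = classify_replicate(traj, reg, threshold=0.05, final_generation=30)
        assert s_lo.classification == "sgv"
        assert s_hi.classification == "none"

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_row_order_invariance(self, rnd):
        reg = _registry({1: -5, 2: 3, 3: 20})
        rows = [(30, 1, 0.5), (30, 2, 0.2), (10, 3, 0.01), (0, 1, 0.001)]
        rnd.shuffle(rows)
        s = classify_replicate(_traj(rows), reg, threshold=1e-4, final_generation=30)
        assert s.classification == "sgv"
        assert s.n_origins_final == 2
        assert s.n_origins_ever == 3

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError):
            classify_replicate(pd.DataFrame({"generation": [1]}), _registry({1: -5}),
                               threshold=0.1, final_generation=30)


class TestAggregate:
    def _summary(self, cls, n_final=1, h="cfg"):
        return ReplicateSummary(0, cls, n_final, n_final, 0.5, 0, h)

    def test_all_none(self):
        rep = aggregate([self._summary("none", 0)] * 10)
        assert rep.proportion_none == 1.0
        assert rep.proportion_sgv == 0.0

    def test_proportions_sum_to_one(self):
        rep = aggregate(
            [self._summary("sgv")] * 3 + [self._summary("de_novo_only")] * 2
            + [self._summary("none", 0)] * 5
        )
        total = rep.proportion_sgv + rep.proportion_de_novo_only + rep.proportion_none
        assert total == pytest.approx(1.0)
        assert rep.origin_histogram == {0: 5, 1: 5}

    def test_mixed_config_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate([self._summary("sgv", h="a"), self._summary("sgv", h="b")])

    def test_sgv_exceeds_de_novo_on_default_protocol(self, template7, dfe):
        # direction of the headline result on a small, fast protocol:
        # standing variation supplies adaptation more often than de novo
        # alone when the standing input 4*N*mu*target is appreciable
        cfg = SimulationConfig(N=400, mu_site=3e-6, seed=0)
        res = run_replicates(cfg, template7, dfe, n_reps=150, base_seed=17)
        rep = aggregate([s for s, _ in res])
        assert rep.proportion_sgv > rep.proportion_de_novo_only


class TestNeutralCensus:
    def test_requires_herbicide_off(self, template7, dfe):
        with pytest.raises(ValueError):
            neutral_census(SimulationConfig(N=100, herbicide_on=True), template7, dfe, 2)

    def test_no_mutation_means_empty_census(self, template7, dfe):
        cfg = SimulationConfig(N=100, mu_site=0.0, herbicide_on=False, seed=0)
        df = neutral_census(cfg, template7, dfe, n_reps=5, sample_every=50)
        assert (df["n_tsr_origins"] == 0).all()

    def test_counts_are_bounded_nonnegative_integers(self, template7, dfe):
        cfg = SimulationConfig(N=150, mu_site=3e-5, herbicide_on=False, seed=0)
        df = neutral_census(cfg, template7, dfe, n_reps=10, sample_every=100)
        assert (df["n_tsr_origins"] >= 0).all()
        assert df["n_tsr_origins"].dtype.kind == "i"

    def test_stationary_mean_matches_segregating_sites_expectation(self, template7, dfe):
        # E[# segregating TSR origins] = Theta_tsr * a_{2N-1} at neutral
        # equilibrium; checked over 100 replicate burn-ins (3 SE), using
        # the second half of the burn-in as the stationary window
        N, mu = 300, 1e-5
        cfg = SimulationConfig(N=N, mu_site=mu, herbicide_on=False, seed=0)
        df = neutral_census(cfg, template7, dfe, n_reps=100, sample_every=100, base_seed=3)
        theta_tsr = 4 * N * mu * 7
        expected = theta_tsr * harmonic_number(2 * N - 1)
        stationary = df[df["generation"] > -cfg.burnin_generations / 2]
        per_rep = stationary.groupby("replicate")["n_tsr_origins"].mean()
        se = per_rep.std(ddof=1) / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - expected) < 3 * se

    def test_sgv_supply_grows_with_population_size(self, template7, dfe):
        # the standing-variation proportion rises with Ne (Monte Carlo)
        res_small = run_replicates(SimulationConfig(N=300, mu_site=3e-6, seed=0),
                                   template7, dfe, n_reps=150, base_seed=1)
        res_big = run_replicates(SimulationConfig(N=900, mu_site=3e-6, seed=0),
                                 template7, dfe, n_reps=150, base_seed=2)
        p_small = np.mean([s.classification == "sgv" for s, _ in res_small])
        p_big = np.mean([s.classification == "sgv" for s, _ in res_big])
        se = np.sqrt(p_small * (1 - p_small) / 150 + p_big * (1 - p_big) / 150 + 1e-9)
        assert p_big - p_small > -3 * se
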