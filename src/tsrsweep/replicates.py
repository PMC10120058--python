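"""Classification and aggregation of simulation replicates.

A replicate adapts "from standing genetic variation" (``sgv``) if at least
one TSR lineage present at the end of the herbicide phase originated before
selection onset; mixed runs (standing plus de novo survivors) also count as
``sgv``.  A replicate is ``de_novo_only`` when every surviving TSR lineage
arose during the selection phase, and ``none`` when no TSR lineage survives
above the presence threshold (default one copy, 1/(2N)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReplicateSummary", "AggregateReport", "classify_replicate", "aggregate", "neutral_census"]


@dataclass(frozen=True)
class ReplicateSummary:
    replicate_id: int
    classification: str          # 'sgv' | 'de_novo_only' | 'none'
    n_origins_final: int
    n_origins_ever: int
    max_tsr_freq_final: float    # aggregate TSR frequency at the end
    seed: int = 0
    config_hash: str = ""


@dataclass(frozen=True)
class AggregateReport:
    n_reps: int
    proportion_sgv: float
    proportion_de_novo_only: float
    proportion_none: float
    origin_histogram: dict
    mean_trajectories: "pd.DataFrame | None" = None
    config_hash: str = ""


def classify_replicate(
    trajectories: pd.DataFrame,
    registry: pd.DataFrame,
    threshold: float,
    final_generation: int,
    replicate_id: int = 0,
    seed: int = 0,
    config_hash: str = "",
) -> ReplicateSummary:
    """Classify one replicate from its TSR trajectory table.

    ``trajectories`` has columns (generation, origin_id, frequency);
    ``registry`` is indexed by origin_id with an ``origin_generation``
    column (>= 1 means the origin arose during selection).  Classification
    is invariant to row order.
    """
    required = {"generation", "origin_id", "frequency"}
    if not required.issubset(trajectories.columns):
        raise ValueError(f"trajectory table must have columns {sorted(required)}")
    if len(trajectories):
        if trajectories["frequency"].min() <= 0 or trajectories["frequency"].max() > 1:
            raise ValueError("trajectory frequencies must lie in (0, 1]")
    final = trajectories[
        (trajectories["generation"] == final_generation)
        & (trajectories["frequency"] >= threshold - 1e-12)
    ]
    surviving = final["origin_id"].unique()
    n_final = len(surviving)
    n_ever = trajectories["origin_id"].nunique()
    agg_freq = float(min(1.0, final["frequency"].sum()))
    if n_final == 0:
        cls = "none"
    else:
        ogen = registry.loc[surviving, "origin_generation"]
        cls = "sgv" if (ogen <= 0).any() else "de_novo_only"
    return ReplicateSummary(
        replicate_id=replicate_id,
        classification=cls,
        n_origins_final=n_final,
        n_origins_ever=int(n_ever),
        max_tsr_freq_final=agg_freq,
        seed=seed,
        config_hash=config_hash,
    )


def aggregate(summaries, trajectories=None) -> AggregateReport:
    """Aggregate replicate summaries into class proportions and the
    histogram of surviving-origin counts.

    If per-replicate trajectory tables are supplied (same order), the mean
    aggregate TSR frequency per generation is computed per class.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one summary")
    hashes = {s.config_hash for s in summaries}
    if len(hashes) > 1:
        raise ValueError("summaries come from mixed configurations")
    n = len(summaries)
    n_sgv = sum(1 for s in summaries if s.classification == "sgv")
    n_dn = sum(1 for s in summaries if s.classification == "de_novo_only")
    n_none = n - n_sgv - n_dn
    hist: dict[int, int] = {}
    for s in summaries:
        hist[s.n_origins_final] = hist.get(s.n_origins_final, 0) + 1
    mean_traj = None
    if trajectories is not None:
        rows = []
        for s, traj in zip(summaries, trajectories):
            if len(traj) == 0:
                continue
            per_gen = traj.groupby("generation")["frequency"].sum().clip(upper=1.0)
            for gen, freq in per_gen.items():
                rows.append({"classification": s.classification, "generation": gen, "frequency": freq})
        if rows:
            mean_traj = (
                pd.DataFrame(rows)
                .groupby(["classification", "generation"], as_index=False)["frequency"]
                .mean()
            )
    return AggregateReport(
        n_reps=n,
        proportion_sgv=n_sgv / n,
        proportion_de_novo_only=n_dn / n,
        proportion_none=n_none / n,
        origin_histogram=dict(sorted(hist.items())),
        mean_trajectories=mean_traj,
        config_hash=summaries[0].config_hash,
    )


def neutral_census(
    config,
    template,
    dfe,
    n_reps: int,
    sample_every: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Census of standing TSR diversity under neutrality.

    Runs ``n_reps`` burn-ins with the herbicide off, sampling the number of
    simultaneously segregating TSR origins every ``sample_every``
    generations.  Returns a tidy frame (replicate, generation,
    n_tsr_origins); the per-replicate maximum is
    ``df.groupby('replicate')['n_tsr_origins'].max()``.
    """
    from .simulate import run_burnin

    if config.herbicide_on:
        raise ValueError("neutral census requires herbicide_on=False")
    frames = []
    for i in range(n_reps):
        seed = (base_seed + 33_331 * i + 7) % (2**31)
        pop = run_burnin(config, template, dfe, seed=seed, census_every=sample_every)
        cen = pop.census.copy()
        cen.insert(0, "replicate", i)
        frames.append(cen)
    return pd.concat(frames, ignore_index=True)
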