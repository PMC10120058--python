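"""Diploid Wright-Fisher forward simulation of the herbicide-target locus.

The model: a constant-size diploid population evolves at a single locus
(:class:`~tsrsweep.locus.LocusTemplate`) with per-site mutation and
crossover, multiplicative viability selection against the deleterious
background (genotype fitness 1 / 1+hs / 1+s per site), a burn-in of
``burnin_multiplier * N`` generations to reach mutation-selection-drift
balance, and a herbicide phase of ``sel_generations`` generations in which
individuals carrying at least one target-site resistance (TSR) allele have
``survival_ratio`` times the parental sampling weight of non-carriers
(dominant, soft selection at constant N).  Every TSR mutation event is
origin-tracked so replicates can be classified by whether surviving
resistance lineages predate the onset of selection.

Two engines are provided:

* ``linked`` (default): exact haplotype-based simulation (numba kernel);
* ``freq``: per-mutation binomial updates assuming linkage equilibrium,
  for fast cross-checks of linkage-insensitive summaries.

Population-rescaling (``rescale_config``) shrinks N by a factor lambda
while multiplying mu, r and all selection coefficients by lambda, keeping
N*mu, N*r and N*s invariant.  The survival ratio is a bounded viability
ratio, not a small coefficient, and is deliberately left unscaled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _engine
from .locus import DFEConfig, LocusTemplate

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "rescale_config",
    "run_burnin",
    "run_selection_phase",
    "run_replicates",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one forward-simulation protocol.

    ``N``, ``mu_site`` and ``rec_site`` are the *effective* (possibly
    rescaled) values used by the engine; ``rescale_lambda`` records the
    accumulated rescaling factor and multiplies every selection coefficient
    at draw time.
    """

    N: int = 42_000
    mu_site: float = 3.0e-8
    rec_site: float = 7.4e-9
    burnin_multiplier: int = 10
    sel_generations: int = 30
    survival_ratio: float = 20.0
    herbicide_on: bool = True
    rescale_lambda: float = 1.0
    seed: int = 0
    engine: str = "linked"
    herbicide_mode: str = "ratio"     # "ratio" | "coefficient"
    s_ben: float = 0.0                # coefficient mode only (unscaled)
    h_ben: float = 0.5
    mutation_during_selection: bool = True
    prune_every: int = 50

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.mu_site < 0 or self.rec_site < 0:
            raise ValueError("rates must be non-negative")
        if self.survival_ratio < 1:
            raise ValueError("survival_ratio must be >= 1")
        if self.rescale_lambda < 1:
            raise ValueError("rescale_lambda must be >= 1")
        if self.engine not in ("linked", "freq"):
            raise ValueError("engine must be 'linked' or 'freq'")
        if self.herbicide_mode not in ("ratio", "coefficient"):
            raise ValueError("herbicide_mode must be 'ratio' or 'coefficient'")

    @property
    def burnin_generations(self) -> int:
        return self.burnin_multiplier * self.N

    def config_hash(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "seed"}
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def rescale_config(config: SimulationConfig, lam: float) -> SimulationConfig:
    """Standard population-genetic rescaling: N/lam, mu*lam, r*lam, s*lam.

    ``4*N*mu``, ``4*N*r`` and ``N*s`` are invariant; the burn-in shortens to
    ``burnin_multiplier * N'`` generations.  The survival ratio and the
    number of selection generations are unchanged.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    n_new = int(round(config.N / lam))
    if n_new < 50:
        raise ValueError("rescaling drives N below 50; use a smaller lambda")
    total_lam = config.rescale_lambda * lam
    if abs(config.s_ben) * total_lam > 1.0:
        raise ValueError("rescaled |s_ben| exceeds 1")
    return replace(
        config,
        N=n_new,
        mu_site=config.mu_site * lam,
        rec_site=config.rec_site * lam,
        rescale_lambda=total_lam,
    )


@dataclass
class PopulationState:
    """Population snapshot: 2N haplotypes as sparse mutation-index lists.

    ``pop_offsets``/``pop_muts`` form a CSR layout over the 2N haplotype
    slots (linked engine); the ``freq`` engine stores per-mutation copy
    counts instead.  ``mut_*`` arrays are the registry of segregating (plus
    fixed TSR) mutations; ``tsr_registry`` records every TSR origin ever
    created, including lost ones.
    """

    generation: int
    N: int
    mut_site: np.ndarray
    mut_s: np.ndarray
    mut_h: np.ndarray
    mut_is_tsr: np.ndarray
    mut_origin_gen: np.ndarray
    mut_origin_id: np.ndarray
    next_origin_id: int
    tsr_registry: pd.DataFrame
    config: SimulationConfig
    template: LocusTemplate
    dfe: DFEConfig
    pop_offsets: "np.ndarray | None" = None
    pop_muts: "np.ndarray | None" = None
    counts: "np.ndarray | None" = None
    census: "pd.DataFrame | None" = None

    def mutation_counts(self) -> np.ndarray:
        """Copy count of every registry mutation in the population."""
        if self.counts is not None:
            return self.counts.astype(np.int64)
        n_mut = self.mut_site.shape[0]
        if n_mut == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.pop_muts, minlength=n_mut).astype(np.int64)

    def frequencies(self) -> pd.Series:
        """Allele frequency per origin_id."""
        c = self.mutation_counts()
        return pd.Series(c / (2.0 * self.N), index=pd.Index(self.mut_origin_id, name="origin_id"))

    @property
    def n_segregating(self) -> int:
        c = self.mutation_counts()
        return int(np.sum((c > 0) & (c < 2 * self.N)))

    def tsr_counts(self) -> pd.Series:
        c = self.mutation_counts()
        mask = self.mut_is_tsr.astype(bool)
        return pd.Series(c[mask], index=pd.Index(self.mut_origin_id[mask], name="origin_id"))

    def aggregate_tsr_frequency(self) -> float:
        """Frequency of chromosomes carrying >= 1 TSR allele (upper-bounded
        by the sum of per-origin frequencies; exact in the linked engine)."""
        if self.counts is not None:
            return float(min(1.0, self.tsr_counts().sum() / (2.0 * self.N)))
        is_tsr = self.mut_is_tsr.astype(bool)
        if not is_tsr.any() or self.pop_muts.shape[0] == 0:
            return 0.0
        carrier = 0
        off = self.pop_offsets
        tsr_flags = is_tsr[self.pop_muts]
        for slot in range(2 * self.N):
            if tsr_flags[off[slot]:off[slot + 1]].any():
                carrier += 1
        return carrier / (2.0 * self.N)

    def diversity_sample(self, n: int, rng: np.random.Generator, L: "int | None" = None) -> dict:
        """Sample ``n`` haplotypes and return S, Watterson's theta and pi
        per site (``L`` defaults to the template length)."""
        from .popstats import harmonic_number

        if L is None:
            L = self.template.length_bp
        two_n = 2 * self.N
        slots = rng.choice(two_n, size=n, replace=False)
        n_mut = self.mut_site.shape[0]
        c = np.zeros(n_mut, dtype=np.int64)
        if self.counts is not None:
            # linkage-free state: hypergeometric subsample per mutation
            for m in range(n_mut):
                c[m] = rng.hypergeometric(self.counts[m], two_n - self.counts[m], n)
        else:
            off = self.pop_offsets
            for slot in slots:
                seg = self.pop_muts[off[slot]:off[slot + 1]]
                c[seg] += 1
        poly = (c > 0) & (c < n)
        S = int(poly.sum())
        pi = float(np.sum(2.0 * c[poly] * (n - c[poly])) / (n * (n - 1)) / L)
        theta_w = S / (harmonic_number(n - 1) * L)
        return {"S": S, "theta_w": theta_w, "pi": pi}


def _registry_df(oid, site, gen) -> pd.DataFrame:
    df = pd.DataFrame({"origin_id": oid.astype(np.int64), "site": site.astype(np.int64),
                       "origin_generation": gen.astype(np.int64)})
    df["origin_phase"] = np.where(df["origin_generation"] >= 1, "selection", "burnin")
    return df.drop_duplicates("origin_id").set_index("origin_id")


def _traj_df(gen, oid, cnt, registry: pd.DataFrame, two_n: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "generation": gen.astype(np.int64),
            "origin_id": oid.astype(np.int64),
            "frequency": cnt.astype(np.float64) / two_n,
        }
    )
    if len(df):
        df = df.join(registry[["origin_generation", "origin_phase", "site"]], on="origin_id")
    else:
        df["origin_generation"] = np.array([], dtype=np.int64)
        df["origin_phase"] = np.array([], dtype=object)
        df["site"] = np.array([], dtype=np.int64)
    return df


def _kernel_args(config: SimulationConfig, template: LocusTemplate, dfe: DFEConfig):
    lam = config.rescale_lambda
    return dict(
        site_class=template.site_classes(),
        mu_site=config.mu_site,
        rec_site=config.rec_site,
        p_neutral_exon=dfe.p_neutral_exon,
        gamma_shape=dfe.gamma_shape,
        gamma_scale=dfe.gamma_scale * lam,
        h_del=dfe.h_del,
        tsr_s=dfe.tsr_s_before * lam,
        tsr_h=1.0,
        survival_ratio=config.survival_ratio,
        s_ben=config.s_ben * lam,
        h_ben=config.h_ben,
    )


_EMPTY_I4 = np.empty(0, np.int32)
_EMPTY_I8 = np.empty(0, np.int64)
_EMPTY_F8 = np.empty(0, np.float64)
_EMPTY_U1 = np.empty(0, np.uint8)


def run_burnin(
    config: SimulationConfig,
    template: LocusTemplate,
    dfe: DFEConfig,
    seed: "int | None" = None,
    census_every: int = 0,
) -> PopulationState:
    """Burn the population in for ``burnin_multiplier * N`` generations from
    a mutation-free start and return the state at generation 0 (selection
    onset).  ``census_every > 0`` additionally samples the number of
    simultaneously segregating TSR origins every that many generations."""
    seed = config.seed if seed is None else seed
    b = config.burnin_generations
    if config.engine == "freq":
        return _freq_run_burnin(config, template, dfe, seed, census_every)
    ka = _kernel_args(config, template, dfe)
    out = _engine.wf_kernel(
        np.int64(seed % (2**31)),
        np.int64(config.N),
        np.int64(-b),
        np.int64(0),
        ka["site_class"],
        ka["mu_site"],
        ka["rec_site"],
        ka["p_neutral_exon"],
        ka["gamma_shape"],
        ka["gamma_scale"],
        ka["h_del"],
        ka["tsr_s"],
        ka["tsr_h"],
        False,
        _engine.MODE_RATIO,
        ka["survival_ratio"],
        ka["s_ben"],
        ka["h_ben"],
        True,
        _EMPTY_I4,
        _EMPTY_F8,
        _EMPTY_F8,
        _EMPTY_U1,
        _EMPTY_I4,
        _EMPTY_I8,
        _EMPTY_I8,
        _EMPTY_I4,
        np.int64(0),
        np.int64(config.prune_every),
        np.int64(census_every),
        False,
    )
    (site, s, h, is_tsr, ogen, oid, pop_off, pop_muts, next_oid,
     treg_oid, treg_site, treg_gen, _tg, _to, _tc, cen_gen, cen_cnt) = out
    census = pd.DataFrame({"generation": cen_gen, "n_tsr_origins": cen_cnt}) if census_every else None
    return PopulationState(
        generation=0,
        N=config.N,
        mut_site=site,
        mut_s=s,
        mut_h=h,
        mut_is_tsr=is_tsr,
        mut_origin_gen=ogen,
        mut_origin_id=oid,
        next_origin_id=int(next_oid),
        tsr_registry=_registry_df(treg_oid, treg_site, treg_gen),
        config=config,
        template=template,
        dfe=dfe,
        pop_offsets=pop_off,
        pop_muts=pop_muts,
        census=census,
    )


def run_selection_phase(
    pop: PopulationState,
    config: "SimulationConfig | None" = None,
    seed: "int | None" = None,
) -> tuple[PopulationState, pd.DataFrame]:
    """Run the herbicide phase from a generation-0 state.

    Returns the final state and the trajectory table of every segregating
    TSR origin per generation (columns: generation, origin_id, frequency,
    origin_phase, site), including the onset generation 0.
    """
    config = pop.config if config is None else config
    if pop.generation != 0:
        raise ValueError("selection phase must start from a generation-0 state")
    seed = (config.seed + 1_000_003) if seed is None else seed
    if config.engine == "freq":
        return _freq_run_selection(pop, config, seed)
    ka = _kernel_args(config, pop.template, pop.dfe)
    mode = _engine.MODE_RATIO if config.herbicide_mode == "ratio" else _engine.MODE_COEFFICIENT
    out = _engine.wf_kernel(
        np.int64(seed % (2**31)),
        np.int64(config.N),
        np.int64(0),
        np.int64(config.sel_generations),
        ka["site_class"],
        ka["mu_site"],
        ka["rec_site"],
        ka["p_neutral_exon"],
        ka["gamma_shape"],
        ka["gamma_scale"],
        ka["h_del"],
        ka["tsr_s"],
        ka["tsr_h"],
        bool(config.herbicide_on),
        mode,
        ka["survival_ratio"],
        ka["s_ben"],
        ka["h_ben"],
        bool(config.mutation_during_selection),
        pop.mut_site.astype(np.int32),
        pop.mut_s.astype(np.float64),
        pop.mut_h.astype(np.float64),
        pop.mut_is_tsr.astype(np.uint8),
        pop.mut_origin_gen.astype(np.int32),
        pop.mut_origin_id.astype(np.int64),
        pop.pop_offsets.astype(np.int64),
        pop.pop_muts.astype(np.int32),
        np.int64(pop.next_origin_id),
        np.int64(config.prune_every),
        np.int64(0),
        True,
    )
    (site, s, h, is_tsr, ogen, oid, pop_off, pop_muts, next_oid,
     treg_oid, treg_site, treg_gen, tg, to, tc, _cg, _cc) = out
    registry = _registry_df(
        np.concatenate([pop.tsr_registry.reset_index()["origin_id"].to_numpy(), treg_oid]),
        np.concatenate([pop.tsr_registry["site"].to_numpy(), treg_site]),
        np.concatenate([pop.tsr_registry["origin_generation"].to_numpy(), treg_gen]),
    )
    traj = _traj_df(tg, to, tc, registry, 2 * config.N)
    final = PopulationState(
        generation=config.sel_generations,
        N=config.N,
        mut_site=site,
        mut_s=s,
        mut_h=h,
        mut_is_tsr=is_tsr,
        mut_origin_gen=ogen,
        mut_origin_id=oid,
        next_origin_id=int(next_oid),
        tsr_registry=registry,
        config=config,
        template=pop.template,
        dfe=pop.dfe,
        pop_offsets=pop_off,
        pop_muts=pop_muts,
    )
    return final, traj


def run_replicates(
    config: SimulationConfig,
    template: LocusTemplate,
    dfe: DFEConfig,
    n_reps: int,
    base_seed: int = 0,
    threshold: "float | None" = None,
):
    """Run independent burn-in + selection replicates and classify each one.

    Replicate ``i`` uses seeds derived from ``base_seed + i``; results are
    deterministic given (config, template, dfe, n_reps, base_seed).
    Returns a list of ``(ReplicateSummary, trajectory DataFrame)`` pairs.
    """
    from .replicates import classify_replicate

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    out = []
    for i in range(n_reps):
        s1 = (base_seed + 7_654_321 * i + 13) % (2**31)
        s2 = (base_seed + 7_654_321 * i + 104_729) % (2**31)
        pop0 = run_burnin(config, template, dfe, seed=s1)
        if config.herbicide_on:
            final, traj = run_selection_phase(pop0, config, seed=s2)
        else:
            # no herbicide: the selection phase is skipped, nothing can adapt
            final = pop0
            traj = _traj_df(
                np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, np.int64),
                pop0.tsr_registry, 2 * config.N,
            )
        summary = classify_replicate(
            traj,
            final.tsr_registry,
            threshold=threshold if threshold is not None else 1.0 / (2 * config.N),
            final_generation=config.sel_generations,
            replicate_id=i,
            seed=base_seed + i,
            config_hash=config.config_hash(),
        )
        out.append((summary, traj))
    return out


# ---------------------------------------------------------------------------
# freq engine: per-mutation binomial updates under linkage equilibrium
# ---------------------------------------------------------------------------


def _freq_state_init():
    return {
        "site": np.zeros(0, np.int64),
        "s": np.zeros(0, np.float64),
        "h": np.zeros(0, np.float64),
        "is_tsr": np.zeros(0, bool),
        "ogen": np.zeros(0, np.int64),
        "oid": np.zeros(0, np.int64),
        "count": np.zeros(0, np.int64),
    }


def _freq_step(state, rng, two_n, herbicide, mode, ratio):
    c = state["count"]
    if c.shape[0] == 0:
        return
    p = c / two_n
    s = state["s"]
    h = state["h"]
    if herbicide and mode == "ratio":
        # dominant carrier advantage: genotype fitness 1 / R / R
        s_eff = np.where(state["is_tsr"], ratio - 1.0, s)
        h_eff = np.where(state["is_tsr"], 1.0, h)
    else:
        s_eff = s
        h_eff = h
    whet = 1.0 + h_eff * s_eff
    whom = 1.0 + s_eff
    q = 1.0 - p
    wbar = p * p * whom + 2 * p * q * whet + q * q
    p_next = (p * p * whom + p * q * whet) / wbar
    state["count"] = rng.binomial(two_n, np.clip(p_next, 0.0, 1.0))


def _freq_add_mutations(state, rng, two_n, n_events, template, dfe, lam, gen,
                        herbicide, mode, s_ben, h_ben, next_oid):
    classes = template.site_classes()
    sites = rng.integers(0, template.length_bp, size=n_events)
    add_s = np.zeros(n_events)
    add_h = np.full(n_events, 0.5)
    add_t = np.zeros(n_events, bool)
    for k, site in enumerate(sites):
        cls = classes[site]
        if cls == 2:
            add_t[k] = True
            if herbicide and mode == "coefficient":
                add_s[k] = s_ben * lam
                add_h[k] = h_ben
            elif not herbicide:
                add_s[k] = dfe.tsr_s_before * lam
                add_h[k] = 1.0
        elif cls == 1 and rng.random() >= dfe.p_neutral_exon:
            add_s[k] = -max(rng.gamma(dfe.gamma_shape, dfe.gamma_scale * lam), 1e-300)
            add_h[k] = dfe.h_del
    state["site"] = np.concatenate([state["site"], sites])
    state["s"] = np.concatenate([state["s"], add_s])
    state["h"] = np.concatenate([state["h"], add_h])
    state["is_tsr"] = np.concatenate([state["is_tsr"], add_t])
    state["ogen"] = np.concatenate([state["ogen"], np.full(n_events, gen, dtype=np.int64)])
    state["oid"] = np.concatenate([state["oid"], next_oid + np.arange(n_events, dtype=np.int64)])
    state["count"] = np.concatenate([state["count"], np.ones(n_events, dtype=np.int64)])
    return next_oid + n_events


def _freq_prune(state, two_n):
    c = state["count"]
    keep = (c > 0) & ((c < two_n) | state["is_tsr"])
    for k in state:
        state[k] = state[k][keep]


def _freq_loop(state, rng, config, template, dfe, gen_start, gen_end, herbicide,
               record_traj, census_every, next_oid, treg, traj_rows, census_rows):
    two_n = 2 * config.N
    lam = config.rescale_lambda
    lam_mut = two_n * config.mu_site * template.length_bp
    mode = config.herbicide_mode
    mutation_on = config.mutation_during_selection if herbicide or gen_start >= 0 else True
    if gen_start < 0:
        mutation_on = True

    def record(g):
        if record_traj:
            mask = state["is_tsr"] & (state["count"] > 0)
            for oidv, cnt in zip(state["oid"][mask], state["count"][mask]):
                traj_rows.append((g, oidv, cnt))
        if census_every > 0 and (g - gen_start) % census_every == 0:
            mask = state["is_tsr"] & (state["count"] > 0) & (state["count"] < two_n)
            census_rows.append((g, int(mask.sum())))

    def census_zeros(lo, hi):
        if census_every > 0:
            for gg in range(lo, hi + 1):
                if (gg - gen_start) % census_every == 0:
                    census_rows.append((gg, 0))

    record(gen_start)
    g = gen_start
    while g < gen_end:
        if state["count"].shape[0] == 0:
            # exchangeable population: fast-forward to the next mutation event
            if not mutation_on or lam_mut == 0:
                census_zeros(g + 1, gen_end)
                g = gen_end
                break
            skip = int(rng.geometric(1.0 - np.exp(-lam_mut)))
            if g + skip > gen_end:
                census_zeros(g + 1, gen_end)
                g = gen_end
                break
            census_zeros(g + 1, g + skip - 1)
            g += skip
            k = 1 + rng.poisson(lam_mut)  # conditioned >= 1 (small-lambda form)
            prev = state["oid"].shape[0]
            next_oid = _freq_add_mutations(
                state, rng, two_n, k, template, dfe, lam, g, herbicide, mode,
                config.s_ben, config.h_ben, next_oid,
            )
            for idx in range(prev, prev + k):
                if state["is_tsr"][idx]:
                    treg.append((state["oid"][idx], state["site"][idx], state["ogen"][idx]))
            record(g)
            continue
        g += 1
        _freq_step(state, rng, two_n, herbicide, mode, config.survival_ratio)
        if mutation_on and lam_mut > 0:
            k = rng.poisson(lam_mut)
            if k:
                prev = state["oid"].shape[0]
                next_oid = _freq_add_mutations(
                    state, rng, two_n, k, template, dfe, lam, g, herbicide, mode,
                    config.s_ben, config.h_ben, next_oid,
                )
                for idx in range(prev, prev + k):
                    if state["is_tsr"][idx]:
                        treg.append((state["oid"][idx], state["site"][idx], state["ogen"][idx]))
        _freq_prune(state, two_n)
        record(g)
    return next_oid


def _freq_run_burnin(config, template, dfe, seed, census_every):
    rng = np.random.default_rng(seed)
    state = _freq_state_init()
    treg, traj_rows, census_rows = [], [], []
    b = config.burnin_generations
    next_oid = _freq_loop(state, rng, config, template, dfe, -b, 0, False,
                          False, census_every, 0, treg, traj_rows, census_rows)
    treg_arr = np.array(treg, dtype=np.int64).reshape(-1, 3)
    census = (
        pd.DataFrame({"generation": [r[0] for r in census_rows],
                      "n_tsr_origins": [r[1] for r in census_rows]})
        if census_every else None
    )
    return PopulationState(
        generation=0,
        N=config.N,
        mut_site=state["site"].astype(np.int32),
        mut_s=state["s"],
        mut_h=state["h"],
        mut_is_tsr=state["is_tsr"].astype(np.uint8),
        mut_origin_gen=state["ogen"].astype(np.int32),
        mut_origin_id=state["oid"],
        next_origin_id=int(next_oid),
        tsr_registry=_registry_df(treg_arr[:, 0], treg_arr[:, 1], treg_arr[:, 2]),
        config=config,
        template=template,
        dfe=dfe,
        counts=state["count"].copy(),
        census=census,
    )


def _freq_run_selection(pop, config, seed):
    rng = np.random.default_rng(seed)
    state = {
        "site": pop.mut_site.astype(np.int64).copy(),
        "s": pop.mut_s.copy(),
        "h": pop.mut_h.copy(),
        "is_tsr": pop.mut_is_tsr.astype(bool).copy(),
        "ogen": pop.mut_origin_gen.astype(np.int64).copy(),
        "oid": pop.mut_origin_id.copy(),
        "count": pop.counts.copy(),
    }
    if config.herbicide_on and config.herbicide_mode == "coefficient":
        lam = config.rescale_lambda
        tsr = state["is_tsr"]
        state["s"][tsr] = config.s_ben * lam
        state["h"][tsr] = config.h_ben
    treg, traj_rows, census_rows = [], [], []
    herb = config.herbicide_on
    next_oid = _freq_loop(state, rng, config, pop.template, pop.dfe, 0,
                          config.sel_generations, herb, True, 0,
                          pop.next_origin_id, treg, traj_rows, census_rows)
    treg_arr = np.array(treg, dtype=np.int64).reshape(-1, 3)
    registry = _registry_df(
        np.concatenate([pop.tsr_registry.reset_index()["origin_id"].to_numpy(), treg_arr[:, 0]]),
        np.concatenate([pop.tsr_registry["site"].to_numpy(), treg_arr[:, 1]]),
        np.concatenate([pop.tsr_registry["origin_generation"].to_numpy(), treg_arr[:, 2]]),
    )
    tg = np.array([r[0] for r in traj_rows], dtype=np.int64)
    to = np.array([r[1] for r in traj_rows], dtype=np.int64)
    tc = np.array([r[2] for r in traj_rows], dtype=np.int64)
    traj = _traj_df(tg, to, tc, registry, 2 * config.N)
    final = PopulationState(
        generation=config.sel_generations,
        N=config.N,
        mut_site=state["site"].astype(np.int32),
        mut_s=state["s"],
        mut_h=state["h"],
        mut_is_tsr=state["is_tsr"].astype(np.uint8),
        mut_origin_gen=state["ogen"].astype(np.int32),
        mut_origin_id=state["oid"],
        next_origin_id=int(next_oid),
        tsr_registry=registry,
        config=config,
        template=pop.template,
        dfe=pop.dfe,
        counts=state["count"].copy(),
    )
    return final, traj
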