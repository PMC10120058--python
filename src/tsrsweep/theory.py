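"""Analytic probabilities of adaptation via a selective sweep.

Closed-form expectations for the probability that a population adapts to a
new selection regime (herbicide application) through a beneficial allele at
a small mutational target, partitioned by the source of the allele:

* standing genetic variation (SGV): copies already segregating at onset
  under mutation-selection-drift balance, where the allele had (possibly
  deleterious) heterozygous effect ``h_del * s_del``;
* de novo mutation: copies arising during the ``T`` generations of
  selection.

With scaled parameters ``alpha = 4 Ne h s`` and locus-wide mutational input
``Theta = 4 Ne u L`` (``u`` per-site rate, ``L`` target nucleotides), the
probability that at least one standing copy escapes stochastic loss is

    P_sgv = 1 - exp(-Theta * ln(1 + alpha_b / (alpha_d + 1)))

(the standing-frequency density ``Theta/x * exp(-alpha_d x)`` integrated
against the establishment probability ``1 - exp(-alpha_b x)``), and the de
novo contribution over ``T`` generations is

    P_dn = 1 - exp(-2 Ne u L T * pi_est)

with ``pi_est`` the diffusion establishment probability of a single copy.
The two sources are combined assuming independence.  "Adaptation" means
establishment (escape from loss), not completed fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SweepParams",
    "establishment_prob",
    "prob_sgv",
    "prob_denovo",
    "prob_adapt_total",
    "fraction_sgv",
    "grid_evaluate",
    "default_sben_grid",
    "default_sdel_grid",
]


@dataclass(frozen=True)
class SweepParams:
    """Parameters of the analytic sweep-probability model.

    Defaults follow the herbicide-target setting: per-site mutation rate
    3.0e-8, a 7-nucleotide resistance target, 30 generations of selection,
    additive dominance.
    """

    Ne: float
    s_ben: float
    s_del: float = 0.0
    u_site: float = 3.0e-8
    target_size: int = 7
    h_ben: float = 0.5
    h_del: float = 0.5
    T: int = 30

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.u_site < 0 or self.target_size < 0:
            raise ValueError("mutational target must be non-negative")
        if self.s_ben < 0 or self.s_del < 0:
            raise ValueError("s_ben and s_del are magnitudes, must be >= 0")
        if not (0 <= self.h_ben <= 1 and 0 <= self.h_del <= 1):
            raise ValueError("dominance must be in [0, 1]")
        if self.T < 0:
            raise ValueError("T must be >= 0")

    @property
    def theta(self) -> float:
        """Locus-wide scaled mutation rate 4 Ne u L of the beneficial target."""
        return 4.0 * self.Ne * self.u_site * self.target_size


def establishment_prob(s: float, h: float, Ne: float) -> float:
    """Diffusion fixation probability of a single new copy with heterozygous
    advantage ``h*s``: ``(1 - exp(-2hs)) / (1 - exp(-4 Ne h s))``, with the
    neutral limit ``1/(2 Ne)`` taken analytically."""
    if s < 0:
        raise ValueError("s must be >= 0")
    hs = h * s
    if hs == 0.0 or 4.0 * Ne * hs < 1e-12:
        return 1.0 / (2.0 * Ne)
    num = -np.expm1(-2.0 * hs)
    den = -np.expm1(-4.0 * Ne * hs)
    return float(num / den)


def prob_sgv(params: SweepParams) -> float:
    """Probability that adaptation succeeds from standing genetic variation."""
    if params.u_site == 0.0 or params.target_size == 0 or params.s_ben == 0.0:
        return 0.0
    alpha_b = 4.0 * params.Ne * params.h_ben * params.s_ben
    alpha_d = 4.0 * params.Ne * params.h_del * params.s_del
    r_alpha = alpha_b / (alpha_d + 1.0)
    return float(-np.expm1(-params.theta * np.log1p(r_alpha)))


def prob_denovo(params: SweepParams) -> float:
    """Probability that at least one de novo copy arising within ``T``
    generations of selection establishes."""
    if params.u_site == 0.0 or params.target_size == 0 or params.T == 0:
        return 0.0
    pi_est = establishment_prob(params.s_ben, params.h_ben, params.Ne)
    rate = 2.0 * params.Ne * params.u_site * params.target_size * params.T
    return float(-np.expm1(-rate * pi_est))


def prob_adapt_total(params: SweepParams) -> float:
    """Total probability of adaptation, assuming the SGV and de novo routes
    establish independently: ``1 - (1 - P_sgv)(1 - P_dn)``."""
    psgv = prob_sgv(params)
    pdn = prob_denovo(params)
    # algebraically identical to 1-(1-psgv)(1-pdn), better conditioned for
    # small probabilities
    return float(psgv + pdn - psgv * pdn)


def fraction_sgv(params: SweepParams) -> float:
    """Conditional probability that adaptation, given that it occurs, derives
    from standing genetic variation: ``P_sgv / P_total``."""
    psgv = prob_sgv(params)
    pdn = prob_denovo(params)
    total = psgv + pdn - psgv * pdn
    if total == 0.0:
        raise ValueError("fraction_sgv undefined when P_total = 0")
    return psgv / total


def default_sben_grid(n: int = 25) -> np.ndarray:
    """Log-spaced beneficial-coefficient grid on [0.01, 1]."""
    return np.logspace(-2, 0, n)


def default_sdel_grid(n: int = 25) -> np.ndarray:
    """Log-spaced prior-deleterious-coefficient grid on [1e-6, 1e-2]."""
    return np.logspace(-6, -2, n)


def grid_evaluate(
    ne_values,
    s_ben_grid,
    s_del_grid,
    params: "SweepParams | None" = None,
) -> pd.DataFrame:
    """Evaluate the sweep probabilities over a parameter grid.

    Returns one row per (Ne, s_ben, s_del) combination with columns
    ``P_sgv``, ``P_dn``, ``P_total`` and ``fraction_sgv``.
    """
    ne_values = np.atleast_1d(np.asarray(ne_values, dtype=float))
    s_ben_grid = np.atleast_1d(np.asarray(s_ben_grid, dtype=float))
    s_del_grid = np.atleast_1d(np.asarray(s_del_grid, dtype=float))
    if ne_values.size == 0 or s_ben_grid.size == 0 or s_del_grid.size == 0:
        raise ValueError("grids must be non-empty")
    base = params or SweepParams(Ne=ne_values[0], s_ben=s_ben_grid[0])
    rows = []
    for ne in ne_values:
        for sd in s_del_grid:
            for sb in s_ben_grid:
                p = replace(base, Ne=ne, s_ben=sb, s_del=sd)
                psgv = prob_sgv(p)
                pdn = prob_denovo(p)
                ptot = 1.0 - (1.0 - psgv) * (1.0 - pdn)
                rows.append(
                    {
                        "Ne": ne,
                        "s_ben": sb,
                        "s_del": sd,
                        "P_sgv": psgv,
                        "P_dn": pdn,
                        "P_total": ptot,
                        "fraction_sgv": psgv / ptot if ptot > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
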