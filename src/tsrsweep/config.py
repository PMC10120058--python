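"""JSON configuration loading.

A configuration file holds up to three blocks::

    {
      "locus":      {"length_bp": 12250, "n_exons": 10, "coding_fraction": 0.5,
                     "n_tsr_sites": 7 | "tsr_sites": [...] | "exon_intervals": [[a,b],...]},
      "dfe":        {"p_neutral_exon": 0.25, "gamma_mean_s": -0.000154, ...},
      "simulation": {"N": 42000, "mu_site": 3e-8, ..., "rescale_lambda": 20}
    }

``rescale_lambda`` > 1 in the simulation block is applied through
:func:`tsrsweep.simulate.rescale_config` at load time, so the stored N, mu
and r are the full-scale values.
"""

from __future__ import annotations

import json
from dataclasses import fields

from .locus import DFEConfig, LocusTemplate, build_template
from .simulate import SimulationConfig, rescale_config

__all__ = ["load_config", "load_template", "load_dfe", "load_simulation"]


def load_template(block: dict) -> LocusTemplate:
    kwargs = dict(block)
    if "exon_intervals" in kwargs:
        kwargs["exon_intervals"] = [tuple(iv) for iv in kwargs["exon_intervals"]]
    return build_template(**kwargs)


def load_dfe(block: dict) -> DFEConfig:
    return DFEConfig(**block)


def load_simulation(block: dict) -> SimulationConfig:
    block = dict(block)
    lam = float(block.pop("rescale_lambda", 1.0))
    valid = {f.name for f in fields(SimulationConfig)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**block)
    if lam > 1.0:
        cfg = rescale_config(cfg, lam)
    return cfg


def load_config(path):
    """Load (template, dfe, simulation config) from a JSON file; missing
    blocks fall back to the shipped defaults."""
    with open(path) as fh:
        data = json.load(fh)
    template = load_template(data.get("locus", {}))
    dfe = load_dfe(data.get("dfe", {}))
    sim = load_simulation(data.get("simulation", {}))
    return template, dfe, sim
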