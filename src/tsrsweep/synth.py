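"""Synthetic amplicon panels and canned fixtures.

The generator emulates the statistical structure of per-field amplicon
haplotype panels: a handful of wild-type backbones at fixed pairwise
divergence, target-site resistance (TSR) codon substitutions planted on one
or more backbones (independent origins), optional single-breakpoint
recombinants, and a population-sharing structure.  Every panel ships with a
machine-readable truth table sufficient to score TSR calling,
deduplication, sharing tables and origin counting without re-reading the
configuration.

Backbones are star-shaped around a bundled mock reference (2 kb by
default) that carries the real TSR codon contexts (Ile/Trp/Trp/Ile/Asp for
ACCase, Pro/Trp for ALS1) at scaled coordinates; each non-reference
backbone carries ``backbone_divergence`` private substitutions at sites of
its own, so two distinct backbones differ at exactly twice that number of
sites.  Coalescent realism is not attempted: the typing logic depends only
on differing-site counts and breakpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .amplicons import (
    CANONICAL_TSR_CODONS,
    AmpliconHaplotype,
    CodonSpec,
    TSRCodonTable,
    write_haplotype_fasta,
)

__all__ = [
    "TSREvent",
    "RecombinantSpec",
    "PanelConfig",
    "mock_reference",
    "mock_codon_table",
    "generate_panel",
    "make_fixture_suite",
]

_BASES = np.array(list("ACGT"))
# canonical codon used for each reference amino acid in mock references
_REF_CODON = {"Ile": "ATA", "Trp": "TGG", "Asp": "GAT", "Pro": "CCT"}
_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]


def _resistant_codon(ref_codon: str, target_aa3: str) -> str:
    """Codon encoding ``target_aa3`` with minimal edits from ``ref_codon``."""
    from Bio.SeqUtils import seq3

    best = None
    best_d = 4
    for codon in _CODONS:
        aa = seq3(str(Seq(codon).translate()))
        if aa != target_aa3:
            continue
        d = sum(1 for x, y in zip(codon, ref_codon) if x != y)
        if d < best_d or (d == best_d and (best is None or codon < best)):
            best, best_d = codon, d
    if best is None:
        raise ValueError(f"no codon encodes {target_aa3}")
    return best


def _codon_positions(gene: str, length: int):
    specs = CANONICAL_TSR_CODONS[gene]
    n = len(specs)
    out = []
    for i, (num, ref_aa, alts) in enumerate(specs):
        p = (i + 1) * length // (n + 2)
        out.append((num, ref_aa, alts, (p, p + 1, p + 2)))
    return out


def mock_reference(gene: str, length: int = 2001) -> str:
    """Deterministic mock reference carrying the gene's TSR codon contexts
    at scaled coordinates (synthetic stand-in for the real amplicon)."""
    rng = np.random.default_rng(abs(hash_stable(gene)) % (2**31) + length)
    seq = rng.choice(_BASES, size=length)
    for num, ref_aa, _alts, pos in _codon_positions(gene, length):
        codon = _REF_CODON[ref_aa]
        for k in range(3):
            seq[pos[k]] = codon[k]
    return "".join(seq)


def hash_stable(text: str) -> int:
    """Deterministic string hash (Python's builtin hash is salted)."""
    h = 2166136261
    for ch in text:
        h = ((h ^ ord(ch)) * 16777619) % (2**32)
    return h


def mock_codon_table(gene: str, length: int = 2001) -> TSRCodonTable:
    codons = tuple(
        CodonSpec(codon_number=num, ref_aa=ref_aa, resistant_aas=alts, positions=pos)
        for num, ref_aa, alts, pos in _codon_positions(gene, length)
    )
    return TSRCodonTable(gene=gene, codons=codons)


@dataclass(frozen=True)
class TSREvent:
    """One independent planted resistance origin: a codon substitution on a
    specific backbone, present in the listed populations."""

    label: str                       # e.g. "Ile1781Leu"
    backbone: int
    populations: tuple
    copies_per_population: int = 1


@dataclass(frozen=True)
class RecombinantSpec:
    """A single-crossover mosaic of one planted TSR haplotype and one
    wild-type backbone, placed in one population."""

    tsr_event: int
    wt_backbone: int
    breakpoint: int
    population: str
    copies: int = 1


@dataclass(frozen=True)
class PanelConfig:
    gene: str = "ACCase"
    n_populations: int = 2
    n_backbones: int = 4
    backbone_divergence: int = 6
    seq_length: int = 2001
    tsr_events: tuple = ()
    recombinants: tuple = ()
    sharing: "dict | None" = None     # backbone -> tuple of populations
    wt_copies: int = 1                # wild-type copies per backbone per population
    seed: int = 0

    def population_names(self):
        return tuple(f"pop{i + 1}" for i in range(self.n_populations))


def _backbone_sequences(config: PanelConfig, reference: str, rng: np.random.Generator):
    """Backbone 0 is the reference; each further backbone carries
    ``backbone_divergence`` private substitutions at sites of its own."""
    table = mock_codon_table(config.gene, config.seq_length)
    codon_sites = {p for c in table.codons for p in c.positions}
    free_sites = np.array(sorted(set(range(config.seq_length)) - codon_sites))
    need = (config.n_backbones - 1) * config.backbone_divergence
    if need > free_sites.size:
        raise ValueError("backbone divergence infeasible for this sequence length")
    chosen = rng.choice(free_sites, size=need, replace=False)
    seqs = [reference]
    for b in range(1, config.n_backbones):
        sites = chosen[(b - 1) * config.backbone_divergence : b * config.backbone_divergence]
        seq = list(reference)
        for s in sites:
            old = seq[s]
            seq[s] = str(rng.choice(_BASES[_BASES != old]))
        seqs.append("".join(seq))
    return seqs


def _apply_event(seq: str, event: TSREvent, table: TSRCodonTable) -> str:
    codon_number = int("".join(ch for ch in event.label if ch.isdigit()))
    spec = next(c for c in table.codons if c.codon_number == codon_number)
    target_aa = event.label[len(spec.ref_aa) + len(str(codon_number)):]
    if target_aa not in spec.resistant_aas:
        raise ValueError(f"{target_aa!r} is not a known resistant amino acid at codon {codon_number}")
    ref_codon = "".join(seq[p] for p in spec.positions)
    new_codon = _resistant_codon(ref_codon, target_aa)
    out = list(seq)
    for k in range(3):
        out[spec.positions[k]] = new_codon[k]
    return "".join(out)


def generate_panel(config: PanelConfig, rng: "np.random.Generator | None" = None):
    """Generate a haplotype panel and its truth table.

    Returns ``(haplotypes, truth)`` where ``truth`` has one row per
    haplotype: name, sample_id, population, backbone, tsr_label (empty for
    wild type), origin_event (index into ``config.tsr_events`` or -1) and
    is_recombinant.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    reference = mock_reference(config.gene, config.seq_length)
    table = mock_codon_table(config.gene, config.seq_length)
    backbones = _backbone_sequences(config, reference, rng)
    pops = config.population_names()
    sharing = config.sharing or {b: pops for b in range(config.n_backbones)}

    haps = []
    truth_rows = []
    counter: dict[str, int] = {}

    def add(seq, pop, backbone, label, event_idx, recomb):
        i = counter.get(pop, 0)
        counter[pop] = i + 1
        h = AmpliconHaplotype(
            sequence=seq,
            sample_id=f"{pop}_s{i:03d}",
            population_id=pop,
            gene=config.gene,
            phase_index=1 + (i % 2),
        )
        haps.append(h)
        truth_rows.append(
            {
                "name": h.name,
                "sample_id": h.sample_id,
                "population": pop,
                "backbone": backbone,
                "tsr_label": label,
                "origin_event": event_idx,
                "is_recombinant": recomb,
            }
        )

    # wild-type copies per backbone per population it occurs in
    for b in range(config.n_backbones):
        for pop in sharing.get(b, ()):
            for _ in range(config.wt_copies):
                add(backbones[b], pop, b, "", -1, False)
    # planted TSR events
    event_seqs = []
    for e_idx, ev in enumerate(config.tsr_events):
        seq = _apply_event(backbones[ev.backbone], ev, table)
        event_seqs.append(seq)
        for pop in ev.populations:
            for _ in range(ev.copies_per_population):
                add(seq, pop, ev.backbone, ev.label, e_idx, False)
    # single-crossover recombinants (mosaic carries the TSR codon side)
    for rc in config.recombinants:
        tsr_seq = event_seqs[rc.tsr_event]
        wt_seq = backbones[rc.wt_backbone]
        ev = config.tsr_events[rc.tsr_event]
        codon_number = int("".join(ch for ch in ev.label if ch.isdigit()))
        spec = next(c for c in table.codons if c.codon_number == codon_number)
        if max(spec.positions) < rc.breakpoint:
            seq = tsr_seq[: rc.breakpoint] + wt_seq[rc.breakpoint :]
        else:
            seq = wt_seq[: rc.breakpoint] + tsr_seq[rc.breakpoint :]
        for _ in range(rc.copies):
            add(seq, rc.population, -1, ev.label, rc.tsr_event, True)

    truth = pd.DataFrame(truth_rows)
    return haps, truth


def sharing_panel_config(seed: int = 2022) -> PanelConfig:
    """Panel whose nonredundant clusters reproduce the sharing structure
    62 TSR (20 shared) vs 188 wild type (55 shared) across two populations."""
    n_backbones = 188
    pops = ("pop1", "pop2")
    sharing = {}
    for b in range(n_backbones):
        if b < 55:
            sharing[b] = pops
        else:
            sharing[b] = (pops[b % 2],)
    labels = ["Ile1781Leu", "Ile1781Thr", "Trp2027Cys", "Ile2041Asn", "Asp2078Gly"]
    events = []
    for i in range(62):
        ev_pops = pops if i < 20 else (pops[i % 2],)
        events.append(TSREvent(label=labels[i % len(labels)], backbone=i, populations=ev_pops))
    return PanelConfig(
        gene="ACCase",
        n_populations=2,
        n_backbones=n_backbones,
        backbone_divergence=4,
        seq_length=2001,
        tsr_events=tuple(events),
        sharing=sharing,
        seed=seed,
    )


def origin_panel_config(seed: int = 7) -> PanelConfig:
    """Single-field panel with the same mutation planted on two backbones
    twelve sites apart (two independent origins, no recombinants)."""
    return PanelConfig(
        gene="ACCase",
        n_populations=1,
        n_backbones=3,
        backbone_divergence=6,
        tsr_events=(
            TSREvent("Ile1781Leu", backbone=1, populations=("pop1",), copies_per_population=3),
            TSREvent("Ile1781Leu", backbone=2, populations=("pop1",), copies_per_population=2),
        ),
        wt_copies=2,
        seed=seed,
    )


def recombinant_panel_config(seed: int = 11) -> PanelConfig:
    """Single-field panel where one resistant haplotype is an exact
    single-crossover of an observed carrier and an observed wild type."""
    return PanelConfig(
        gene="ACCase",
        n_populations=1,
        n_backbones=3,
        backbone_divergence=12,
        tsr_events=(
            TSREvent("Trp2027Cys", backbone=1, populations=("pop1",), copies_per_population=3),
        ),
        recombinants=(
            RecombinantSpec(tsr_event=0, wt_backbone=2, breakpoint=1000, population="pop1"),
        ),
        wt_copies=2,
        seed=seed,
    )


def make_fixture_suite(out_dir) -> dict:
    """Write the canned fixtures: a small rescaled simulation config, the
    sharing-table panel, the origin-counting panel and the recombinant
    panel, each with FASTA + truth TSV and a manifest of embedded seeds.

    Returns a manifest dict mapping fixture names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    sim_cfg = {
        "locus": {"length_bp": 12250, "n_exons": 10, "coding_fraction": 0.5, "n_tsr_sites": 7,
                  "name": "ACCase-like"},
        "dfe": {"p_neutral_exon": 0.25, "gamma_mean_s": -0.000154, "gamma_shape": 0.245,
                "h_del": 0.5, "tsr_s_before": 0.0},
        "simulation": {"N": 42000, "mu_site": 3.0e-8, "rec_site": 7.4e-9,
                       "burnin_multiplier": 10, "sel_generations": 30,
                       "survival_ratio": 20.0, "herbicide_on": True,
                       "rescale_lambda": 20.0, "engine": "linked", "seed": 1},
        "note": "rescale_lambda is applied via rescale_config at load time",
    }
    p = out / "sim_config.json"
    p.write_text(json.dumps(sim_cfg, indent=2))
    manifest["sim_config"] = str(p)

    for name, cfg in [
        ("sharing", sharing_panel_config()),
        ("origins", origin_panel_config()),
        ("recombinant", recombinant_panel_config()),
    ]:
        haps, truth = generate_panel(cfg)
        fa = out / f"panel_{name}.fa"
        tsv = out / f"panel_{name}.truth.tsv"
        write_haplotype_fasta(haps, fa)
        truth.to_csv(tsv, sep="\t", index=False)
        ref = out / f"reference_{cfg.gene}.fa"
        ref.write_text(f">{cfg.gene}_mock_reference\n{mock_reference(cfg.gene, cfg.seq_length)}\n")
        tab = out / f"tsr_codons_{cfg.gene}.json"
        tab.write_text(json.dumps(mock_codon_table(cfg.gene, cfg.seq_length).to_dict(), indent=2))
        manifest[name] = {"fasta": str(fa), "truth": str(tsv), "reference": str(ref),
                          "codon_table": str(tab), "seed": cfg.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
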