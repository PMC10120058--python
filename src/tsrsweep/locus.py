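"""Locus template and distribution of fitness effects (DFE).

The simulated locus mimics a herbicide-target gene (ACCase-like): a
12,250-bp stretch partitioned into exons and introns/noncoding sequence,
with a small set of nucleotide positions ("TSR sites") at which a mutation
confers target-site herbicide resistance.  New mutations are classified by
the site they hit:

* TSR site            -> resistance allele, selection coefficient
                         ``tsr_s_before`` until herbicide onset;
* other exonic site   -> neutral with probability ``p_neutral_exon``,
                         otherwise deleterious with ``s`` drawn from a
                         gamma distribution (negative effects);
* noncoding site      -> neutral.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SiteClass",
    "LocusTemplate",
    "DFEConfig",
    "MutationEffect",
    "build_template",
    "classify_site",
    "draw_effect",
]


class SiteClass(str, Enum):
    """Mutually exclusive site/mutation classes, precedence tsr > exonic > noncoding."""

    TSR_TARGET = "tsr_target"
    EXON_NEUTRAL = "exon_neutral"
    EXON_DELETERIOUS = "exon_deleterious"
    NONCODING_NEUTRAL = "noncoding_neutral"


@dataclass(frozen=True)
class LocusTemplate:
    """Coordinates of exons and TSR target nucleotides on a simulated locus.

    Parameters
    ----------
    length_bp
        Number of sites in the locus.
    exon_intervals
        Sorted, disjoint half-open ``(start, end)`` ranges within
        ``[0, length_bp)``.
    tsr_sites
        Site indices at which mutations confer target-site resistance; every
        TSR site must lie inside an exon.
    name
        Free-form label.
    """

    length_bp: int
    exon_intervals: tuple[tuple[int, int], ...]
    tsr_sites: frozenset[int]
    name: str = "locus"

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        ivals = tuple((int(a), int(b)) for a, b in self.exon_intervals)
        object.__setattr__(self, "exon_intervals", ivals)
        object.__setattr__(self, "tsr_sites", frozenset(int(s) for s in self.tsr_sites))
        prev_end = 0
        for a, b in ivals:
            if not (0 <= a < b <= self.length_bp):
                raise ValueError(f"exon interval ({a}, {b}) outside [0, {self.length_bp})")
            if a < prev_end:
                raise ValueError("exon intervals must be sorted and disjoint")
            prev_end = b
        for s in self.tsr_sites:
            if not any(a <= s < b for a, b in ivals):
                raise ValueError(f"TSR site {s} lies outside every exon interval")

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exon_intervals)

    @property
    def coding_fraction(self) -> float:
        return self.exonic_length / self.length_bp

    def site_classes(self) -> np.ndarray:
        """Per-site class codes (0 noncoding, 1 exonic, 2 tsr), shape (length_bp,)."""
        codes = np.zeros(self.length_bp, dtype=np.uint8)
        for a, b in self.exon_intervals:
            codes[a:b] = 1
        for s in self.tsr_sites:
            codes[s] = 2
        return codes


@dataclass(frozen=True)
class DFEConfig:
    """Distribution of fitness effects for new mutations.

    ``gamma_mean_s`` is the mean selection coefficient of the *deleterious*
    class itself (not averaged over the neutral fraction); deleterious draws
    are ``-Gamma(shape=gamma_shape, mean=|gamma_mean_s|)``.
    """

    p_neutral_exon: float = 0.25
    gamma_mean_s: float = -0.000154
    gamma_shape: float = 0.245
    h_del: float = 0.5
    tsr_s_before: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_neutral_exon <= 1.0:
            raise ValueError("p_neutral_exon must be in [0, 1]")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.gamma_mean_s > 0:
            raise ValueError("gamma_mean_s must be <= 0")
        if not 0.0 <= self.h_del <= 1.0:
            raise ValueError("h_del must be in [0, 1]")

    @property
    def gamma_scale(self) -> float:
        """Scale parameter of the deleterious gamma (mean = shape * scale)."""
        return abs(self.gamma_mean_s) / self.gamma_shape


@dataclass(frozen=True)
class MutationEffect:
    s: float
    h: float
    site_class: SiteClass

    def __post_init__(self) -> None:
        if self.site_class in (SiteClass.EXON_NEUTRAL, SiteClass.NONCODING_NEUTRAL) and self.s != 0.0:
            raise ValueError("neutral classes require s = 0")
        if self.site_class is SiteClass.EXON_DELETERIOUS and self.s >= 0.0:
            raise ValueError("exon_deleterious requires s < 0")


def build_template(
    length_bp: int = 12_250,
    n_exons: int = 10,
    coding_fraction: float = 0.5,
    tsr_sites: "list[int] | None" = None,
    exon_intervals: "list[tuple[int, int]] | None" = None,
    n_tsr_sites: int = 7,
    name: str = "ACCase-like",
) -> LocusTemplate:
    """Construct a locus template with evenly spaced exons.

    If ``exon_intervals`` is given it is used verbatim; otherwise ``n_exons``
    equal-length exons totalling ``round(coding_fraction * length_bp)`` sites
    are spread evenly across the locus (intron before, between, and after).
    If ``tsr_sites`` is None, ``n_tsr_sites`` sites are placed evenly across
    the exonic sequence.

    Note: the exon/intron count and coding fraction of the real ACCase gene
    are configuration choices; users modelling a specific gene should supply
    ``exon_intervals`` from an annotation.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if exon_intervals is None:
        if n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        total_exonic = int(round(coding_fraction * length_bp))
        if not 0 < total_exonic <= length_bp:
            raise ValueError("coding_fraction must yield at least one exonic site")
        base, extra = divmod(total_exonic, n_exons)
        exon_lens = [base + (1 if i < extra else 0) for i in range(n_exons)]
        gap_total = length_bp - total_exonic
        gbase, gextra = divmod(gap_total, n_exons + 1)
        gap_lens = [gbase + (1 if i < gextra else 0) for i in range(n_exons + 1)]
        intervals = []
        pos = 0
        for i in range(n_exons):
            pos += gap_lens[i]
            intervals.append((pos, pos + exon_lens[i]))
            pos += exon_lens[i]
        exon_intervals = intervals

    if tsr_sites is None:
        exonic_sites: list[int] = []
        for a, b in exon_intervals:
            exonic_sites.extend(range(a, b))
        if n_tsr_sites > len(exonic_sites):
            raise ValueError("more TSR sites requested than exonic sites available")
        if n_tsr_sites == 0:
            tsr_sites = []
        else:
            idx = np.linspace(0, len(exonic_sites) - 1, n_tsr_sites).round().astype(int)
            tsr_sites = [exonic_sites[i] for i in idx]

    return LocusTemplate(
        length_bp=length_bp,
        exon_intervals=tuple(exon_intervals),
        tsr_sites=frozenset(tsr_sites),
        name=name,
    )


def classify_site(template: LocusTemplate, site: int) -> str:
    """Region label of a site ('tsr_target', 'exonic' or 'noncoding').

    TSR class takes precedence over plain exonic; classes are exhaustive and
    mutually exclusive.
    """
    if not 0 <= site < template.length_bp:
        raise IndexError(f"site {site} outside [0, {template.length_bp})")
    if site in template.tsr_sites:
        return "tsr_target"
    if any(a <= site < b for a, b in template.exon_intervals):
        return "exonic"
    return "noncoding"


def draw_effect(
    template: LocusTemplate,
    site: int,
    dfe: DFEConfig,
    rng: np.random.Generator,
) -> MutationEffect:
    """Draw the fitness effect of a new mutation at ``site``."""
    region = classify_site(template, site)
    if region == "tsr_target":
        return MutationEffect(s=dfe.tsr_s_before, h=1.0, site_class=SiteClass.TSR_TARGET)
    if region == "noncoding":
        return MutationEffect(s=0.0, h=0.5, site_class=SiteClass.NONCODING_NEUTRAL)
    if rng.random() < dfe.p_neutral_exon:
        return MutationEffect(s=0.0, h=0.5, site_class=SiteClass.EXON_NEUTRAL)
    s = -rng.gamma(dfe.gamma_shape, dfe.gamma_scale)
    if s == 0.0:  # underflow guard: keep the class invariant s < 0
        s = -np.nextafter(0.0, 1.0)
    return MutationEffect(s=s, h=dfe.h_del, site_class=SiteClass.EXON_DELETERIOUS)
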