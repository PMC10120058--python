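"""Amplicon haplotype typing: TSR codon calls, deduplication, sharing
tables and independent-origin counting.

Inputs are phased amplicon haplotype sequences (e.g. long-read consensus
haplotypes of the ACCase or ALS1 gene), a coordinate-mapped reference
sequence, and a codon table listing the known resistance codons (codon
number, reference amino acid, resistant amino acids, and the reference
coordinates of the codon's three nucleotides).

A haplotype is anchored to the reference by global pairwise alignment
(identity mapping is used as a fast path for equal-length, low-divergence
pairs); each listed codon is translated and reported resistant, wild-type
or uncallable (gap or ambiguous base), never silently wild type.

"Independent origin" counting groups the carriers of one resistance
mutation by backbone (sequence with the resistance codon masked); backbones
further apart than ``k_backbone`` mismatches are distinct, and a distinct
backbone is downgraded to a putative recombinant if it is exactly a
single-breakpoint mosaic of one observed resistant haplotype and one
observed wild-type haplotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .popstats import ContingencyTable2x2

__all__ = [
    "AmpliconHaplotype",
    "CodonSpec",
    "TSRCodonTable",
    "TSRCallResult",
    "read_haplotype_fasta",
    "write_haplotype_fasta",
    "call_tsr",
    "dedupe_haplotypes",
    "shared_2x2",
    "count_origins",
    "CANONICAL_TSR_CODONS",
]

# Known target-site resistance codons (codon number, reference amino acid,
# resistant amino acids).  ACCase numbering follows the standard
# Ile1781/Trp1999/Trp2027/Ile2041/Asp2078 nomenclature; ALS uses
# Pro197/Trp574.  Reference-coordinate positions are supplied per reference
# (see TSRCodonTable).
CANONICAL_TSR_CODONS = {
    "ACCase": (
        (1781, "Ile", ("Leu", "Thr", "Val")),
        (1999, "Trp", ("Leu",)),
        (2027, "Trp", ("Cys",)),
        (2041, "Ile", ("Asn",)),
        (2078, "Asp", ("Gly",)),
    ),
    "ALS1": (
        (197, "Pro", ("Thr", "Ala", "Ser")),
        (574, "Trp", ("Leu",)),
    ),
}


@dataclass(frozen=True)
class AmpliconHaplotype:
    """One phased amplicon haplotype sequence with sample metadata."""

    sequence: str
    sample_id: str
    population_id: str
    gene: str
    phase_index: int = 1

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGTN-"):
            raise ValueError("sequence alphabet must be within {A,C,G,T,N,-}")
        if self.phase_index not in (1, 2):
            raise ValueError("phase_index must be 1 or 2")

    @property
    def normalized(self) -> str:
        return self.sequence.replace("-", "")

    @property
    def name(self) -> str:
        return f"{self.sample_id}|{self.population_id}|{self.gene}|{self.phase_index}"


@dataclass(frozen=True)
class CodonSpec:
    codon_number: int
    ref_aa: str                       # three-letter code, e.g. "Ile"
    resistant_aas: tuple[str, ...]
    positions: tuple[int, int, int]   # 0-based reference coordinates

    def __post_init__(self) -> None:
        if len(self.positions) != 3:
            raise ValueError("a codon maps to exactly three reference positions")


@dataclass(frozen=True)
class TSRCodonTable:
    gene: str
    codons: tuple[CodonSpec, ...]

    @classmethod
    def from_json(cls, path) -> "TSRCodonTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "TSRCodonTable":
        codons = tuple(
            CodonSpec(
                codon_number=int(c["codon_number"]),
                ref_aa=c["ref_aa"],
                resistant_aas=tuple(c["resistant_aas"]),
                positions=tuple(int(p) for p in c["positions"]),
            )
            for c in data["codons"]
        )
        return cls(gene=data["gene"], codons=codons)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "codons": [
                {
                    "codon_number": c.codon_number,
                    "ref_aa": c.ref_aa,
                    "resistant_aas": list(c.resistant_aas),
                    "positions": list(c.positions),
                }
                for c in self.codons
            ],
        }


@dataclass
class TSRCallResult:
    """Per-haplotype TSR typing outcome.

    ``labels`` lists resistant calls like ``"ACCase Ile1781Leu"``;
    ``uncallable`` lists codon numbers that could not be translated
    (alignment gap or ambiguous base); ``codon_aa`` maps codon number to
    the translated amino acid (three-letter) where callable.
    """

    labels: list = field(default_factory=list)
    uncallable: list = field(default_factory=list)
    codon_aa: dict = field(default_factory=dict)

    @property
    def is_resistant(self) -> bool:
        return len(self.labels) > 0


def read_haplotype_fasta(path) -> list:
    """Read haplotypes from FASTA with ``>sampleID|populationID|gene|phase``
    headers."""
    haps = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise ValueError(f"header '{rec.id}' is not sampleID|populationID|gene|phase")
        haps.append(
            AmpliconHaplotype(
                sequence=str(rec.seq),
                sample_id=parts[0],
                population_id=parts[1],
                gene=parts[2],
                phase_index=int(parts[3]),
            )
        )
    return haps


def write_haplotype_fasta(haps, path) -> None:
    with open(path, "w") as fh:
        for h in haps:
            fh.write(f">{h.name}\n{h.sequence}\n")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2
    al.mismatch_score = -1
    al.open_gap_score = -6
    al.extend_gap_score = -1
    return al


def _profile(seq: str, reference: str) -> str:
    """Haplotype bases in reference coordinates ('-' where deleted).

    Equal-length low-divergence pairs map by identity (indel-free fast
    path); otherwise a global pairwise alignment anchors the haplotype.
    """
    if len(seq) == len(reference):
        mism = sum(1 for a, b in zip(seq, reference) if a != b)
        if mism <= 0.2 * len(reference):
            return seq
    aln = _aligner().align(reference, seq)[0]
    ref_idx, qry_idx = aln.indices
    out = ["-"] * len(reference)
    for r, q in zip(ref_idx, qry_idx):
        if r >= 0 and q >= 0:
            out[r] = seq[q]
    return "".join(out)


def call_tsr(
    hap: AmpliconHaplotype,
    table: TSRCodonTable,
    reference: str,
) -> TSRCallResult:
    """Translate each listed resistance codon of one haplotype.

    Codons containing an alignment gap or an N are reported in
    ``uncallable`` (never silently wild type); codons translating to a
    listed resistant amino acid yield a label ``"<gene> <Ref><num><Alt>"``.
    """
    if hap.gene != table.gene:
        raise ValueError(f"haplotype gene {hap.gene!r} does not match table gene {table.gene!r}")
    reference = reference.upper()
    prof = _profile(hap.normalized, reference)
    result = TSRCallResult()
    for codon in table.codons:
        bases = "".join(prof[p] for p in codon.positions)
        if "-" in bases or "N" in bases:
            result.uncallable.append(codon.codon_number)
            continue
        aa = seq3(str(Seq(bases).translate()))
        result.codon_aa[codon.codon_number] = aa
        if aa in codon.resistant_aas:
            result.labels.append(f"{table.gene} {codon.ref_aa}{codon.codon_number}{aa}")
    return result


def dedupe_haplotypes(
    haps,
    table: "TSRCodonTable | None" = None,
    reference: "str | None" = None,
) -> pd.DataFrame:
    """Cluster identical sequences (after uppercase/gap normalization) into
    nonredundant haplotypes.

    Returns one row per cluster with columns ``sequence``, ``count``,
    ``populations`` (sorted tuple), ``n_populations``, ``shared`` (present
    in >= 2 populations) and, when a codon table and reference are given,
    ``tsr_labels``/``is_tsr``.  Order-invariant: rows are sorted by
    descending count then sequence.
    """
    haps = list(haps)
    if not haps:
        raise ValueError("no haplotypes given")
    genes = {h.gene for h in haps}
    if len(genes) > 1:
        raise ValueError(f"mixed genes in input: {sorted(genes)}")
    groups: dict[str, list] = {}
    for h in haps:
        groups.setdefault(h.normalized, []).append(h)
    rows = []
    for seq, members in groups.items():
        pops = tuple(sorted({m.population_id for m in members}))
        row = {
            "sequence": seq,
            "count": len(members),
            "populations": pops,
            "n_populations": len(pops),
            "shared": len(pops) >= 2,
            "gene": members[0].gene,
        }
        if table is not None and reference is not None:
            res = call_tsr(members[0], table, reference)
            row["tsr_labels"] = tuple(res.labels)
            row["is_tsr"] = res.is_resistant
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["count", "sequence"], ascending=[False, True])
    return df.reset_index(drop=True)


def shared_2x2(nonredundant: pd.DataFrame) -> ContingencyTable2x2:
    """Sharing contingency table over nonredundant haplotypes:
    (TSR shared, TSR private, wild-type shared, wild-type private)."""
    if "is_tsr" not in nonredundant.columns:
        raise ValueError("nonredundant table lacks TSR annotation; dedupe with a codon table")
    tsr = nonredundant["is_tsr"].astype(bool)
    shared = nonredundant["shared"].astype(bool)
    return ContingencyTable2x2(
        a=int((tsr & shared).sum()),
        b=int((tsr & ~shared).sum()),
        c=int((~tsr & shared).sum()),
        d=int((~tsr & ~shared).sum()),
    )


def _single_breakpoint_mosaic(target: str, donors_a, donors_b) -> "tuple[str, str, int] | None":
    """Return (donor_a, donor_b, breakpoint) if ``target`` equals
    ``a[:b] + b[b:]`` for some observed pair and internal breakpoint."""
    L = len(target)
    for xa in donors_a:
        if len(xa) != L or xa == target:
            continue
        # longest common prefix with the resistant donor
        p = 0
        while p < L and target[p] == xa[p]:
            p += 1
        if p == 0:
            continue
        for yb in donors_b:
            if len(yb) != L or yb == target:
                continue
            s = 0
            while s < L and target[L - 1 - s] == yb[L - 1 - s]:
                s += 1
            # a breakpoint b in [max(1, L-s), min(p, L-1)] splices them
            lo = max(1, L - s)
            hi = min(p, L - 1)
            if lo <= hi:
                return (xa, yb, lo)
    return None


@dataclass
class OriginCallReport:
    """Independent-origin calls for one population and gene."""

    population_id: str
    gene: str
    per_mutation: pd.DataFrame        # mutation, n_backbones, n_independent, n_recombinant
    backbone_calls: pd.DataFrame      # mutation, backbone index, call, n_haplotypes
    n_independent_total: int          # distinct nonrecombinant TSR haplotypes in the field


def count_origins(
    haps,
    table: TSRCodonTable,
    reference: str,
    k_backbone: int = 3,
) -> OriginCallReport:
    """Count independent origins of each resistance mutation in one field.

    Carriers of a mutation are grouped by backbone (profile with the
    resistance codon masked) using single-linkage at ``<= k_backbone``
    mismatches; each backbone is called ``independent_origin`` unless its
    representative sequence is exactly a single-breakpoint mosaic of one
    observed resistant haplotype (different backbone) and one observed
    wild-type haplotype, in which case it is ``putative_recombinant``.
    """
    haps = list(haps)
    pops = {h.population_id for h in haps}
    if len(pops) > 1:
        raise ValueError("count_origins expects haplotypes from a single population")
    genes = {h.gene for h in haps}
    if len(genes) > 1:
        raise ValueError("count_origins expects haplotypes from a single gene")
    reference = reference.upper()
    profiles = [_profile(h.normalized, reference) for h in haps]
    calls = []
    for h, prof in zip(haps, profiles):
        res = call_tsr(
            AmpliconHaplotype(prof, h.sample_id, h.population_id, h.gene, h.phase_index),
            table,
            reference,
        )
        calls.append(res)
    wt_profiles = [p for p, c in zip(profiles, calls) if not c.is_resistant]
    tsr_profiles = [p for p, c in zip(profiles, calls) if c.is_resistant]

    codon_positions = {
        label_codon.codon_number: label_codon.positions for label_codon in table.codons
    }
    per_mut_rows = []
    backbone_rows = []
    mutations = sorted({lab for c in calls for lab in c.labels})
    for mut in mutations:
        codon_number = int("".join(ch for ch in mut.split()[-1] if ch.isdigit()))
        mask_pos = set(codon_positions[codon_number])
        carriers = [p for p, c in zip(profiles, calls) if mut in c.labels]
        # backbone = profile with the mutated codon masked
        def mask(p):
            return "".join("." if i in mask_pos else b for i, b in enumerate(p))

        uniq = {}
        for p in carriers:
            uniq.setdefault(mask(p), []).append(p)
        keys = sorted(uniq, key=lambda k: (-len(uniq[k]), k))
        # single-linkage clustering at <= k_backbone mismatches
        parent = list(range(len(keys)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = sum(1 for x, y in zip(keys[i], keys[j]) if x != y)
                if d <= k_backbone:
                    pi, pj = find(i), find(j)
                    if pi != pj:
                        parent[pj] = pi
        clusters: dict[int, list[int]] = {}
        for i in range(len(keys)):
            clusters.setdefault(find(i), []).append(i)
        # Greedy parsimony: process clusters by descending carrier count; a
        # cluster is a putative recombinant only if it is a mosaic of an
        # already-kept (independent) resistant haplotype and a wild type.
        # This prevents a mosaic and its donor from mutually explaining
        # each other away; an exact count tie is reported as ambiguous.
        ordered = sorted(
            clusters.values(),
            key=lambda ms: (-sum(len(uniq[keys[mi]]) for mi in ms), keys[ms[0]]),
        )
        n_indep = 0
        n_recomb = 0
        kept_profiles: list[str] = []
        kept_counts: list[int] = []
        for ci, members in enumerate(ordered):
            reps = [p for mi in members for p in uniq[keys[mi]]]
            rep = max(set(reps), key=reps.count)
            mosaic = _single_breakpoint_mosaic(rep, kept_profiles, wt_profiles)
            if mosaic is None:
                call = "independent_origin"
                n_indep += 1
                kept_profiles.append(rep)
                kept_counts.append(len(reps))
            elif kept_counts and len(reps) == max(kept_counts):
                call = "ambiguous"
                n_recomb += 1
            else:
                call = "putative_recombinant"
                n_recomb += 1
            backbone_rows.append(
                {
                    "mutation": mut,
                    "backbone": ci,
                    "call": call,
                    "n_haplotypes": len(reps),
                }
            )
        per_mut_rows.append(
            {
                "mutation": mut,
                "n_backbones": len(clusters),
                "n_independent": n_indep,
                "n_recombinant": n_recomb,
            }
        )
    # field-level total: distinct resistant haplotypes not explained as
    # mosaics of a kept haplotype and a wild type (same greedy order)
    prof_counts: dict[str, int] = {}
    for p in tsr_profiles:
        prof_counts[p] = prof_counts.get(p, 0) + 1
    kept_field: list[str] = []
    for p in sorted(prof_counts, key=lambda q: (-prof_counts[q], q)):
        if _single_breakpoint_mosaic(p, kept_field, wt_profiles) is None:
            kept_field.append(p)
    n_total = len(kept_field)
    return OriginCallReport(
        population_id=next(iter(pops)) if pops else "",
        gene=table.gene,
        per_mutation=pd.DataFrame(per_mut_rows),
        backbone_calls=pd.DataFrame(backbone_rows),
        n_independent_total=n_total,
    )
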