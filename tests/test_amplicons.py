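import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsrsweep import synth
from tsrsweep.amplicons import (
    AmpliconHaplotype,
    call_tsr,
    count_origins,
    dedupe_haplotypes,
    read_haplotype_fasta,
    shared_2x2,
    write_haplotype_fasta,
)
from tsrsweep.popstats import chi2_yates


@pytest.fixture(scope="module")
def accase():
    ref = synth.mock_reference("ACCase")
    table = synth.mock_codon_table("ACCase")
    return ref, table


def _hap(seq, sample="s1", pop="pop1", gene="ACCase", phase=1):
    return AmpliconHaplotype(seq, sample, pop, gene, phase)


class TestCallTSR:
    def test_reference_is_wild_type(self, accase):
        ref, table = accase
        res = call_tsr(_hap(ref), table, ref)
        assert res.labels == []
        assert res.uncallable == []
        assert res.codon_aa[1781] == "Ile"

    def test_ile1781leu_single_base_change(self, accase):
        # ATA -> TTA converts Ile1781 to Leu
        ref, table = accase
        spec = next(c for c in table.codons if c.codon_number == 1781)
        assert "".join(ref[p] for p in spec.positions) == "ATA"
        seq = list(ref)
        seq[spec.positions[0]] = "T"
        res = call_tsr(_hap("".join(seq)), table, ref)
        assert res.labels == ["ACCase Ile1781Leu"]

    def test_ambiguous_codon_is_uncallable_not_wild_type(self, accase):
        ref, table = accase
        spec1781 = next(c for c in table.codons if c.codon_number == 1781)
        spec2078 = next(c for c in table.codons if c.codon_number == 2078)
        seq = list(ref)
        seq[spec1781.positions[0]] = "T"    # resistant at 1781
        seq[spec2078.positions[1]] = "N"    # ambiguous at 2078
        res = call_tsr(_hap("".join(seq)), table, ref)
        assert res.labels == ["ACCase Ile1781Leu"]  # other codons still called
        assert res.uncallable == [2078]

    def test_indel_haplotype_is_anchored_by_alignment(self, accase):
        ref, table = accase
        spec = next(c for c in table.codons if c.codon_number == 1781)
        seq = list(ref)
        seq[spec.positions[0]] = "T"
        seq = "".join(seq)
        with_indel = seq[:500] + seq[520:]  # 20-bp deletion upstream of codons
        res = call_tsr(_hap(with_indel), table, ref)
        assert res.labels == ["ACCase Ile1781Leu"]

    def test_gene_mismatch_rejected(self, accase):
        ref, table = accase
        with pytest.raises(ValueError):
            call_tsr(_hap(ref, gene="ALS1"), table, ref)


class TestDedupe:
    def test_identical_sequences_shared_cluster(self, accase):
        ref, _ = accase
        df = dedupe_haplotypes([_hap(ref, "a", "pop1"), _hap(ref, "b", "pop2")])
        assert len(df) == 1
        assert df.iloc[0]["count"] == 2
        assert df.iloc[0]["shared"]

    def test_one_mismatch_two_clusters(self, accase):
        ref, _ = accase
        other = "A" + ref[1:] if ref[0] != "A" else "C" + ref[1:]
        df = dedupe_haplotypes([_hap(ref), _hap(other, "b")])
        assert len(df) == 2

    def test_gap_and_case_normalization(self, accase):
        ref, _ = accase
        df = dedupe_haplotypes([_hap(ref), _hap(ref[:100].lower() + "-" + ref[100:], "b")])
        assert len(df) == 1

    def test_mixed_genes_rejected(self, accase):
        ref, _ = accase
        with pytest.raises(ValueError, match="mixed genes"):
            dedupe_haplotypes([_hap(ref), _hap(ref, gene="ALS1")])

    @given(st.permutations(list(range(6))))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_invariance_and_idempotence(self, order):
        ref = synth.mock_reference("ACCase")
        haps = [_hap(ref, f"s{i}", f"pop{i % 2}") for i in range(3)]
        haps += [_hap("G" + ref[1:] if ref[0] != "G" else "T" + ref[1:], f"t{i}") for i in range(3)]
        shuffled = [haps[i] for i in order]
        df1 = dedupe_haplotypes(haps)
        df2 = dedupe_haplotypes(shuffled)
        assert df1[["sequence", "count", "shared"]].equals(df2[["sequence", "count", "shared"]])

    def test_planted_backbone_recovery(self, accase):
        cfg = synth.PanelConfig(n_backbones=5, backbone_divergence=6, seed=13)
        haps, truth = synth.generate_panel(cfg)
        df = dedupe_haplotypes(haps)
        assert len(df) == 5
        assert sorted(df["count"]) == sorted(truth.groupby("backbone").size())


class TestShared2x2:
    def test_all_private(self, accase):
        ref, table = accase
        other = ("G" if ref[5] != "G" else "T") + ref[1:]
        df = dedupe_haplotypes([_hap(ref, "a", "pop1"), _hap(other[:0] + other, "b", "pop2")],
                               table, ref)
        t = shared_2x2(df)
        assert t.a == 0 and t.c == 0
        assert t.a + t.b + t.c + t.d == len(df)

    def test_reproduces_printed_sharing_counts(self, accase):
        ref, table = accase
        cfg = synth.sharing_panel_config()
        haps, _ = synth.generate_panel(cfg)
        df = dedupe_haplotypes(haps, table, ref)
        t = shared_2x2(df)
        assert (t.a, t.b, t.c, t.d) == (20, 42, 55, 133)
        _stat, p = chi2_yates(t)
        assert p == pytest.approx(0.7736, abs=5e-4)


class TestCountOrigins:
    def test_single_tsr_haplotype_single_origin(self, accase):
        ref, table = accase
        cfg = synth.PanelConfig(
            n_populations=1, n_backbones=2,
            tsr_events=(synth.TSREvent("Trp1999Leu", 1, ("pop1",), 2),),
            seed=3,
        )
        haps, _ = synth.generate_panel(cfg)
        rep = count_origins(haps, table, ref)
        assert rep.per_mutation.iloc[0]["n_independent"] == 1
        assert rep.n_independent_total == 1

    def test_two_backbones_two_origins(self, accase):
        ref, table = accase
        haps, _ = synth.generate_panel(synth.origin_panel_config())
        rep = count_origins(haps, table, ref)
        row = rep.per_mutation.iloc[0]
        assert row["mutation"] == "ACCase Ile1781Leu"
        assert row["n_backbones"] == 2
        assert row["n_independent"] == 2
        assert rep.n_independent_total == 2

    def test_single_crossover_flagged_recombinant(self, accase):
        ref, table = accase
        haps, truth = synth.generate_panel(synth.recombinant_panel_config())
        rep = count_origins(haps, table, ref)
        calls = rep.backbone_calls
        assert (calls["call"] == "putative_recombinant").sum() == 1
        assert (calls["call"] == "independent_origin").sum() == 1
        assert rep.n_independent_total == 1

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
    def test_unambiguous_panels_recover_truth_exactly(self, accase, seed):
        # backbones far apart, no recombinants: planted origin count is
        # recovered on every panel
        ref, table = accase
        cfg = synth.PanelConfig(
            n_populations=1, n_backbones=4, backbone_divergence=8,
            tsr_events=(
                synth.TSREvent("Ile1781Leu", 1, ("pop1",), 2),
                synth.TSREvent("Ile1781Leu", 2, ("pop1",), 2),
                synth.TSREvent("Asp2078Gly", 3, ("pop1",), 1),
            ),
            seed=seed,
        )
        haps, _ = synth.generate_panel(cfg)
        rep = count_origins(haps, table, ref)
        by_mut = rep.per_mutation.set_index("mutation")["n_independent"]
        assert by_mut["ACCase Ile1781Leu"] == 2
        assert by_mut["ACCase Asp2078Gly"] == 1
        assert rep.n_independent_total == 3

    def test_mixed_population_rejected(self, accase):
        ref, table = accase
        with pytest.raises(ValueError):
            count_origins([_hap(ref, "a", "pop1"), _hap(ref, "b", "pop2")], table, ref)


class TestFastaRoundTrip:
    def test_read_write(self, tmp_path, accase):
        ref, _ = accase
        haps = [_hap(ref, "s1", "p1", phase=1), _hap(ref, "s1", "p1", phase=2)]
        path = tmp_path / "h.fa"
        write_haplotype_fasta(haps, path)
        back = read_haplotype_fasta(path)
        assert [h.name for h in back] == [h.name for h in haps]
        assert back[0].sequence == ref

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">seq1\nACGT\n")
        with pytest.raises(ValueError):
            read_haplotype_fasta(p)
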