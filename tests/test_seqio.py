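"""Alignment parsing, indel coding, haplotype collapsing, polymorphism."""

import math

import numpy as np
import pytest

from phylogrid import seqio
from phylogrid.seqio import (
    Alignment,
    AlignmentError,
    InsufficientDataError,
    SampleTableError,
    code_indels,
    collapse_haplotypes,
    concatenate_coded,
    read_alignment,
    read_sample_table,
    summarize_polymorphism,
)

from conftest import random_alignment


class TestReadAlignment:
    def test_parses_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a extra tokens\nACGTA\n>b\nACG-A\n")
        aln = read_alignment(p)
        assert aln.length == 5
        assert aln.ids == ("a", "b")

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGTA\n>b\nACGTAA\n")
        with pytest.raises(AlignmentError, match="unequal"):
            read_alignment(p)

    def test_lowercase_normalised(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacgta\n>b\nacgta\n")
        aln = read_alignment(p)
        assert aln.records["a"] == "ACGTA"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(AlignmentError):
            read_alignment(p)

    def test_unknown_symbols_become_n(self):
        aln = Alignment.from_sequences({"a": "ACRTA"})
        assert aln.records["a"] == "ACNTA"


class TestReadSampleTable:
    def _write(self, tmp_path, body, header="id\tspecies\tlat\tlon"):
        p = tmp_path / "samples.tsv"
        p.write_text(header + "\n" + body)
        return p

    def test_basic_row(self, tmp_path):
        t = read_sample_table(self._write(tmp_path, "s1\tHaloAzu\t0.5\t9.25\n"))
        assert t.coords("s1") == (0.5, 9.25)
        assert t.species_of("s1") == "HaloAzu"

    def test_latitude_out_of_range(self, tmp_path):
        with pytest.raises(SampleTableError, match="latitude"):
            read_sample_table(self._write(tmp_path, "s1\tX\t91\t9\n"))

    def test_missing_column(self, tmp_path):
        with pytest.raises(SampleTableError, match="missing column"):
            read_sample_table(
                self._write(tmp_path, "s1\tX\t1\n", header="id\tspecies\tlat")
            )

    def test_duplicate_id(self, tmp_path):
        with pytest.raises(SampleTableError, match="duplicate"):
            read_sample_table(
                self._write(tmp_path, "s1\tX\t1\t2\ns1\tX\t3\t4\n")
            )


class TestCodeIndels:
    def test_shared_gap_run_single_character(self):
        aln = Alignment.from_sequences(
            {"a": "ACGTA", "b": "AC--A", "c": "ACGTA"}
        )
        coded = code_indels(aln)
        assert coded.indel_spans == ((2, 4),)
        assert coded.sub_columns == ()
        assert coded.matrix["b"] == (1,)
        assert coded.matrix["a"] == (0,)

    def test_substitution_only(self):
        coded = code_indels(
            Alignment.from_sequences({"a": "ACGTA", "b": "ACGTT"})
        )
        assert coded.n_indel == 0
        assert coded.sub_columns == (4,)

    def test_distinct_overlapping_runs_are_distinct_characters(self):
        # maximal runs at columns 2-3 and column 2 (1-based) are different
        # spans, hence two indel characters
        coded = code_indels(
            Alignment.from_sequences({"a": "A--TA", "b": "A-GTA"})
        )
        assert set(coded.indel_spans) == {(1, 3), (1, 2)}
        assert coded.n_indel == 2
        # the longer gap subsumes the shorter span -> missing, not 0
        i_short = coded.indel_spans.index((1, 2))
        assert coded.matrix["a"][coded.n_sub + i_short] is None

    def test_no_gaps_degenerate(self, rng):
        aln = random_alignment(rng, n=6, length=30)
        assert code_indels(aln).n_indel == 0

    def test_snp_count_matches_per_column_brute_force(self, rng):
        # characters with >= 2 states, checked column by column
        for _ in range(5):
            aln = random_alignment(rng, n=20, length=50)
            coded = code_indels(aln)
            brute = sum(
                1
                for c in range(aln.length)
                if len({aln.records[s][c] for s in aln.ids}) >= 2
            )
            assert coded.n_characters == brute


class TestCollapseHaplotypes:
    def test_identical_sequences_one_haplotype(self):
        aln = Alignment.from_sequences(
            {"a": "ACGTA", "b": "ACGTA", "c": "ACGTA"}
        )
        haps = collapse_haplotypes(code_indels(aln))
        assert haps.ids == ("H1",)
        assert haps.counts["H1"] == 3

    def test_counts_ordered_decreasing(self):
        aln = Alignment.from_sequences(
            {"a": "ACGTT", "b": "ACGTA", "c": "ACGTA"}
        )
        haps = collapse_haplotypes(code_indels(aln))
        assert [haps.counts[h] for h in haps.ids] == [2, 1]
        assert set(haps.carriers["H1"]) == {"b", "c"}

    def test_ambiguous_sample_dropped(self, caplog):
        aln = Alignment.from_sequences(
            {"a": "ACGTA", "b": "ACGTT", "c": "ACGTN"}
        )
        with caplog.at_level("WARNING"):
            haps = collapse_haplotypes(code_indels(aln))
        assert haps.n == 2
        assert "dropping" in caplog.text

    def test_n_only_drops_at_varying_characters(self):
        # N at an invariant column is harmless ...
        aln = Alignment.from_sequences({"a": "ACGTN", "b": "ACGTA"})
        assert collapse_haplotypes(code_indels(aln)).n == 2
        # ... but N at a varying column makes the sample unplaceable
        aln2 = Alignment.from_sequences({"a": "NCGTA", "b": "ACGTA", "c": "TCGTA"})
        assert "a" not in collapse_haplotypes(code_indels(aln2)).assignment()

    def test_all_dropped_is_error(self):
        aln = Alignment.from_sequences(
            {"a": "NG", "b": "AN", "c": "GN", "d": "NA"}
        )
        with pytest.raises(InsufficientDataError):
            collapse_haplotypes(code_indels(aln))

    def test_multilocus_concatenation(self):
        l1 = code_indels(Alignment.from_sequences({"a": "ACGTA", "b": "ACGTT"}))
        l2 = code_indels(Alignment.from_sequences({"a": "GGAA", "b": "GGAA"}))
        cat = concatenate_coded([l1, l2])
        assert cat.length == 9
        haps = collapse_haplotypes(cat)
        assert len(haps.ids) == 2
        # second-locus columns are offset by the first locus length
        l3 = code_indels(Alignment.from_sequences({"a": "GGAA", "b": "GGTA"}))
        cat2 = concatenate_coded([l1, l3])
        assert cat2.sub_columns == (4, 5 + 2)

    def test_mismatched_sample_sets_rejected(self):
        l1 = code_indels(Alignment.from_sequences({"a": "ACGTA", "b": "ACGTT"}))
        l2 = code_indels(Alignment.from_sequences({"a": "GGAA", "c": "GGAA"}))
        with pytest.raises(SampleTableError):
            concatenate_coded([l1, l2])

    def test_roundtrip_expand(self, rng):
        aln = random_alignment(rng, n=15, length=40)
        coded = code_indels(aln)
        haps = collapse_haplotypes(coded)
        expanded = haps.expand()
        for s in aln.ids:
            assert expanded[s] == tuple(coded.matrix[s])

    def test_missing_from_sample_table_rejected(self, tiny_alignment):
        coded = code_indels(tiny_alignment)
        table = seqio.SampleTable.from_records([("s1", "spX", 0.0, 0.0)])
        with pytest.raises(SampleTableError):
            collapse_haplotypes(coded, table)


class TestPolymorphism:
    def test_two_sequences_three_diffs(self):
        # pi = 2 * (2 * 0.5 * 0.5 * 3) / 600 = 0.005
        base = "A" * 600
        other = "T" * 3 + "A" * 597
        summ = summarize_polymorphism(
            *(lambda a: (a, code_indels(a)))(
                Alignment.from_sequences({"x": base, "y": other})
            )
        )
        assert summ.pi == pytest.approx(0.005)
        assert summ.n_snps == 3

    def test_monomorphic(self):
        aln = Alignment.from_sequences({"a": "ACGT", "b": "ACGT"})
        summ = summarize_polymorphism(aln, code_indels(aln))
        assert summ.pi == 0.0
        assert summ.n_snps == 0
        assert summ.pi_sd == 0.0

    def test_indel_counts_one_step(self):
        aln = Alignment.from_sequences({"a": "ACGTA", "b": "AC--A"})
        summ = summarize_polymorphism(aln, code_indels(aln))
        assert summ.n_snps == 1
        assert summ.pi == pytest.approx(2 * (2 * 0.25 * 1) / 5)

    def test_single_sequence_rejected(self):
        aln = Alignment.from_sequences({"a": "ACGT"})
        with pytest.raises(InsufficientDataError):
            summarize_polymorphism(aln, code_indels(aln))

    @pytest.mark.parametrize("dup", [1, 2])
    def test_pi_equals_brute_force_pair_average(self, rng, dup):
        # pi must equal the mean over ordered pairs of distinct individuals
        # of (coded distance / L) -- also after duplicating the sample set
        aln = random_alignment(rng, n=8, length=60)
        if dup == 2:
            aln = Alignment.from_sequences(
                {f"{s}_{k}": aln.records[s] for k in range(2) for s in aln.ids}
            )
        coded = code_indels(aln)
        summ = summarize_polymorphism(aln, coded)
        ids = aln.ids
        tot, cnt = 0.0, 0
        for i in ids:
            for j in ids:
                if i != j:
                    tot += seqio.coded_distance(coded.matrix[i], coded.matrix[j])
                    cnt += 1
        assert summ.pi == pytest.approx(tot / cnt / aln.length, abs=1e-12)

    def test_pi_invariant_under_relabeling(self, rng):
        aln = random_alignment(rng, n=10, length=50)
        coded = code_indels(aln)
        pi1 = summarize_polymorphism(aln, coded).pi
        renamed = Alignment.from_sequences(
            {f"z{k}": aln.records[s] for k, s in enumerate(reversed(aln.ids))}
        )
        pi2 = summarize_polymorphism(renamed, code_indels(renamed)).pi
        assert pi1 == pytest.approx(pi2, abs=1e-15)

    def test_sd_formula(self):
        # Nei-style total variance at n=2, L=600, pi=0.005
        base = "A" * 600
        other = "T" * 3 + "A" * 597
        aln = Alignment.from_sequences({"x": base, "y": other})
        summ = summarize_polymorphism(aln, code_indels(aln))
        n, L, pi = 2, 600, 0.005
        var = (n + 1) / (3 * (n - 1) * L) * pi + (
            2 * (n * n + n + 3) / (9 * n * (n - 1))
        ) * pi**2
        assert summ.pi_sd == pytest.approx(math.sqrt(var))
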