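"""Sequence I/O and alignment machinery."""

import logging
from functools import lru_cache
from itertools import product

import pytest

from barcodekey.seq_panel import (
    DnaSequence,
    MultipleAlignment,
    SequenceError,
    center_star_msa,
    pairwise_align,
    read_alignment_fasta,
    read_fasta,
    read_genbank_sequence,
    revcomp,
    write_fasta,
)

from conftest import random_dna


class TestFasta:
    def test_single_record_case_folding(self, write_text):
        path = write_text("one.fasta", ">s1\nacgt\n")
        records = read_fasta(path)
        assert [(r.identifier, r.residues) for r in records] == [("s1", "ACGT")]

    def test_round_trip_identity(self, write_text, tmp_path, rng):
        seqs = [DnaSequence(f"s{i}", random_dna(rng, 150)) for i in range(5)]
        out = tmp_path / "out.fasta"
        write_fasta(seqs, out)
        again = read_fasta(out)
        assert [(s.identifier, s.residues) for s in again] == [
            (s.identifier, s.residues) for s in seqs
        ]

    def test_order_matches_independent_parse(self, write_text, rng):
        lines = []
        expected = []
        for i in range(5):
            seq = random_dna(rng, 80)
            lines.append(f">rec{i} extra description\n{seq[:40]}\n{seq[40:]}\n")
            expected.append((f"rec{i}", seq))
        path = write_text("panel.fasta", "".join(lines))
        records = read_fasta(path)
        # independent line-by-line parse
        naive = []
        ident, chunks = None, []
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                if ident is not None:
                    naive.append((ident, "".join(chunks)))
                ident, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.strip())
        naive.append((ident, "".join(chunks)))
        assert [(r.identifier, r.residues) for r in records] == naive == expected

    @pytest.mark.parametrize(
        "content,message",
        [
            ("", "no FASTA records"),
            (">a\nACGT\n>a\nACGT\n", "duplicate identifier"),
            (">a\nACXT\n", "illegal characters"),
            (">a\n\n", "empty"),
        ],
    )
    def test_rejections_name_offender(self, write_text, content, message):
        path = write_text("bad.fasta", content)
        with pytest.raises(SequenceError, match=message):
            read_fasta(path)

    def test_prealigned_file_detected(self, write_text):
        path = write_text("aln.fasta", ">a\nAC-GT\n>b\nACTGT\n")
        msa = read_alignment_fasta(path)
        assert msa is not None
        assert msa.rows == ["AC-GT", "ACTGT"]
        assert msa.ungapped("a") == "ACGT"

    def test_unaligned_file_not_mistaken_for_alignment(self, write_text):
        path = write_text("plain.fasta", ">a\nACGT\n>b\nACGTT\n")
        assert read_alignment_fasta(path) is None


MOCK_GENBANK = """LOCUS       TEST0001                  10 bp    DNA     linear   PLN 01-JAN-2020
ACCESSION   TEST0001
FEATURES             Location/Qualifiers
     source          1..10
ORIGIN
        1 acgtacgtac
//
"""


class TestGenBank:
    def test_minimal_origin_parse(self, write_text):
        path = write_text("mini.gb", MOCK_GENBANK)
        acc, seq = read_genbank_sequence(path)
        assert acc == "TEST0001"
        assert seq.residues == "ACGTACGTAC"

    def test_length_disagreement_warns_but_returns(self, write_text, caplog):
        content = MOCK_GENBANK.replace("10 bp", "999 bp")
        path = write_text("mism.gb", content)
        with caplog.at_level(logging.WARNING):
            _, seq = read_genbank_sequence(path)
        assert seq.residues == "ACGTACGTAC"
        assert any("disagrees" in rec.message for rec in caplog.records)

    def test_missing_origin_rejected(self, write_text):
        path = write_text("noorig.gb", "LOCUS  X  10 bp\nACCESSION  X\n//\n")
        with pytest.raises(SequenceError, match="ORIGIN"):
            read_genbank_sequence(path)

    def test_mock_record_length_is_origin_letter_count(self, write_text, rng):
        seq = random_dna(rng, 1000).lower()
        body = "".join(
            f"  {i + 1:>7} " + " ".join(seq[i + j : i + j + 10] for j in range(0, 60, 10)) + "\n"
            for i in range(0, 1000, 60)
        )
        content = (
            f"LOCUS       MOCK1 {len(seq)} bp DNA linear\nACCESSION   MOCK1\nORIGIN\n{body}//\n"
        )
        path = write_text("kb.gb", content)
        _, parsed = read_genbank_sequence(path)
        letters = sum(c.isalpha() for line in body.splitlines() for c in line)
        assert len(parsed.residues) == letters == 1000


@lru_cache(maxsize=None)
def _best_alignment_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Oracle: top-down maximization over the three alignment moves."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    sub = match if a[0] == b[0] and a[0] != "N" else mismatch
    return max(
        _best_alignment_score(a[1:], b[1:]) + sub,
        _best_alignment_score(a[1:], b) + gap,
        _best_alignment_score(a, b[1:]) + gap,
    )


class TestPairwiseAlign:
    def test_identity(self):
        aln_a, aln_b, score = pairwise_align("ACGT", "ACGT")
        assert (aln_a, aln_b, score) == ("ACGT", "ACGT", 4)

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            pairwise_align("A", "")

    def test_matches_enumeration_oracle_on_all_short_pairs(self):
        strings = [
            "".join(p)
            for length in range(1, 5)
            for p in product("AC", repeat=length)
        ]
        for a in strings:
            for b in strings:
                aln_a, aln_b, score = pairwise_align(a, b)
                assert score == _best_alignment_score(a, b), (a, b)
                assert aln_a.replace("-", "") == a
                assert aln_b.replace("-", "") == b

    def test_matches_biopython_on_random_pairs(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        for _ in range(25):
            a = random_dna(rng, int(rng.integers(5, 40)))
            b = random_dna(rng, int(rng.integers(5, 40)))
            _, _, score = pairwise_align(a, b)
            assert score == aligner.score(a, b)

    def test_n_never_matches(self):
        _, _, score = pairwise_align("N", "N")
        assert score == -1

    def test_deterministic_traceback(self):
        results = {pairwise_align("ACGTACGT", "ACGACG") for _ in range(5)}
        assert len(results) == 1


class TestCenterStar:
    def test_identical_sequences_no_gap_columns(self):
        table = {f"s{i}": DnaSequence(f"s{i}", "ACGTACGT") for i in range(3)}
        msa = center_star_msa(table)
        assert all("-" not in row for row in msa.rows)
        assert msa.n_columns == 8

    def test_single_indel(self):
        table = {"a": DnaSequence("a", "ACGT"), "b": DnaSequence("b", "ACT")}
        msa = center_star_msa(table)
        assert msa.n_columns == 4
        assert msa.ungapped("a") == "ACGT"
        assert msa.ungapped("b") == "ACT"
        assert sum(row.count("-") for row in msa.rows) == 1

    def test_degapping_restores_inputs(self, rng):
        base = random_dna(rng, 200)
        table = {}
        for i in range(4):
            seq = list(base)
            for pos in rng.integers(0, 200, size=4):
                seq[pos] = "ACGT"[int(rng.integers(0, 4))]
            table[f"s{i}"] = DnaSequence(f"s{i}", "".join(seq))
        msa = center_star_msa(table)
        for label in table:
            assert msa.ungapped(label) == table[label].residues

    def test_induced_scores_near_optimal_at_low_divergence(self, rng):
        base = random_dna(rng, 300)
        table = {}
        for i in range(5):
            seq = list(base)
            for pos in rng.choice(300, size=6, replace=False):  # 2% divergence
                seq[pos] = [b for b in "ACGT" if b != seq[pos]][int(rng.integers(0, 3))]
            table[f"s{i}"] = DnaSequence(f"s{i}", "".join(seq))
        msa = center_star_msa(table)

        def induced_score(ra, rb):
            score = 0
            for x, y in zip(ra, rb):
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    score -= 2
                elif x == y and x != "N":
                    score += 1
                else:
                    score -= 1
            return score

        labels = msa.labels
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                _, _, optimal = pairwise_align(table[la].residues, table[lb].residues)
                ind = induced_score(msa.rows[labels.index(la)], msa.rows[labels.index(lb)])
                assert ind >= 0.9 * optimal

    def test_coordinate_map_strictly_increasing(self):
        msa = MultipleAlignment(["a", "b"], ["AC-GT", "ACTGT"])
        coords = [msa.coord_maps[0][c] for c in sorted(msa.coord_maps[0])]
        assert coords == sorted(coords) == [0, 1, 2, 3]


def test_revcomp_involution(rng):
    seq = random_dna(rng, 50)
    assert revcomp(revcomp(seq)) == seq
    assert revcomp("ACGTN") == "NACGT"
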