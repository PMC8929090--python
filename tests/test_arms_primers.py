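"""ARMS primer construction, quality filters and pair design."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodekey.arms_primers import (
    ArmsDesignError,
    DesignConstraints,
    arms_modify,
    design_allele_specific_pairs,
    pair_penalty,
    primer_quality_filters,
    tm_estimate,
)
from barcodekey.seq_panel import DnaSequence, SequenceError, align_panel_locus, revcomp
from barcodekey.synthetic import PanelSimSpec, simulate_panel

from conftest import random_dna


class TestTm:
    def test_gc_count_formula_hand_value(self):
        # 20-mer with 11 G/C: 64.9 + 41*(11-16.4)/20 = 53.83
        primer = "GCGCGCGCGCGAATTAATTA"
        assert (primer.count("G") + primer.count("C")) == 11
        assert tm_estimate(primer) == pytest.approx(53.83)

    def test_monotone_in_gc(self):
        assert tm_estimate("A" * 20) < tm_estimate("G" * 20)

    @given(st.text(alphabet="ACGT", min_size=14, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_revcomp_invariance(self, seq):
        assert tm_estimate(seq) == pytest.approx(tm_estimate(revcomp(seq)))

    def test_short_input_rejected(self):
        with pytest.raises(SequenceError):
            tm_estimate("ACGTACGTACGACA"[:13])


class TestArmsModify:
    def test_single_substitution_at_offset_two(self):
        core = "ACGTACGTACGTACGTTACG"
        modified, offset = arms_modify(core, {"t": "A", "s2": "A", "s3": "A"})
        assert offset == 2
        diffs = [i for i, (x, y) in enumerate(zip(core, modified)) if x != y]
        assert diffs == [len(core) - 3]
        assert modified[-3] != "A"

    def test_fixed_point_when_already_mismatching(self):
        core = "ACGTACGTACGTACGTTGCG"  # offset-2 base 'G'
        modified, _ = arms_modify(core, {"t": "A", "s2": "C"})
        assert modified == core

    def test_replacement_avoids_every_template(self):
        core = "ACGTACGTACGTACGTTACG"
        modified, _ = arms_modify(core, {"a": "A", "b": "C", "c": "G"})
        assert modified[-3] == "T"  # only base excluded by none

    def test_no_legal_base_raises(self):
        core = "ACGTACGTACGTACGTTACG"
        with pytest.raises(ArmsDesignError):
            arms_modify(core, {"a": "A", "b": "C", "c": "G", "d": "T"})

    def test_strong_mismatch_preferred(self):
        # template base (primer sense) 'A' sits across 'T' (pyrimidine);
        # legal replacements C,G,T: C and T give pyrimidine-pyrimidine
        # appositions, G gives purine-pyrimidine; tie C<T resolved to C
        core = "ACGTACGTACGTACGTTACG"
        modified, _ = arms_modify(core, {"t": "A"})
        assert modified[-3] == "C"


class TestQualityFilters:
    def test_homopolymer_violation(self):
        ok, reasons = primer_quality_filters("ACGTAAAAAGTACGTACGTA")
        assert not ok and "homopolymer" in reasons

    def test_low_gc_reference_primer_fails_gc_filter(self):
        # a wet-lab-validated primer with 3/20 GC still trips the default
        # window — design-time filters are advisory for imported primers
        ok, reasons = primer_quality_filters("GAAATTACTTTTAAATTCAT")
        assert not ok and "gc_range" in reasons
        assert (3 / 20) < DesignConstraints().gc_range[0]

    def test_clean_primer_passes_with_no_reasons(self):
        ok, reasons = primer_quality_filters("ACGTACGGCATCACTATGCA")
        assert ok and reasons == []

    def test_length_violation(self):
        ok, reasons = primer_quality_filters("ACGTACGTACGTACG")
        assert not ok and "length" in reasons


def _panel_msa(seed=3, **kwargs):
    spec = PanelSimSpec(species=5, locus_length=1000, divergence=0.0, snps=1,
                        seed=seed, **kwargs)
    panel, truth = simulate_panel(spec)
    return align_panel_locus(panel.loci["locus1"]), truth


class TestDesign:
    def test_product_range_and_anchor_contract(self):
        msa, truth = _panel_msa()
        target = "sp1"
        planted = next(v for v in truth if v.species == target)
        pairs = design_allele_specific_pairs(msa, target, locus="locus1")
        assert pairs
        for pair in pairs:
            assert 100 <= pair.product_length <= 1000
            allele_specific = pair.forward if pair.forward.site else pair.reverse
            assert allele_specific.site is not None
            start, end = allele_specific.interval
            if allele_specific.strand == "+":
                assert end - 1 == planted.species_position
            else:
                assert start == planted.species_position

    def test_designed_mismatch_bookkeeping(self):
        msa, _ = _panel_msa()
        template = msa.ungapped("sp1")
        for pair in design_allele_specific_pairs(msa, "sp1", locus="locus1"):
            primer = pair.forward if pair.forward.site else pair.reverse
            start, end = primer.interval
            window = template[start:end]
            expected = window if primer.strand == "+" else revcomp(window)
            diffs = [i for i, (x, y) in enumerate(zip(primer.residues, expected)) if x != y]
            assert diffs == [len(primer.residues) - 3]  # 3' offset 2 only

    def test_mismatch_counts_against_each_species(self):
        msa, _ = _panel_msa()
        pairs = design_allele_specific_pairs(msa, "sp1", locus="locus1")
        primer = pairs[0].forward if pairs[0].forward.site else pairs[0].reverse
        start, end = primer.interval
        for sp in msa.labels:
            window = msa.ungapped(sp)[start:end]  # invariant context: same coords
            expected = window if primer.strand == "+" else revcomp(window)
            n_mismatch = sum(x != y for x, y in zip(primer.residues, expected))
            if sp == "sp1":
                assert n_mismatch == 1
            else:
                assert n_mismatch == 2
                assert primer.residues[-1] != expected[-1]  # 3'-terminal mismatch

    def test_no_sites_yields_empty(self):
        table = {f"s{i}": DnaSequence(f"s{i}", "ACGT" * 100) for i in range(4)}
        msa = align_panel_locus(table)
        assert design_allele_specific_pairs(msa, "s1") == []

    def test_matches_exhaustive_enumeration_on_toy_locus(self, rng):
        spec = PanelSimSpec(species=4, locus_length=600, divergence=0.0, snps=(1, 0, 0, 0),
                            seed=17)
        panel, truth = simulate_panel(spec)
        msa = align_panel_locus(panel.loci["locus1"])
        constraints = DesignConstraints(max_pairs_per_site=None)
        pairs = design_allele_specific_pairs(msa, "sp1", constraints, "locus1")
        got = set()
        for p in pairs:
            allele_specific = p.forward if p.forward.site else p.reverse
            mate = p.reverse if p.forward.site else p.forward
            got.add((allele_specific.strand, len(allele_specific.residues),
                     mate.interval, p.product_length))
        oracle = _enumerate_designs(msa, "sp1", truth, constraints)
        assert got == oracle

    def test_ranking_is_deterministic(self):
        msa, _ = _panel_msa()
        a = design_allele_specific_pairs(msa, "sp2", locus="locus1")
        b = design_allele_specific_pairs(msa, "sp2", locus="locus1")
        assert [p.name for p in a] == [p.name for p in b]
        assert [p.penalty for p in a] == sorted(p.penalty for p in a)


def _enumerate_designs(msa, target, truth, constraints):
    """Independent brute force over (orientation, AS length, mate window)."""
    template = msa.ungapped(target)
    anchor = next(v for v in truth if v.species == target).species_position
    lo, hi = constraints.primer_length
    plo, phi = constraints.product_length
    combos = set()
    for orientation in "+-":
        for L in range(lo, hi + 1):
            if orientation == "+":
                start, end = anchor - L + 1, anchor + 1
            else:
                start, end = anchor, anchor + L
            if start < 0 or end > len(template):
                continue
            core = template[start:end] if orientation == "+" else revcomp(template[start:end])
            tb_pos = anchor - 2 if orientation == "+" else anchor + 2
            base = template[tb_pos] if orientation == "+" else revcomp(template[tb_pos])
            try:
                modified, _ = arms_modify(core, {sp: base for sp in msa.labels})
            except ArmsDesignError:
                continue
            if not primer_quality_filters(modified, constraints)[0]:
                continue
            for Lm in range(lo, hi + 1):
                for m_start in range(0, len(template) - Lm + 1):
                    m_end = m_start + Lm
                    if orientation == "+":
                        if m_start < end:
                            continue
                        product = m_end - start
                        mate = revcomp(template[m_start:m_end])
                        fwd, rev = modified, mate
                    else:
                        if m_end > start:
                            continue
                        product = end - m_start
                        mate = template[m_start:m_end]
                        fwd, rev = mate, modified
                    if not (plo <= product <= phi):
                        continue
                    if not primer_quality_filters(mate, constraints)[0]:
                        continue
                    if abs(tm_estimate(fwd) - tm_estimate(rev)) > constraints.max_pair_tm_diff:
                        continue
                    from barcodekey.arms_primers import max_3prime_complement_run

                    if max(
                        max_3prime_complement_run(fwd, rev),
                        max_3prime_complement_run(rev, fwd),
                    ) > constraints.max_end_complement:
                        continue
                    combos.add((orientation, L, (m_start, m_end), product))
    return combos


def test_pair_penalty_components():
    # equal-Tm 20-mers at 50% GC are penalty-free
    f = "ACGTACGTACGTACGTACGT"
    assert pair_penalty(f, f) == pytest.approx(0.0)
    longer = "ACGTACGTACGTACGTACGTAC"  # +2 nt, same GC fraction
    assert pair_penalty(f, longer) > 0
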