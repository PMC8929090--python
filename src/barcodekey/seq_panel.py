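"""Sequence and panel I/O plus the alignment machinery behind diagnostic-site detection.

A *panel* is a per-locus collection of species-labelled barcode sequences
(one sequence per species, as in a typical multi-species barcoding study).
This module reads panels from multi-FASTA files (optionally pre-aligned,
CLC-style, with ``-`` gaps), reads amplification templates from minimal
GenBank flat files, and builds per-locus multiple alignments with a
center-star strategy on top of deterministic Needleman-Wunsch pairwise
alignment.

Coordinate convention: 0-based, half-open, everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"
ALIGNED_ALPHABET = DNA_ALPHABET | {GAP}

#: default global-alignment scoring: match, mismatch, gap (linear)
DEFAULT_SCORES = (1, -1, -2)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(residues: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return residues.translate(_COMPLEMENT)[::-1]


class SequenceError(ValueError):
    """Raised for malformed sequence input (empty, bad alphabet, duplicates)."""


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over {A,C,G,T,N}, upper-cased on construction."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceError(f"sequence {self.identifier!r} is empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.identifier!r} contains illegal characters "
                f"{sorted(bad)}; allowed alphabet is A,C,G,T,N "
                "(IUPAC ambiguity codes are not supported)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequencePanel:
    """Per-locus tables mapping species label -> :class:`DnaSequence`."""

    loci: dict[str, dict[str, DnaSequence]] = field(default_factory=dict)

    def add_locus(self, name: str, table: Mapping[str, DnaSequence]) -> None:
        if len(table) < 2:
            raise SequenceError(f"locus {name!r} needs >=2 species, got {len(table)}")
        self.loci[name] = dict(table)

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for table in self.loci.values():
            for label in table:
                seen.setdefault(label)
        return list(seen)


@dataclass
class MultipleAlignment:
    """Species-labelled gapped rows of equal length.

    ``coord_maps[i][col]`` gives the 0-based ungapped coordinate of the
    residue of row ``i`` at alignment column ``col`` (absent for gap cells).
    """

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise SequenceError("label/row count mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise SequenceError(f"alignment rows have unequal lengths {sorted(widths)}")
        for label, row in zip(self.labels, self.rows):
            bad = set(row) - ALIGNED_ALPHABET
            if bad:
                raise SequenceError(f"row {label!r} has illegal characters {sorted(bad)}")
        self.coord_maps: list[dict[int, int]] = []
        for row in self.rows:
            cmap: dict[int, int] = {}
            pos = 0
            for col, ch in enumerate(row):
                if ch != GAP:
                    cmap[col] = pos
                    pos += 1
            self.coord_maps.append(cmap)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, col: int) -> dict[str, str]:
        """Symbols by species at one alignment column."""
        return {label: row[col] for label, row in zip(self.labels, self.rows)}

    def ungapped(self, label: str) -> str:
        return self.rows[self.labels.index(label)].replace(GAP, "")


# ---------------------------------------------------------------------------
# FASTA / GenBank I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a multi-FASTA file into DnaSequence records, order preserved.

    Rejects empty files, duplicate identifiers and illegal residue
    characters, naming the offending record. Gap characters are accepted
    only through :func:`read_alignment_fasta`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out: list[DnaSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(DnaSequence(rec.id, str(rec.seq)))
        except SequenceError as exc:
            raise SequenceError(f"{path}: {exc}") from exc
    return out


def write_fasta(sequences: Iterable[DnaSequence], path: str | Path, width: int = 70) -> None:
    """Write records as multi-FASTA wrapped at `width` columns."""
    records = [SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in sequences]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_alignment_fasta(path: str | Path) -> MultipleAlignment | None:
    """Detect and load a pre-aligned FASTA (equal-length rows containing '-').

    Returns None if the file is not a pre-built alignment, in which case the
    caller should align the records itself.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    rows = [str(r.seq).upper() for r in records]
    if len({len(r) for r in rows}) == 1 and any(GAP in r for r in rows):
        return MultipleAlignment([r.id for r in records], rows)
    return None


def read_genbank_sequence(path: str | Path) -> tuple[str, DnaSequence]:
    """Minimal GenBank flat-file reader: LOCUS/ACCESSION/ORIGIN only.

    Feature tables are ignored. A LOCUS length that disagrees with the
    ORIGIN block is logged as a warning but the sequence is still returned;
    a missing ORIGIN block is an error.
    """
    accession = ""
    locus_name = ""
    locus_length: int | None = None
    origin_chars: list[str] = []
    in_origin = False
    with open(path) as handle:
        for line in handle:
            if line.startswith("LOCUS"):
                parts = line.split()
                if len(parts) >= 2:
                    locus_name = parts[1]
                for tok, nxt in zip(parts, parts[1:] + [""]):
                    if nxt == "bp" and tok.isdigit():
                        locus_length = int(tok)
            elif line.startswith("ACCESSION"):
                parts = line.split()
                if len(parts) >= 2:
                    accession = parts[1]
            elif line.startswith("VERSION"):
                parts = line.split()
                if len(parts) >= 2 and "." in parts[1]:
                    accession = parts[1]
            elif line.startswith("ORIGIN"):
                in_origin = True
            elif line.startswith("//"):
                in_origin = False
            elif in_origin:
                origin_chars.extend(c for c in line if c.isalpha())
    if not in_origin and not origin_chars:
        raise SequenceError(f"{path}: no ORIGIN block found")
    residues = "".join(origin_chars).upper()
    if locus_length is not None and locus_length != len(residues):
        logger.warning(
            "%s: LOCUS length %d disagrees with ORIGIN length %d; using ORIGIN",
            path, locus_length, len(residues),
        )
    ident = accession or locus_name or str(path)
    return ident, DnaSequence(ident, residues)


def load_panel(
    paths: Mapping[str, str | Path],
    labels: Mapping[str, str] | None = None,
) -> SequencePanel:
    """Build a SequencePanel from {locus name: fasta path}.

    Species label = FASTA identifier up to first whitespace (SeqIO's ``id``),
    optionally remapped through `labels`.
    """
    panel = SequencePanel()
    for locus, path in paths.items():
        table: dict[str, DnaSequence] = {}
        for seq in read_fasta(path):
            label = labels.get(seq.identifier, seq.identifier) if labels else seq.identifier
            if label in table:
                raise SequenceError(f"{path}: duplicate species {label!r} in locus {locus!r}")
            table[label] = DnaSequence(label, seq.residues)
        panel.add_locus(locus, table)
    return panel


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sequence identifier -> species label."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ident, label = line.split("\t")[:2]
            mapping[ident] = label
    return mapping


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def pairwise_align(
    a: DnaSequence | str,
    b: DnaSequence | str,
    scores: tuple[int, int, int] = DEFAULT_SCORES,
) -> tuple[str, str, int]:
    """Global (Needleman-Wunsch) alignment with linear gap penalty.

    Returns (aligned_a, aligned_b, score). The traceback is deterministic
    with tie-break priority diagonal > up > left, so identical inputs always
    give identical gap placement. 'N' never matches anything (scored as a
    mismatch even against 'N').

    The fill is vectorized row-wise: within a row the left-gap recurrence
    row[j] = max_k<=j (cand[k] + (j-k)*gap) collapses to a running maximum
    of cand[k] - k*gap, which keeps kb-scale alignments fast.
    """
    sa = a.residues if isinstance(a, DnaSequence) else a.upper()
    sb = b.residues if isinstance(b, DnaSequence) else b.upper()
    if not sa or not sb:
        raise SequenceError("pairwise_align requires two non-empty sequences")
    match, mismatch, gap = scores
    n, m = len(sa), len(sb)
    arr_b = np.frombuffer(sb.encode(), dtype=np.uint8)
    n_code = ord("N")

    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = np.arange(m + 1, dtype=np.int32) * gap
    score[:, 0] = np.arange(n + 1, dtype=np.int32) * gap
    jgap = np.arange(1, m + 1, dtype=np.int32) * gap
    for i in range(1, n + 1):
        ca = ord(sa[i - 1])
        sub = np.where((arr_b == ca) & (ca != n_code), match, mismatch).astype(np.int32)
        prev = score[i - 1]
        cand = np.maximum(prev[:-1] + sub, prev[1:] + gap)  # diag, up at j=1..m
        # fold in the left-gap chain, including a start from score[i,0]
        shifted = np.empty(m + 1, dtype=np.int32)
        shifted[0] = score[i, 0]
        shifted[1:] = cand - jgap
        best = np.maximum.accumulate(shifted)
        score[i, 1:] = best[1:] + jgap

    # deterministic traceback from the score matrix, priority diag > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = score[i, j]
        if i > 0 and j > 0:
            sub = match if (sa[i - 1] == sb[j - 1] and sa[i - 1] != "N") else mismatch
            if here == score[i - 1, j - 1] + sub:
                out_a.append(sa[i - 1])
                out_b.append(sb[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and here == score[i - 1, j] + gap:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(sb[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[n, m])


def center_star_msa(
    table: Mapping[str, DnaSequence],
    scores: tuple[int, int, int] = DEFAULT_SCORES,
) -> MultipleAlignment:
    """Center-star multiple alignment of one locus table.

    The center is the sequence maximizing its summed pairwise score against
    all others (ties broken by species-label order in the table); every other
    sequence is merged against the center under "once a gap, always a gap".
    """
    labels = list(table)
    if len(labels) < 2:
        raise SequenceError("center_star_msa requires >=2 sequences")
    seqs = {lab: table[lab].residues for lab in labels}

    pair_scores: dict[tuple[str, str], int] = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            _, _, sc = pairwise_align(seqs[la], seqs[lb], scores)
            pair_scores[(la, lb)] = pair_scores[(lb, la)] = sc
    sums = {la: sum(pair_scores[(la, lb)] for lb in labels if lb != la) for la in labels}
    center = max(labels, key=lambda la: (sums[la], -labels.index(la)))

    center_row = seqs[center]
    others = [la for la in labels if la != center]
    merged: dict[str, str] = {}
    for la in others:
        aln_c, aln_o, _ = pairwise_align(center_row.replace(GAP, ""), seqs[la], scores)
        # map new center gaps back into the running master row and all merged rows
        new_center: list[str] = []
        new_other: list[str] = []
        k = 0  # position in aln_c / aln_o
        for ch in center_row:
            if ch == GAP:
                new_center.append(GAP)
                new_other.append(GAP)
                continue
            # consume any gap columns newly introduced in the center
            while k < len(aln_c) and aln_c[k] == GAP:
                new_center.append(GAP)
                new_other.append(aln_o[k])
                for lb in merged:
                    merged[lb] = merged[lb][: len(new_center) - 1] + GAP + merged[lb][len(new_center) - 1:]
                k += 1
            new_center.append(aln_c[k])
            new_other.append(aln_o[k])
            k += 1
        while k < len(aln_c):  # trailing insertions in the incoming sequence
            if aln_c[k] == GAP:
                new_center.append(GAP)
                new_other.append(aln_o[k])
                for lb in merged:
                    merged[lb] = merged[lb] + GAP
            k += 1
        center_row = "".join(new_center)
        merged[la] = "".join(new_other)
        # pad previously merged rows that predate this round's width
        for lb in merged:
            if len(merged[lb]) < len(center_row):
                merged[lb] = merged[lb] + GAP * (len(center_row) - len(merged[lb]))

    rows = [center_row if la == center else merged[la] for la in labels]
    msa = MultipleAlignment(labels, rows)
    for la, row in zip(msa.labels, msa.rows):
        assert row.replace(GAP, "") == seqs[la], f"de-gapping row {la!r} does not restore input"
    return msa


def align_panel_locus(
    table: Mapping[str, DnaSequence],
    scores: tuple[int, int, int] = DEFAULT_SCORES,
) -> MultipleAlignment:
    """Alignment entry point for one locus table (center-star)."""
    return center_star_msa(table, scores)
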