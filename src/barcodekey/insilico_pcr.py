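"""Mismatch-tolerant electronic PCR with a 3'-anchored binding model.

Primer binding is scored per window with weights that emphasize the 3'
pentamer, where polymerase extension is decided: a mismatch at the 3'
terminus blocks the site outright (the ARMS specificity mechanism), a
mismatch at offsets 1-4 from the terminus costs 2, and anything further
5'-ward costs 1. A window is a predicted binding site when its total score
does not exceed ``max_score`` (default 3 — loose enough to tolerate the
designed third-base mismatch plus one distal mismatch, tight enough that a
second 3'-proximal mismatch kills the site).

Binding is ungapped: primer-template indel bubbles are out of model; the
diagnostic indels of the pipeline are instead handled upstream by
junction-spanning primers. Product lengths count both primer footprints
inclusively, the standard amplicon convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arms_primers import Primer, PrimerPair
from .discrimination_key import AmplificationMatrix, Cell
from .seq_panel import DnaSequence, SequenceError, revcomp

#: sentinel score for a 3'-terminal mismatch: the site is never reported
BLOCKED = float("inf")

DEFAULT_MAX_SCORE = 3
DEFAULT_SIZE_RANGE = (50, 5000)


@dataclass(frozen=True)
class BindingSite:
    """One scored, non-blocked primer-template window."""

    template_id: str
    interval: tuple[int, int]  # plus-strand, 0-based half-open
    strand: str  # strand the primer binds: '+' extends rightward, '-' leftward
    mismatch_offsets: tuple[int, ...]  # offsets from the primer 3' end
    score: int


@dataclass(frozen=True)
class Amplicon:
    """Predicted product between a convergent site pair."""

    template_id: str
    interval: tuple[int, int]  # forward-site start to reverse-site end
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def _offset_weight(offset: int) -> float:
    if offset == 0:
        return BLOCKED
    return 2 if offset <= 4 else 1


def mismatch_score(primer: str, window: str, orientation: str) -> float:
    """Score one primer/template window in the given binding orientation.

    `window` is the plus-strand template slice of primer length. Returns the
    summed 3'-offset weights of the mismatched positions, or ``BLOCKED`` for
    a 3'-terminal mismatch. A template 'N' counts as a mismatch.
    """
    if len(primer) != len(window):
        raise SequenceError("mismatch_score: window length must equal primer length")
    primer = primer.upper()
    window = window.upper()
    probe = primer if orientation == "+" else revcomp(primer)
    score = 0.0
    n = len(primer)
    for i, (p, t) in enumerate(zip(probe, window)):
        if p == t and t != "N":
            continue
        offset = (n - 1 - i) if orientation == "+" else i
        w = _offset_weight(offset)
        if w == BLOCKED:
            return BLOCKED
        score += w
    return score


def binding_sites(
    primer: Primer | str,
    template: DnaSequence | str,
    max_score: float = DEFAULT_MAX_SCORE,
    template_id: str = "",
) -> list[BindingSite]:
    """All non-blocked windows on both strands with score <= max_score.

    Sites are returned in ascending position order, plus strand before minus
    at equal start. The scan is an exhaustive sliding-window comparison,
    vectorized over windows.
    """
    if isinstance(template, DnaSequence):
        template_id = template_id or template.identifier
        template = template.residues
    pseq = primer.residues if isinstance(primer, Primer) else primer.upper()
    template = template.upper()
    n, L = len(template), len(pseq)
    if n < L:
        raise SequenceError("template shorter than primer")

    tmpl = np.frombuffer(template.encode(), dtype=np.uint8)
    n_byte = ord("N")
    windows = sliding_window_view(tmpl, L)  # (n-L+1, L)
    out: list[BindingSite] = []
    for strand in "+-":
        probe = pseq if strand == "+" else revcomp(pseq)
        parr = np.frombuffer(probe.encode(), dtype=np.uint8)
        mism = (windows != parr) | (windows == n_byte)
        offsets = (np.arange(L)[::-1] if strand == "+" else np.arange(L))
        weights = np.where(offsets == 0, 0.0, np.where(offsets <= 4, 2.0, 1.0))
        blocked = mism[:, int(np.argmin(offsets))]
        scores = mism @ weights
        hits = np.flatnonzero(~blocked & (scores <= max_score))
        for start in hits:
            offs = tuple(sorted(int(offsets[j]) for j in np.flatnonzero(mism[start])))
            out.append(
                BindingSite(
                    template_id=template_id,
                    interval=(int(start), int(start) + L),
                    strand=strand,
                    mismatch_offsets=offs,
                    score=int(scores[start]),
                )
            )
    out.sort(key=lambda s: (s.interval[0], s.strand))
    return out


def predict_amplicons(
    pair: PrimerPair,
    template: DnaSequence | str,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    max_score: float = DEFAULT_MAX_SCORE,
    template_id: str = "",
) -> list[Amplicon]:
    """Predict products of a primer pair on one template.

    Pairs every plus-strand forward site with every downstream minus-strand
    reverse site whose span falls inside `size_range`; the swapped assignment
    (forward primer binding the minus strand) is evaluated too, so a primer
    table with exchanged orientations still amplifies. Results sorted by
    start, then end.
    """
    if isinstance(template, DnaSequence):
        template_id = template_id or template.identifier
    f_sites = binding_sites(pair.forward, template, max_score, template_id)
    r_sites = binding_sites(pair.reverse, template, max_score, template_id)
    lo, hi = size_range
    out: list[Amplicon] = []
    for left_name, right_name in (("f", "r"), ("r", "f")):
        lefts = [s for s in (f_sites if left_name == "f" else r_sites) if s.strand == "+"]
        rights = [s for s in (r_sites if right_name == "r" else f_sites) if s.strand == "-"]
        for ls in lefts:
            for rs in rights:
                if ls.interval[1] > rs.interval[0]:
                    continue
                width = rs.interval[1] - ls.interval[0]
                if lo <= width <= hi:
                    out.append(
                        Amplicon(
                            template_id=template_id,
                            interval=(ls.interval[0], rs.interval[1]),
                            forward_site=ls,
                            reverse_site=rs,
                        )
                    )
    # the swapped pass can rediscover the same physical product when both
    # primers bind both strands; deduplicate on coordinates
    seen: set[tuple[int, int]] = set()
    unique = []
    for amp in sorted(out, key=lambda a: a.interval):
        if amp.interval not in seen:
            seen.add(amp.interval)
            unique.append(amp)
    return unique


def amplification_matrix(
    pairs: Sequence[PrimerPair],
    templates: Mapping[str, Mapping[str, DnaSequence | str] | DnaSequence | str],
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    max_score: float = DEFAULT_MAX_SCORE,
) -> AmplificationMatrix:
    """Species x primer-pair predicted-amplicon table.

    `templates` maps species either to a single template or to a per-locus
    table; a species lacking a template for a pair's locus is recorded as
    "untested", distinct from a negative prediction.
    """
    species = list(templates)
    pair_names = [p.name for p in pairs]
    cells: dict[tuple[str, str], Cell] = {}
    for sp in species:
        entry = templates[sp]
        for pair in pairs:
            if isinstance(entry, (DnaSequence, str)):
                template = entry
            else:
                template = entry.get(pair.locus)
            if template is None:
                cells[(sp, pair.name)] = Cell.untested()
                continue
            amps = predict_amplicons(pair, template, size_range, max_score,
                                     template_id=sp)
            cells[(sp, pair.name)] = Cell.from_lengths([a.length for a in amps])
    return AmplificationMatrix(species, pair_names, cells)
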