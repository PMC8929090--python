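"""Allele-specific (ARMS) primer design anchored on species-diagnostic sites.

The design rule: the discriminating allele sits at the primer's 3' terminus,
and the base third from the 3' end (offset 2, counting the terminus as
offset 0) is deliberately replaced so that it mismatches the template of
every species in the panel. On the target template the primer then carries a
single tolerated internal mismatch; on every other template it additionally
mismatches at the 3' terminus, which refractory polymerase extension — and
the in-silico PCR model — treats as blocking.

Melting temperatures use the GC-count formula Tm = 64.9 + 41*(GC - 16.4)/N,
adequate for ranking primers of ordinary length; empirical annealing
temperatures from wet-lab tables are carried as metadata, never recomputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .diagnostic_sites import (
    DiagnosticSite,
    SiteClass,
    find_diagnostic_sites,
    indel_blocks,
)
from .seq_panel import GAP, MultipleAlignment, SequenceError, revcomp

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = "ACGT"  # fixed tie-break order


@dataclass(frozen=True)
class Primer:
    """One oriented primer with designed-mismatch bookkeeping.

    ``interval`` is the footprint on the *ungapped target sequence* of its
    locus, 0-based half-open, always given in plus-strand coordinates.
    ``designed_mismatch_offset`` counts from the 3' end (terminus = 0).
    """

    name: str
    residues: str
    strand: str  # '+' or '-'
    interval: tuple[int, int]
    designed_mismatch_offset: int | None = None
    site: DiagnosticSite | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceError(f"primer {self.name!r}: strand must be '+' or '-'")
        if self.designed_mismatch_offset is not None and self.designed_mismatch_offset != 2:
            raise SequenceError(
                f"primer {self.name!r}: a designed mismatch must sit at 3' offset 2 "
                "(third base from the 3' end)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PrimerPair:
    """Forward (plus-strand) and reverse (minus-strand) primer with product size.

    ``annealing_tm`` is empirical metadata (e.g. from a published primer
    table), never a computed melting temperature. ``penalty`` is the design
    score, lower is better; fixture pairs carry penalty 0 and
    ``designed=False``, exempting them from design-time constraints.
    """

    name: str
    forward: Primer
    reverse: Primer
    product_length: int
    target_species: str
    locus: str = ""
    annealing_tm: float | None = None
    penalty: float = 0.0
    designed: bool = True

    def __post_init__(self) -> None:
        if self.designed:
            if not (100 <= self.product_length <= 1000):
                raise SequenceError(
                    f"pair {self.name!r}: designed product length {self.product_length} "
                    "outside [100, 1000] bp"
                )
            f0, f1 = self.forward.interval
            r0, r1 = self.reverse.interval
            if not (f1 <= r0):
                raise SequenceError(
                    f"pair {self.name!r}: forward footprint must lie upstream of reverse"
                )


@dataclass(frozen=True)
class DesignConstraints:
    """Design-time acceptance windows; all ranges are inclusive."""

    primer_length: tuple[int, int] = (18, 25)
    product_length: tuple[int, int] = (100, 1000)
    tm_range: tuple[float, float] = (50.0, 62.0)
    max_pair_tm_diff: float = 5.0
    gc_range: tuple[float, float] = (0.30, 0.70)
    max_homopolymer: int = 4
    max_end_complement: int = 4
    #: pairs kept per (site, orientation) after ranking; None keeps all
    max_pairs_per_site: int | None = 10

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (*self.primer_length, "primer length"),
            (*self.product_length, "product length"),
            (*self.tm_range, "Tm"),
            (*self.gc_range, "GC"),
        ):
            if not lo < hi:
                raise SequenceError(f"degenerate {what} range ({lo}, {hi})")


def gc_fraction(residues: str) -> float:
    return (residues.count("G") + residues.count("C")) / len(residues)


def tm_estimate(residues: str) -> float:
    """GC-count melting temperature: 64.9 + 41*(GC - 16.4)/N. Needs N >= 14."""
    residues = residues.upper()
    if len(residues) < 14:
        raise SequenceError(f"tm_estimate needs >=14 nt, got {len(residues)}")
    if set(residues) - set(BASES):
        raise SequenceError("tm_estimate requires an unambiguous A/C/G/T sequence")
    n = len(residues)
    gc = residues.count("G") + residues.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / n


def max_homopolymer_run(residues: str) -> int:
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", residues))


def max_3prime_complement_run(primer: str, partner: str) -> int:
    """Longest 3'-terminal suffix of `primer` reverse-complementary to a
    substring of `partner` (antiparallel annealing model)."""
    best = 0
    for run in range(1, len(primer) + 1):
        suffix = primer[-run:]
        if revcomp(suffix) in partner:
            best = run
        else:
            break
    return best


# ---------------------------------------------------------------------------
# ARMS third-base modification
# ---------------------------------------------------------------------------

def _apposition_strength(primer_base: str, template_base_primer_sense: str) -> int:
    """1 for a purine-purine or pyrimidine-pyrimidine apposition, else 0.

    ``template_base_primer_sense`` is the base the primer would need to EQUAL
    to match that template; the physical base it sits across in the duplex is
    its complement.
    """
    across = _COMPLEMENT[template_base_primer_sense]
    same_purine = primer_base in PURINES and across in PURINES
    same_pyrimidine = primer_base not in PURINES and across not in PURINES
    return 1 if (same_purine or same_pyrimidine) else 0


class ArmsDesignError(ValueError):
    """No legal third-base replacement exists for a site."""


def arms_modify(
    core: str,
    template_bases: dict[str, str],
    orientation: str = "+",
) -> tuple[str, int]:
    """Introduce the deliberate third-base mismatch into a primer core.

    `core` is the template-matching primer window (5'->3', ending at the
    diagnostic column). `template_bases` maps each panel species to the base
    the primer would need to equal to match that species' template at the
    offset-2 column, already read in the primer's sense (species gapped at
    that column are omitted by the caller). Returns (modified core, designed
    offset). The replacement mismatches EVERY listed template; among legal
    bases the one maximizing purine-purine / pyrimidine-pyrimidine
    appositions across the panel wins, ties broken by A<C<G<T. A core whose
    offset-2 base already mismatches all templates is returned unchanged.
    """
    if len(core) < 3:
        raise ArmsDesignError("primer core shorter than 3 nt")
    offset = 2
    current = core[-1 - offset]
    excluded = set(template_bases.values())
    if current not in excluded:
        return core, offset  # fixed point: already mismatches every template
    legal = [b for b in BASES if b not in excluded]
    if not legal:
        raise ArmsDesignError(
            "no replacement base can mismatch every template at the third position"
        )
    best = max(
        legal,
        key=lambda b: (
            sum(_apposition_strength(b, t) for t in template_bases.values()),
            -BASES.index(b),
        ),
    )
    modified = core[: -1 - offset] + best + core[-offset:]
    return modified, offset


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------

def primer_quality_filters(
    obj: Primer | PrimerPair | str,
    constraints: DesignConstraints = DesignConstraints(),
) -> tuple[bool, list[str]]:
    """Check a primer (or a pair) against the design constraints.

    Returns (verdict, reason codes); the verdict is False iff at least one
    constraint is violated, and the reasons enumerate every violation.
    """
    reasons: list[str] = []
    if isinstance(obj, PrimerPair):
        for label, primer in (("forward", obj.forward), ("reverse", obj.reverse)):
            ok, sub = primer_quality_filters(primer, constraints)
            reasons.extend(f"{label}:{r}" for r in sub)
        tm_f = tm_estimate(obj.forward.residues)
        tm_r = tm_estimate(obj.reverse.residues)
        if abs(tm_f - tm_r) > constraints.max_pair_tm_diff:
            reasons.append("pair_tm_difference")
        cross = max(
            max_3prime_complement_run(obj.forward.residues, obj.reverse.residues),
            max_3prime_complement_run(obj.reverse.residues, obj.forward.residues),
        )
        if cross > constraints.max_end_complement:
            reasons.append("cross_3prime_complementarity")
        return (not reasons, reasons)

    residues = obj.residues if isinstance(obj, Primer) else obj.upper()
    lo, hi = constraints.primer_length
    if not (lo <= len(residues) <= hi):
        reasons.append("length")
    try:
        tm = tm_estimate(residues)
        if not (constraints.tm_range[0] <= tm <= constraints.tm_range[1]):
            reasons.append("tm_range")
    except SequenceError:
        reasons.append("tm_uncomputable")
    gc = gc_fraction(residues)
    if not (constraints.gc_range[0] <= gc <= constraints.gc_range[1]):
        reasons.append("gc_range")
    if max_homopolymer_run(residues) > constraints.max_homopolymer:
        reasons.append("homopolymer")
    if max_3prime_complement_run(residues, residues) > constraints.max_end_complement:
        reasons.append("self_3prime_complementarity")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# Pair design
# ---------------------------------------------------------------------------

def pair_penalty(forward: str, reverse: str) -> float:
    """Deterministic design score, lower better.

    |Tm_f - Tm_r| plus, per primer, 0.5 deg-equivalents per nt away from the
    20-nt optimum and 10 per unit of GC-fraction away from 0.50.
    """
    tm_f, tm_r = tm_estimate(forward), tm_estimate(reverse)
    pen = abs(tm_f - tm_r)
    for residues in (forward, reverse):
        pen += 0.5 * abs(len(residues) - 20)
        pen += 10.0 * abs(gc_fraction(residues) - 0.5)
    return pen


def _anchor_positions(
    msa: MultipleAlignment, target: str, sites: list[DiagnosticSite]
) -> list[tuple[DiagnosticSite, int, str]]:
    """Resolve each usable site to (site, 3'-anchor in target coords, kind).

    SNPs anchor on their own target base. Insertion blocks anchor on the
    block's 3'-most inserted base (forward sense). Deletion blocks anchor on
    the first target base after the junction so the primer spans it.
    """
    t_idx = msa.labels.index(target)
    cmap = msa.coord_maps[t_idx]
    anchors: list[tuple[DiagnosticSite, int, str]] = []
    snps = [s for s in sites if s.site_class is SiteClass.SNP]
    for s in snps:
        anchors.append((s, s.target_position, "snp"))
    for block in indel_blocks(sites):
        last_col = block.start_column + block.length - 1
        if block.site_class is SiteClass.INSERTION:
            pos = cmap.get(last_col)
            if pos is None:
                continue
            site = next(s for s in sites if s.column == last_col)
            anchors.append((site, pos, "insertion"))
        else:  # deletion: first target base 3' of the block
            row = msa.rows[t_idx]
            nxt = next((c for c in range(last_col + 1, msa.n_columns) if row[c] != GAP), None)
            if nxt is None:
                continue
            site = next(s for s in sites if s.column == block.start_column)
            anchors.append((site, cmap[nxt], "deletion"))
    return anchors


def _template_bases_at(
    msa: MultipleAlignment, target: str, target_pos: int, orientation: str
) -> dict[str, str]:
    """Panel template bases at one target coordinate, read in primer sense."""
    t_idx = msa.labels.index(target)
    col = next(c for c, p in msa.coord_maps[t_idx].items() if p == target_pos)
    out: dict[str, str] = {}
    for sp, sym in msa.column(col).items():
        if sym in _COMPLEMENT:
            out[sp] = sym if orientation == "+" else _COMPLEMENT[sym]
    return out


def _mate_candidates(template: str, orientation: str, constraints: DesignConstraints):
    """All quality-passing mate windows on `template`, one-off per design call.

    For orientation '-' the mate binds the minus strand (a reverse primer,
    residues = revcomp of the plus-strand window); for '+' it is a plus-strand
    forward primer. Yields (start, end, residues, tm)."""
    lo, hi = constraints.primer_length
    out = []
    for length in range(lo, hi + 1):
        for start in range(0, len(template) - length + 1):
            window = template[start : start + length]
            residues = revcomp(window) if orientation == "-" else window
            ok, _ = primer_quality_filters(residues, constraints)
            if ok:
                out.append((start, start + length, residues, tm_estimate(residues)))
    return out


def design_allele_specific_pairs(
    msa: MultipleAlignment,
    target: str,
    constraints: DesignConstraints = DesignConstraints(),
    locus: str = "",
) -> list[PrimerPair]:
    """Design ranked allele-specific primer pairs for one target species.

    For every diagnostic site and both orientations, the allele-specific
    primer is built at every legal length with its 3' end on the site and the
    third-base mismatch applied; the opposite strand is scanned for mate
    windows giving a product inside the configured range. Pairs failing
    :func:`primer_quality_filters` are dropped (the allele-specific primer's
    engineered third base is exempt from no filter — it competes like any
    other base). Result is sorted by (penalty, locus, column, product length)
    and truncated to ``constraints.max_pairs_per_site`` per site/orientation.
    """
    sites = find_diagnostic_sites(msa, target, locus)
    if not sites:
        logger.info("no diagnostic site for %s at locus %s; nothing to design", target, locus)
        return []
    template = msa.ungapped(target)
    lo, hi = constraints.primer_length
    plo, phi = constraints.product_length
    mates_minus = _mate_candidates(template, "-", constraints)
    mates_plus = _mate_candidates(template, "+", constraints)

    all_pairs: list[PrimerPair] = []
    for site, anchor, kind in _anchor_positions(msa, target, sites):
        for orientation in "+-":
            candidates: list[PrimerPair] = []
            for length in range(lo, hi + 1):
                if orientation == "+":
                    start, end = anchor - length + 1, anchor + 1
                    if start < 0:
                        continue
                    core = template[start:end]
                else:
                    start, end = anchor, anchor + length
                    if end > len(template):
                        continue
                    core = revcomp(template[start:end])
                off2_pos = anchor - 2 if orientation == "+" else anchor + 2
                if not (0 <= off2_pos < len(template)):
                    continue
                try:
                    tb = _template_bases_at(msa, target, off2_pos, orientation)
                    modified, offset = arms_modify(core, tb, orientation)
                except (ArmsDesignError, StopIteration) as exc:
                    logger.info("site %s/%s col %d skipped: %s", locus, target, site.column, exc)
                    continue
                as_primer = Primer(
                    name=f"{locus}_{target}_c{site.column}{orientation}L{length}",
                    residues=modified,
                    strand=orientation,
                    interval=(start, end),
                    designed_mismatch_offset=offset,
                    site=site,
                )
                ok, _reasons = primer_quality_filters(as_primer, constraints)
                if not ok:
                    continue
                mates = mates_minus if orientation == "+" else mates_plus
                for m_start, m_end, m_res, _m_tm in mates:
                    if orientation == "+":
                        if m_start < end:
                            continue
                        product = m_end - start
                        fwd, rev = as_primer, Primer(
                            name=f"{as_primer.name}_mate", residues=m_res,
                            strand="-", interval=(m_start, m_end))
                    else:
                        if m_end > start:
                            continue
                        product = end - m_start
                        fwd, rev = Primer(
                            name=f"{as_primer.name}_mate", residues=m_res,
                            strand="+", interval=(m_start, m_end)), as_primer
                    if not (plo <= product <= phi):
                        continue
                    pair = PrimerPair(
                        name=f"{as_primer.name}_m{m_start}.{m_end - m_start}",
                        forward=fwd,
                        reverse=rev,
                        product_length=product,
                        target_species=target,
                        locus=locus,
                        penalty=pair_penalty(fwd.residues, rev.residues),
                    )
                    ok, _reasons = primer_quality_filters(pair, constraints)
                    if ok:
                        candidates.append(pair)
            candidates.sort(
                key=lambda p: (p.penalty, p.locus, p.forward.site.column if p.forward.site
                               else p.reverse.site.column, p.product_length)
            )
            if constraints.max_pairs_per_site is not None:
                candidates = candidates[: constraints.max_pairs_per_site]
            all_pairs.extend(candidates)

    all_pairs.sort(
        key=lambda p: (
            p.penalty,
            p.locus,
            (p.forward.site or p.reverse.site).column,
            p.product_length,
        )
    )
    return all_pairs
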