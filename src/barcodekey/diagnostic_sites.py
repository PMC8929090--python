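"""Detection of species-diagnostic alignment columns.

A column is *diagnostic* for a target species when the target's symbol at
that column is carried by no other species in the panel — a species-unique
SNP, insertion or deletion. Uniqueness is defined strictly against the
species present in the panel; nothing is claimed about unsampled taxa.

Columns containing 'N' in any species are skipped: an ambiguous base can
never certify uniqueness. Columns where the target has a base but the
remaining species mix bases and gaps are likewise skipped as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .seq_panel import GAP, MultipleAlignment


class SiteClass(str, Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class DiagnosticSite:
    """One alignment column whose allele is unique to the target species."""

    locus: str
    column: int  # 0-based alignment column
    site_class: SiteClass
    target: str
    target_allele: str  # one of A,C,G,T,-
    other_alleles: Mapping[str, str]  # species -> symbol at the column
    target_position: int | None  # ungapped coord in the target; None for deletions


@dataclass(frozen=True)
class IndelBlock:
    """Maximal run of consecutive same-class indel columns for one species."""

    locus: str
    start_column: int
    length: int
    site_class: SiteClass
    target: str


def classify_column(symbols: Mapping[str, str], target: str) -> SiteClass | None:
    """Classify one alignment column for the target species, or None.

    Rules: any 'N' in the column disqualifies it; the target symbol must be
    absent from every other species; the class follows the gap pattern —
    all-others-gapped with a target base is an insertion, a gapped target
    with all others based is a deletion, a gap-free column is a SNP, and any
    other gap mixture is ambiguous (None).
    """
    if target not in symbols:
        raise KeyError(f"unknown target species {target!r}")
    tsym = symbols[target]
    others = {sp: sym for sp, sym in symbols.items() if sp != target}
    column = [tsym, *others.values()]
    if "N" in column:
        return None
    if tsym in others.values():
        return None
    other_gaps = [sym == GAP for sym in others.values()]
    if tsym == GAP:
        # target deleted; diagnostic only if every other species has a base
        return SiteClass.DELETION if not any(other_gaps) else None
    if all(other_gaps):
        return SiteClass.INSERTION
    if any(other_gaps):
        return None  # mixed gap/base among non-targets: ambiguous
    return SiteClass.SNP


def find_diagnostic_sites(
    msa: MultipleAlignment, target: str, locus: str = ""
) -> list[DiagnosticSite]:
    """Scan every alignment column, reporting diagnostic sites in column order."""
    if target not in msa.labels:
        raise KeyError(f"unknown target species {target!r}")
    t_idx = msa.labels.index(target)
    sites: list[DiagnosticSite] = []
    for col in range(msa.n_columns):
        symbols = msa.column(col)
        cls = classify_column(symbols, target)
        if cls is None:
            continue
        tpos = msa.coord_maps[t_idx].get(col)
        sites.append(
            DiagnosticSite(
                locus=locus,
                column=col,
                site_class=cls,
                target=target,
                target_allele=symbols[target],
                other_alleles={sp: s for sp, s in symbols.items() if sp != target},
                target_position=tpos,
            )
        )
    return sites


def indel_blocks(sites: list[DiagnosticSite]) -> list[IndelBlock]:
    """Merge runs of consecutive same-class indel columns into blocks.

    Per-column indel sites remain in the site list; blocks are the reporting
    (and primer-anchoring) view: primer design places the allele-specific
    3' end at the 3'-most column of each block.
    """
    blocks: list[IndelBlock] = []
    run: list[DiagnosticSite] = []
    for site in sites:
        if site.site_class is SiteClass.SNP:
            continue
        if run and (
            site.column == run[-1].column + 1
            and site.site_class is run[-1].site_class
            and site.target == run[-1].target
            and site.locus == run[-1].locus
        ):
            run.append(site)
        else:
            if run:
                blocks.append(_close(run))
            run = [site]
    if run:
        blocks.append(_close(run))
    return blocks


def _close(run: list[DiagnosticSite]) -> IndelBlock:
    return IndelBlock(
        locus=run[0].locus,
        start_column=run[0].column,
        length=len(run),
        site_class=run[0].site_class,
        target=run[0].target,
    )


def sites_to_rows(sites: list[DiagnosticSite]) -> list[dict]:
    """Flatten sites for TSV output (locus, column, class, alleles, position)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "locus": s.locus,
                "column": s.column,
                "class": s.site_class.value,
                "target": s.target,
                "target_allele": s.target_allele,
                "other_alleles": ";".join(f"{sp}={a}" for sp, a in sorted(s.other_alleles.items())),
                "target_position": "" if s.target_position is None else s.target_position,
            }
        )
    return rows
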