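"""Minimal primer sets that uniquely identify every species in a panel.

The amplification matrix records, per species and primer pair, the predicted
product lengths (or a negative, or "untested"). Keying works on the boolean
presence/absence view — the information a band on a gel carries — and seeks
the smallest subset of pairs under which every species' signature is
distinct. Two species lacking any distinguishing pair are reported as an
indistinguishable group instead of emitting a key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence


class KeyError_(ValueError):
    """Raised when a matrix cannot support the requested keying operation."""


@dataclass(frozen=True)
class Cell:
    """One matrix cell: positive (with product lengths), negative or untested."""

    lengths: tuple[int, ...] = ()
    tested: bool = True

    @classmethod
    def positive(cls, lengths: Iterable[int]) -> "Cell":
        return cls(tuple(lengths), True)

    @classmethod
    def negative(cls) -> "Cell":
        return cls((), True)

    @classmethod
    def untested(cls) -> "Cell":
        return cls((), False)

    @classmethod
    def from_lengths(cls, lengths: Iterable[int]) -> "Cell":
        return cls(tuple(lengths), True)

    @property
    def is_positive(self) -> bool:
        return self.tested and bool(self.lengths)

    def render(self) -> str:
        if not self.tested:
            return "NT"
        return ",".join(str(n) for n in self.lengths) if self.lengths else "-"

    @classmethod
    def parse(cls, text: str) -> "Cell":
        text = text.strip()
        if text == "NT":
            return cls.untested()
        if text in ("-", "", "0"):
            return cls.negative()
        if text == "+":
            return cls.positive((1,))  # presence-only input
        return cls.positive(int(t) for t in text.split(","))


@dataclass
class AmplificationMatrix:
    """Rectangular species x primer-pair table of :class:`Cell` values."""

    species: list[str]
    pairs: list[str]
    cells: dict[tuple[str, str], Cell]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise KeyError_("duplicate species labels")
        if len(set(self.pairs)) != len(self.pairs):
            raise KeyError_("duplicate pair names")
        for sp in self.species:
            for pr in self.pairs:
                self.cells.setdefault((sp, pr), Cell.negative())

    def cell(self, species: str, pair: str) -> Cell:
        return self.cells[(species, pair)]

    def signature(self, species: str, subset: Sequence[str]) -> tuple[bool, ...]:
        return tuple(self.cell(species, pr).is_positive for pr in subset)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.pairs) + "\n")
            for sp in self.species:
                fh.write(sp + "\t" + "\t".join(self.cell(sp, pr).render() for pr in self.pairs) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "AmplificationMatrix":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        pairs = header[1:]
        species: list[str] = []
        cells: dict[tuple[str, str], Cell] = {}
        for ln in lines[1:]:
            fields = ln.split("\t")
            sp = fields[0]
            species.append(sp)
            for pr, text in zip(pairs, fields[1:]):
                cells[(sp, pr)] = Cell.parse(text)
        return cls(species, pairs, cells)


@dataclass(frozen=True)
class DiscriminationKey:
    """A selected pair subset plus each species' expected +/- signature."""

    pairs: tuple[str, ...]
    signatures: Mapping[str, tuple[bool, ...]]

    def lookup(self, signature: Sequence[bool]) -> str | None:
        sig = tuple(bool(b) for b in signature)
        for sp, s in self.signatures.items():
            if s == sig:
                return sp
        return None


def distinguishes(matrix: AmplificationMatrix, subset: Sequence[str]) -> bool:
    """True iff species signatures restricted to `subset` are pairwise distinct.

    Untested cells poison the evaluation: the cross-validation logic assumes
    every selected pair was run on every sample.
    """
    for pr in subset:
        if pr not in matrix.pairs:
            raise KeyError_(f"unknown pair {pr!r}")
        for sp in matrix.species:
            if not matrix.cell(sp, pr).tested:
                raise KeyError_(f"cell ({sp!r}, {pr!r}) is untested; cannot evaluate subset")
    sigs = [matrix.signature(sp, subset) for sp in matrix.species]
    return len(set(sigs)) == len(sigs)


def _indistinct_groups(matrix: AmplificationMatrix) -> list[list[str]]:
    groups: dict[tuple, list[str]] = {}
    for sp in matrix.species:
        groups.setdefault(matrix.signature(sp, matrix.pairs), []).append(sp)
    return [g for g in groups.values() if len(g) > 1]


EXACT_SEARCH_LIMIT = 20


def minimal_key(matrix: AmplificationMatrix) -> DiscriminationKey:
    """Smallest pair subset distinguishing every species.

    Exact subset search (by increasing cardinality, lexicographic pair-name
    order within a cardinality) up to 20 pairs; a greedy set cover of
    unresolved species-pairs beyond that. Raises with the offending group
    when the full matrix cannot separate some species.
    """
    groups = _indistinct_groups(matrix)
    if groups:
        listing = "; ".join("{" + ", ".join(g) + "}" for g in groups)
        raise KeyError_(f"species indistinguishable by the full matrix: {listing}")

    names = sorted(matrix.pairs)
    chosen: Sequence[str] | None = None
    if len(names) <= EXACT_SEARCH_LIMIT:
        for size in range(1, len(names) + 1):
            for subset in combinations(names, size):
                if distinguishes(matrix, subset):
                    chosen = subset
                    break
            if chosen:
                break
    else:
        remaining = {
            (a, b)
            for i, a in enumerate(matrix.species)
            for b in matrix.species[i + 1:]
        }
        picked: list[str] = []
        while remaining:
            def resolved_by(pr: str) -> set[tuple[str, str]]:
                return {
                    (a, b)
                    for (a, b) in remaining
                    if matrix.cell(a, pr).is_positive != matrix.cell(b, pr).is_positive
                }
            best, best_gain = "", -1
            for pr in sorted(names):
                g = len(resolved_by(pr))
                if g > best_gain:
                    best, best_gain = pr, g
            gain = resolved_by(best)
            if not gain:
                raise KeyError_("greedy cover stalled; matrix should have been separable")
            picked.append(best)
            remaining -= gain
            names.remove(best)
        chosen = sorted(picked)

    assert chosen is not None
    ordered = [pr for pr in matrix.pairs if pr in set(chosen)]
    sigs = {sp: matrix.signature(sp, ordered) for sp in matrix.species}
    return DiscriminationKey(tuple(ordered), sigs)


def render_key(key: DiscriminationKey, matrix: AmplificationMatrix) -> str:
    """Human-readable decision table plus a signature lookup section.

    Cells show +/-; positive cells append the expected product lengths in
    brackets, which aid gel reading but are not required for distinctness.
    """
    widths = [max(len(pr), 8) for pr in key.pairs]
    name_w = max(len(sp) for sp in matrix.species) + 2
    lines = ["species".ljust(name_w) + "  ".join(pr.ljust(w) for pr, w in zip(key.pairs, widths))]
    for sp in matrix.species:
        cells = []
        for pr, w in zip(key.pairs, widths):
            cell = matrix.cell(sp, pr)
            mark = "+" if cell.is_positive else "-"
            if cell.is_positive and cell.lengths:
                mark += "[" + ",".join(str(n) for n in cell.lengths) + "]"
            cells.append(mark.ljust(w))
        lines.append(sp.ljust(name_w) + "  ".join(cells))
    lines.append("")
    lines.append("signature lookup (order: " + ", ".join(key.pairs) + ")")
    for sp, sig in key.signatures.items():
        pattern = "".join("+" if b else "-" for b in sig)
        lines.append(f"  {pattern} -> {sp}")
    return "\n".join(lines) + "\n"


def parse_key(text: str) -> DiscriminationKey:
    """Invert :func:`render_key`'s lookup section back into a key."""
    lines = text.splitlines()
    try:
        idx = next(i for i, ln in enumerate(lines) if ln.startswith("signature lookup"))
    except StopIteration:
        raise KeyError_("no signature lookup section found")
    header = lines[idx]
    pairs = tuple(p.strip() for p in header[header.index(":") + 1 : header.rindex(")")].split(","))
    sigs: dict[str, tuple[bool, ...]] = {}
    for ln in lines[idx + 1:]:
        ln = ln.strip()
        if not ln or "->" not in ln:
            continue
        pattern, sp = (part.strip() for part in ln.split("->"))
        sigs[sp] = tuple(c == "+" for c in pattern)
    return DiscriminationKey(pairs, sigs)
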