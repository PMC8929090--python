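"""Ground-truthed synthetic inputs: species panels and k-mer histograms.

The panel generator emulates a small clade of closely related taxa typed at
one or more barcode loci: every species descends from a common ancestor
sequence, shares background polymorphism with at least one other species,
and carries its own planted species-unique variants (SNPs, insertions,
deletions). Because each background substitution event is applied to a
subset of 2..n-2 species, both allele groups at a background column always
have two or more members — so the planted variants are, by construction,
the only species-diagnostic columns, and detector output can be scored for
both recall and precision against the truth table. (This guarantee needs a
panel of at least four species when background divergence is non-zero.)

The histogram generator builds an explicit diploid genome — a haplotype
pair differing at heterozygous sites spaced at least k apart, with a repeat
block at a configurable copy number — counts its k-mers exactly, then draws
per-k-mer depths from a Poisson at half-coverage per haplotype copy and
adds a singleton error spike. Heterozygosity is parameterized as the
fraction of genomic k-mers spanning a het site (so the half-depth-peak
volume ratio recovers the parameter directly); real data differ by
overdispersion, GC bias and error k-mers at depth >1, none of which are
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .diagnostic_sites import SiteClass
from .kmer_profile import KmerHistogram
from .seq_panel import DnaSequence, SequenceError, SequencePanel

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedVariant:
    """One planted species-unique variant, in ancestor and species coordinates."""

    locus: str
    species: str
    site_class: SiteClass
    ancestor_position: int  # 0-based on the ancestor sequence
    length: int  # 1 for SNPs; block length for indels
    allele: str  # new base (SNP) / inserted residues (insertion) / '' (deletion)
    species_position: int  # ungapped coord in the carrier: SNP base, 3'-most
    # inserted base, or (deletions) first base after the junction


@dataclass(frozen=True)
class PanelSimSpec:
    """Study conditions for one synthetic panel.

    Planted counts are per (species, locus); pass a sequence for per-species
    counts. Background divergence is the expected fraction of ancestor
    positions carrying a shared substitution event.
    """

    species: int = 5
    loci: int = 1
    locus_length: int = 1000
    divergence: float = 0.02
    snps: int | Sequence[int] = 1
    insertions: int | Sequence[int] = 0
    deletions: int | Sequence[int] = 0
    indel_length: tuple[int, int] = (2, 6)
    seed: int = 0
    edge_margin: int = 30  # room for primer windows

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.2):
            raise SimulationError("divergence must be in [0, 0.2]")
        if self.species < 2:
            raise SimulationError("need >=2 species")
        if self.divergence > 0 and self.species < 4:
            raise SimulationError(
                "background divergence needs >=4 species so shared substitutions "
                "never create species-unique columns"
            )

    def per_species(self, value: int | Sequence[int]) -> list[int]:
        if isinstance(value, int):
            return [value] * self.species
        if len(value) != self.species:
            raise SimulationError("per-species count list length != species count")
        return list(value)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    options = [b for b in "ACGT" if b not in exclude]
    return options[int(rng.integers(0, len(options)))]


def species_labels(n: int) -> list[str]:
    return [f"sp{i + 1}" for i in range(n)]


def simulate_panel(spec: PanelSimSpec) -> tuple[SequencePanel, list[PlantedVariant]]:
    """Generate a panel plus its planted-variant truth table.

    Deterministic for a fixed spec (the seed is part of the spec): same seed,
    byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    labels = species_labels(spec.species)
    snps = spec.per_species(spec.snps)
    insertions = spec.per_species(spec.insertions)
    deletions = spec.per_species(spec.deletions)
    n_planted = sum(snps) + sum(insertions) + sum(deletions)
    slot = spec.indel_length[1] + 5  # spacing so indel blocks never touch
    usable = spec.locus_length - 2 * spec.edge_margin
    if n_planted * slot > usable:
        raise SimulationError(
            f"{n_planted} planted variants do not fit a {spec.locus_length} bp locus"
        )

    panel = SequencePanel()
    truth: list[PlantedVariant] = []
    for locus_i in range(spec.loci):
        locus = f"locus{locus_i + 1}"
        L = spec.locus_length
        ancestor = _random_dna(rng, L)

        # planted positions: well separated, away from the ends
        positions = _spaced_positions(rng, spec.edge_margin, L - spec.edge_margin, slot, n_planted)

        assignments: list[tuple[str, SiteClass, int]] = []  # species, class, length
        for sp_i, label in enumerate(labels):
            assignments += [(label, SiteClass.SNP, 1)] * snps[sp_i]
            for _ in range(insertions[sp_i]):
                assignments.append(
                    (label, SiteClass.INSERTION,
                     int(rng.integers(spec.indel_length[0], spec.indel_length[1] + 1)))
                )
            for _ in range(deletions[sp_i]):
                assignments.append(
                    (label, SiteClass.DELETION,
                     int(rng.integers(spec.indel_length[0], spec.indel_length[1] + 1)))
                )
        order = rng.permutation(len(assignments))
        planted = [(positions[i], *assignments[order[i]]) for i in range(len(assignments))]
        planted.sort()
        planted_span = set()
        for pos, _label, _cls, length in planted:
            planted_span.update(range(pos - 1, pos + length + 1))

        # shared background substitutions
        n_events = int(round(spec.divergence * L))
        free = np.array([p for p in range(L) if p not in planted_span], dtype=np.int64)
        if n_events > len(free):
            raise SimulationError("divergence too high for locus length")
        bg_positions = rng.choice(free, size=n_events, replace=False)
        background: dict[int, tuple[str, frozenset[str]]] = {}
        for pos in sorted(int(p) for p in bg_positions):
            # subset of 2..n-2 carriers: both allele groups keep >=2 members
            subset_size = int(rng.integers(2, spec.species - 1))
            members = frozenset(
                labels[i] for i in rng.choice(spec.species, size=subset_size, replace=False)
            )
            background[pos] = (_other_base(rng, ancestor[pos]), members)

        # per-species edit scripts
        table: dict[str, DnaSequence] = {}
        locus_truth: list[PlantedVariant] = []
        for label in labels:
            subs: dict[int, str] = {
                pos: base for pos, (base, members) in background.items() if label in members
            }
            own: list[tuple[int, SiteClass, int, str]] = []
            for pos, p_label, cls, length in planted:
                if p_label != label:
                    continue
                if cls is SiteClass.SNP:
                    allele = _other_base(rng, ancestor[pos])
                    subs[pos] = allele
                    own.append((pos, cls, 1, allele))
                elif cls is SiteClass.INSERTION:
                    own.append((pos, cls, length, _random_dna(rng, length)))
                else:
                    own.append((pos, cls, length, ""))
            inserts = {pos: content for pos, cls, _l, content in own if cls is SiteClass.INSERTION}
            deletes = {pos: length for pos, cls, length, _c in own if cls is SiteClass.DELETION}
            residues: list[str] = []
            anc2sp: dict[int, int] = {}
            skip_until = -1
            for pos in range(L):
                if pos in deletes:
                    skip_until = pos + deletes[pos]
                if pos < skip_until:
                    continue
                anc2sp[pos] = len(residues)
                residues.append(subs.get(pos, ancestor[pos]))
                if pos in inserts:
                    residues.extend(inserts[pos])
            seq = "".join(residues)
            table[label] = DnaSequence(label, seq)
            for pos, cls, length, content in own:
                if cls is SiteClass.SNP:
                    sp_pos = anc2sp[pos]
                elif cls is SiteClass.INSERTION:
                    sp_pos = anc2sp[pos] + length  # 3'-most inserted base
                else:
                    nxt = next(p for p in range(pos + length, L) if p in anc2sp)
                    sp_pos = anc2sp[nxt]  # first base after the junction
                locus_truth.append(
                    PlantedVariant(locus, label, cls, pos, length, content, sp_pos)
                )
        panel.add_locus(locus, table)
        truth.extend(sorted(locus_truth, key=lambda v: (v.ancestor_position, v.species)))
    return panel, truth


def _spaced_positions(
    rng: np.random.Generator, lo: int, hi: int, min_gap: int, n: int
) -> list[int]:
    """n positions in [lo, hi) pairwise separated by >= min_gap, sorted draws."""
    span = hi - lo - (n - 1) * min_gap
    if n > 0 and span <= 0:
        raise SimulationError("not enough room for the requested planted variants")
    if n == 0:
        return []
    raw = np.sort(rng.choice(span, size=n, replace=False))
    return [int(lo + raw[i] + i * min_gap) for i in range(n)]


# ---------------------------------------------------------------------------
# k-mer histogram simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistSimSpec:
    """Study conditions for one synthetic diploid k-mer histogram."""

    genome_length: int = 1_000_000  # haploid bp
    het_fraction: float = 0.0  # fraction of genomic k-mers spanning a het site
    repeat_fraction: float = 0.0  # fraction of haploid content that is repetitive
    repeat_copy_number: int = 4
    coverage: float = 60.0  # depth of homozygous single-copy k-mers
    error_rate: float = 0.0  # per-base sequencing error rate
    k: int = 21
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_fraction", "repeat_fraction", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")
        if self.repeat_fraction > 0 and self.repeat_copy_number < 2:
            raise SimulationError("repeat copy number must be >=2")


def _encode(seq_codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every k-mer of a base-code array into one int64."""
    powers = (4 ** np.arange(k, dtype=np.int64))[::-1]
    windows = sliding_window_view(seq_codes.astype(np.int64), k)
    return windows @ powers


def simulate_histogram(spec: HistSimSpec) -> tuple[KmerHistogram, dict[str, float]]:
    """Simulate a diploid k-mer histogram plus its generating truth.

    Builds haplotype 1 as unique content plus a tandem repeat block, derives
    haplotype 2 by substituting het sites spaced >= k apart, counts k-mers of
    both haplotypes exactly, then draws each distinct k-mer's depth from
    Poisson(multiplicity x coverage / 2) and adds ``error_rate x coverage x
    genome_length x k`` singleton error k-mers at depth 1.
    """
    rng = np.random.default_rng(spec.seed)
    G, k = spec.genome_length, spec.k
    rep_total = int(round(G * spec.repeat_fraction))
    unit_len = rep_total // spec.repeat_copy_number if rep_total else 0
    unique_len = G - unit_len * spec.repeat_copy_number
    unique = rng.integers(0, 4, size=unique_len, dtype=np.int8)
    unit = rng.integers(0, 4, size=unit_len, dtype=np.int8)
    hap1 = np.concatenate([unique] + [unit] * spec.repeat_copy_number) if unit_len \
        else unique

    n_het = int(round(spec.het_fraction * G / k))
    hap2 = hap1.copy()
    if n_het:
        sites = _spaced_positions(rng, k, G - k, k, n_het)
        for pos in sites:
            hap2[pos] = (hap2[pos] + int(rng.integers(1, 4))) % 4

    codes = np.concatenate([_encode(hap1, k), _encode(hap2, k)])
    _, multiplicity = np.unique(codes, return_counts=True)
    depths = rng.poisson(multiplicity * (spec.coverage / 2.0))
    depths = depths[depths > 0]
    observed, counts = np.unique(depths, return_counts=True)
    table = {int(d): float(c) for d, c in zip(observed, counts)}
    n_err = int(round(spec.error_rate * spec.coverage * G * k))
    if n_err:
        table[1] = table.get(1, 0.0) + n_err
    hist = KmerHistogram.from_table(table, k=k)
    truth = {
        "genome_length": float(G),
        "het_fraction": float(spec.het_fraction),
        "repeat_fraction": float(spec.repeat_fraction),
        "coverage": float(spec.coverage),
    }
    return hist, truth
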