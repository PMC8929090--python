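"""Packaged reference fixtures: validated primer pairs and their gel pattern.

The seven primer pairs ship verbatim from the wet-lab study that validated
them on genomic DNA of five *Scutellaria* species; they are loaded with
``designed=False`` and are exempt from design-time quality filters (several
violate the default windows — the SP forward primer has 15% GC — yet worked
empirically). Their annealing temperatures are empirical metadata.

Template sequences for these accessions are not packaged (two are complete
chloroplast genomes); :func:`synthetic_pair_template` builds a synthetic
template embedding a pair's exact binding sites at the recorded product
size, for offline exercises of the in-silico PCR arithmetic.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

from .arms_primers import Primer, PrimerPair
from .discrimination_key import AmplificationMatrix, Cell
from .seq_panel import DnaSequence, revcomp

SPECIES = [
    "S_indica_L",
    "S_pekinensis_transitra",
    "S_indica_tsusimensis",
    "S_barbata",
    "S_baicalensis",
]

#: sample numbering of the validation gels (sample i -> species label)
SAMPLES = dict(enumerate(SPECIES, start=1))


def _data_rows(name: str) -> list[dict[str, str]]:
    text = resources.files("barcodekey.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def pairs_from_rows(rows: list[dict[str, str]]) -> list[PrimerPair]:
    """Build filter-exempt PrimerPair objects from primer-table rows.

    Expected columns: name, forward, reverse, product_size, target_species;
    optional: annealing_tm, accession, locus.
    """
    pairs = []
    for row in rows:
        fwd = Primer(
            name=f"{row['name']}_F",
            residues=row["forward"],
            strand="+",
            interval=(0, len(row["forward"])),
        )
        rev = Primer(
            name=f"{row['name']}_R",
            residues=row["reverse"],
            strand="-",
            interval=(0, len(row["reverse"])),
        )
        tm = row.get("annealing_tm")
        pairs.append(
            PrimerPair(
                name=row["name"],
                forward=fwd,
                reverse=rev,
                product_length=int(row["product_size"]),
                target_species=row.get("target_species", ""),
                locus=row.get("locus", ""),
                annealing_tm=float(tm) if tm not in (None, "", "-") else None,
                designed=False,
            )
        )
    return pairs


def load_primer_tsv(path) -> list[PrimerPair]:
    """Read a primer table TSV (same column layout as the packaged fixture)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    return pairs_from_rows(list(csv.DictReader(lines, delimiter="\t")))


def load_reference_pairs() -> list[PrimerPair]:
    """The seven validated pairs, verbatim, filters bypassed."""
    return pairs_from_rows(_data_rows("table7_primers.tsv"))


def expected_pattern() -> dict[str, tuple[set[str], bool]]:
    """Pair -> (positive species set, ambiguous-in-source flag)."""
    out: dict[str, tuple[set[str], bool]] = {}
    for row in _data_rows("fig6_pattern.tsv"):
        out[row["pair"]] = (set(row["positives"].split(";")), row["ambiguous"] == "yes")
    return out


def reference_matrix(pairs: list[str] | None = None) -> AmplificationMatrix:
    """Presence/absence matrix of the validated pattern.

    `pairs` selects and orders columns (default: the six-pair cross-validation
    view SL, SP, ST1, SD1, SD2, SB; ST2 duplicates ST1's column). Positive
    cells carry the pair's recorded product size.
    """
    if pairs is None:
        pairs = ["SL", "SP", "ST1", "SD1", "SD2", "SB"]
    pattern = expected_pattern()
    sizes = {p.name: p.product_length for p in load_reference_pairs()}
    cells = {
        (sp, pr): (
            Cell.positive((sizes[pr],)) if sp in pattern[pr][0] else Cell.negative()
        )
        for sp in SPECIES
        for pr in pairs
    }
    return AmplificationMatrix(list(SPECIES), list(pairs), cells)


def synthetic_pair_template(pair: PrimerPair, seed: int = 0,
                            flank: int = 60) -> DnaSequence:
    """Synthetic amplification template for one reference pair.

    A random sequence with the pair's exact forward site and reverse-site
    complement embedded so the predicted product equals the recorded product
    size. This is a stand-in constructed for offline use — it is not the
    GenBank record the pair was designed against.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    total = flank + pair.product_length + flank
    arr = bases[rng.integers(0, 4, size=total)]
    template = bytearray(arr.tobytes())
    f = pair.forward.residues.encode()
    r = revcomp(pair.reverse.residues).encode()
    template[flank : flank + len(f)] = f
    end = flank + pair.product_length
    template[end - len(r) : end] = r
    return DnaSequence(f"synthetic_{pair.name}_template", template.decode())
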