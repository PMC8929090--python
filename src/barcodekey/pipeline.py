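"""End-to-end orchestration: panel -> sites -> primers -> e-PCR -> key.

Each stage persists a TSV into the run directory, every output carries a
header comment with the config hash and seed, and a machine-readable
summary.json ties the run together. The all-vs-rest mode designs primers
for every species in the panel and merges them into one amplification
matrix before keying — the way a mixed-provenance primer set discriminates
a whole panel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .arms_primers import DesignConstraints, PrimerPair, design_allele_specific_pairs
from .diagnostic_sites import find_diagnostic_sites, sites_to_rows
from .discrimination_key import (
    AmplificationMatrix,
    DiscriminationKey,
    KeyError_,
    minimal_key,
    render_key,
)
from .insilico_pcr import DEFAULT_MAX_SCORE, DEFAULT_SIZE_RANGE, amplification_matrix
from .seq_panel import (
    MultipleAlignment,
    SequenceError,
    SequencePanel,
    align_panel_locus,
    load_panel,
    read_alignment_fasta,
    read_fasta,
    read_labels_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run configuration. ``loci`` maps locus name -> multi-FASTA path."""

    loci: dict[str, str]
    targets: list[str] | None = None  # None: all-vs-rest sweep
    labels_tsv: str | None = None
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    max_score: float = DEFAULT_MAX_SCORE
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE
    out_dir: str = "barcodekey_run"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "loci": self.loci,
                "targets": self.targets,
                "labels_tsv": self.labels_tsv,
                "constraints": dataclasses.asdict(self.constraints),
                "max_score": self.max_score,
                "size_range": list(self.size_range),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (
        f"# barcodekey {__version__} | config {config.config_hash()} | "
        f"seed {config.seed}\n"
    )


def _write_tsv(path: Path, config: PipelineConfig, header: list[str],
               rows: list[list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def load_alignments(config: PipelineConfig) -> dict[str, MultipleAlignment]:
    """Stage 0: read every locus FASTA; accept pre-aligned files as-is."""
    labels = read_labels_tsv(config.labels_tsv) if config.labels_tsv else None
    alignments: dict[str, MultipleAlignment] = {}
    for locus, path in config.loci.items():
        if not Path(path).exists():
            raise PipelineError(f"input: {path} does not exist")
        msa = read_alignment_fasta(path)
        if msa is None:
            panel = load_panel({locus: path}, labels)
            msa = align_panel_locus(panel.loci[locus])
        elif labels:
            msa = MultipleAlignment([labels.get(l, l) for l in msa.labels], msa.rows)
        alignments[locus] = msa
    return alignments


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute sites -> design -> epcr -> key, persisting per-stage TSVs.

    Returns the summary dict (also written to summary.json). Raises
    :class:`PipelineError` naming the failing stage. A panel whose species
    remain indistinguishable is reported in the summary with
    ``distinguishable: false`` rather than raising.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        alignments = load_alignments(config)
    except (SequenceError, OSError) as exc:
        raise PipelineError(f"input: {exc}") from exc

    species: list[str] = []
    for msa in alignments.values():
        for label in msa.labels:
            if label not in species:
                species.append(label)
    targets = config.targets or species

    # stage 1: diagnostic sites
    site_rows = []
    sites_by_target: dict[str, int] = {t: 0 for t in targets}
    for locus, msa in alignments.items():
        for target in targets:
            if target not in msa.labels:
                continue
            found = find_diagnostic_sites(msa, target, locus)
            sites_by_target[target] += len(found)
            for row in sites_to_rows(found):
                site_rows.append(list(row.values()))
    _write_tsv(
        out / "sites.tsv", config,
        ["locus", "column", "class", "target", "target_allele", "other_alleles",
         "target_position"],
        site_rows,
    )

    # stage 2: primer design
    pairs: list[PrimerPair] = []
    for locus, msa in alignments.items():
        for target in targets:
            if target not in msa.labels:
                continue
            try:
                pairs.extend(
                    design_allele_specific_pairs(msa, target, config.constraints, locus)
                )
            except SequenceError as exc:
                raise PipelineError(f"design: {exc}") from exc
    _write_tsv(
        out / "primers.tsv", config,
        ["name", "forward", "reverse", "product_size", "locus", "target_species",
         "penalty"],
        [
            [p.name, p.forward.residues, p.reverse.residues, p.product_length,
             p.locus, p.target_species, f"{p.penalty:.3f}"]
            for p in pairs
        ],
    )

    # stage 3: in-silico PCR matrix over the panel's own templates
    templates = {
        sp: {
            locus: msa.ungapped(sp)
            for locus, msa in alignments.items()
            if sp in msa.labels
        }
        for sp in species
    }
    matrix = amplification_matrix(pairs, templates, config.size_range, config.max_score)
    matrix_path = out / "matrix.tsv"
    matrix_path.write_text(_header(config))
    _append_matrix(matrix_path, matrix)

    # stage 4: discrimination key
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "species": species,
        "sites_per_target": sites_by_target,
        "n_pairs_designed": len(pairs),
    }
    try:
        key = minimal_key(matrix)
        (out / "key.txt").write_text(_header(config) + render_key(key, matrix))
        summary["distinguishable"] = True
        summary["key_pairs"] = list(key.pairs)
        summary["key_size"] = len(key.pairs)
    except KeyError_ as exc:
        summary["distinguishable"] = False
        summary["key_error"] = str(exc)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _append_matrix(path: Path, matrix: AmplificationMatrix) -> None:
    with open(path, "a") as fh:
        fh.write("species\t" + "\t".join(matrix.pairs) + "\n")
        for sp in matrix.species:
            fh.write(
                sp + "\t"
                + "\t".join(matrix.cell(sp, pr).render() for pr in matrix.pairs)
                + "\n"
            )
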