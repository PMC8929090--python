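# Methods

This note records the models, parameter choices and numerical conventions
behind `barcodekey`, and what its synthetic benchmarks do and do not show.

## Sequence handling and alignment

Sequences are upper-cased DNA over {A,C,G,T,N}. IUPAC ambiguity codes other
than N are rejected at ingest with a clear message rather than silently
degraded; `N` matches nothing, including another `N` — an ambiguous base can
never support a match or certify a diagnostic allele. All coordinates are
0-based and half-open throughout.

Pairwise alignment is global Needleman–Wunsch with linear gap costs,
default +1 match / −1 mismatch / −2 gap. Affine gaps were deliberately
omitted: the panels this tool targets are near-identical barcode sequences
where the indels of interest are short and species-unique, and a second gap
parameter adds nothing testable. The traceback is deterministic with fixed
priority diagonal > up > left, so gap placement is reproducible across
runs and platforms. The fill is vectorized row-wise; within a row the
left-gap recurrence collapses to a running maximum, keeping kb-scale
alignments fast without native code.

The multiple alignment is center-star: the center maximizes summed pairwise
score (ties broken by input order) and other rows are merged under "once a
gap, always a gap". Every MSA asserts that de-gapping each row reproduces
its input byte-exactly. Files whose records are equal length and contain
`-` are accepted as pre-built alignments and bypass the aligner, so
externally aligned panels can be supplied as-is. Alignment parameters used
by external viewers are not reconstructed; no claim is made that
center-star reproduces any particular third-party gap placement.

A minimal GenBank flat-file reader (LOCUS/ACCESSION/ORIGIN) handles
template records: features are ignored, a LOCUS/ORIGIN length disagreement
warns but returns the ORIGIN sequence, and a missing ORIGIN is an error.

## Diagnostic sites

A column is diagnostic for target *t* iff *t*'s symbol differs from every
other species' symbol, no `N` occurs in the column, and the gap pattern is
clean: all-others-gapped (insertion), target-gapped with all others based
(deletion), or gap-free (SNP). Columns where non-target species mix gaps
and bases are skipped as ambiguous. Columns where the non-targets disagree
among themselves still qualify when the target allele is absent from all of
them. Uniqueness is defined against the panel only — nothing is claimed
about unsampled taxa. Runs of indel columns are additionally merged into
blocks for reporting; primer design anchors on the 3′-most column of a
block. Note that tied gap placements can scatter one biological indel over
nearby non-adjacent columns; the per-column site list is complete either
way.

## ARMS primer design

The allele-specific primer ends 3′ on the diagnostic site. "Third base from
the 3′ end" is read as offset 2 counting the terminus as offset 0; the
replacement base must mismatch the template of every panel species at that
column and is chosen by destabilization priority — purine–purine or
pyrimidine–pyrimidine appositions preferred, ties broken by fixed base
order A<C<G<T — so designs are reproducible. For insertion sites the 3′ end
sits on the 3′-most inserted base of the carrier; for target deletions the
primer spans the junction (3′ end on the first base after it), which makes
an ungapped perfect-match window impossible on templates that retain the
deleted bases. Both orientations are attempted per site.

Melting temperature is the GC-count formula Tm = 64.9 + 41·(GC − 16.4)/N
(valid for N ≥ 14). Nearest-neighbor thermodynamics are out of scope; the
formula only ranks primers and enforces coarse windows. The packaged
validated primer table carries empirical annealing temperatures that are
metadata, never recomputed — spot checks show them inconsistent with any
single standard formula.

Default design constraints: primer length 18–25 nt, product 100–1000 bp,
Tm 50–62 °C with pair ΔTm ≤ 5 °C, GC 0.30–0.70, homopolymer runs ≤ 4,
3′ self/cross complementary runs ≤ 4. The product range is the assay
design target; the other windows are conventional primer-design practice.
Pairs are ranked by penalty = |Tm_f − Tm_r| + Σ per primer (0.5 per nt from
20 + 10 per unit GC from 0.50), with a stable tie-break, and truncated to
10 pairs per site/orientation by default (`max_pairs_per_site=None`
disables truncation, used by the exhaustive-enumeration test). The packaged
validated pairs are exempt from these filters: several violate the default
windows (one forward primer has 15% GC) yet worked empirically.

## In-silico PCR

Binding is ungapped, scored per window on both strands against an
exhaustive sliding-window scan. Mismatch weights by 3′ offset: offset 0
blocks the site, offsets 1–4 cost 2, offsets ≥ 5 cost 1; template `N`
counts as a mismatch. The default acceptance threshold max_score = 3 is the
minimal setting that makes the ARMS design rule self-consistent: the
designed offset-2 mismatch (weight 2) plus one distal mismatch is
tolerated, while a diagnostic 3′-terminal mismatch — or the designed
mismatch plus a second 3′-proximal one — kills the site. Both the weights
and the threshold are exposed as parameters.

Amplicons pair convergent sites within a size window (default 50–5000 bp);
the swapped strand assignment is also evaluated so primer tables with
exchanged forward/reverse labels still amplify. Product length is the
plus-strand span from forward-site start to reverse-site end, counting both
primer footprints inclusively — the convention under which the validated
pairs' recorded sizes are exact. Species lacking a template for a pair's
locus are recorded as "untested", distinct from a negative prediction.

## Discrimination keys

Keying uses presence/absence only — the information a gel band carries —
with product lengths surfaced in rendered tables but not required for
distinctness. Untested cells poison subset evaluation rather than being
coerced to negative, since the cross-validation logic presumes every pair
was run on every sample. The minimal subset is found exactly (subsets by
increasing cardinality, lexicographic within) up to 20 pairs; beyond that a
greedy cover of unresolved species-pairs runs, which guarantees a valid but
not necessarily minimum key. Species that no pair separates are reported
as an indistinguishable group instead of a key.

## K-mer genome profile

Estimators operate on the histogram's bins as recorded, in depth order;
k itself is metadata. With main-peak depth *c* and bin volume
V(d) = d·count(d):

- **error cutoff** — first trough of the window-3 moving-average volume
  curve, with two guards: the curve must descend into the trough from the
  spectrum's start (an error peak opens the spectrum; a valley between the
  main and a repeat peak never qualifies), and the trough bin cannot carry
  the global volume maximum (a 3-bin edge artifact otherwise). No trough
  means cutoff 0 with a warning. Depths ≤ cutoff are discarded downstream.
- **k-mer coverage** — argmax of V(d) beyond the cutoff, refined through
  the parabola fitted to the three surrounding bins and rounded to one
  decimal, so fractional peak depths are representable.
- **genome length** — retained volume / *c*, rounded. Haplotype-unique
  k-mer volume is deliberately left in; this plain estimator over-counts
  het content by construction (documented, visible in the two-peak hand
  example: (50·500 + 100·1000)/100 = 1250).
- **heterozygosity** — V(c/4 .. 3c/4] / (V(c/4 .. 3c/4] + V(3c/4 .. 1.8c]),
  the half-depth-peak volume share. This is a self-contained definition
  validated by monotone recovery on the package's own simulator; it is not
  claimed to reproduce any particular published heterozygosity figure,
  whose formula and units are typically unstated.
- **repeat length** — genome length × retained-volume fraction at depths
  > 1.8·*c*. The 1.8 factor keeps the upper main-peak shoulder out of the
  repeat mass; the reading "volume beyond 1.8× the peak, as a fraction of
  total retained volume, times genome length" is the one under which a
  repeat length is a length in bp.

## Synthetic data

The panel generator draws a uniform ancestor per locus, plants
species-unique variants (SNPs, insertions, deletions) at well-separated
positions ≥ 30 bp from the ends (room for primer windows), then applies
background substitution events each shared by a random subset of 2..n−2
species. Sharing is the load-bearing choice: it emulates polymorphism
inherited from common ancestry, and it guarantees both allele groups at a
background column have ≥ 2 members, so the planted variants are the *only*
species-diagnostic columns and detector output can be scored for recall
and precision against the truth table. This guarantee needs ≥ 4 species
when divergence > 0 (enforced). Per-species divergence is therefore the
panel-wide density of shared substitution events (default 2%, matching
closely related congeners), not an independent per-lineage rate.
Defaults: 5 species, 1 kb loci — a small clade typed at chloroplast
barcode loci.

The histogram generator builds an explicit diploid genome: unique content
plus a tandem repeat block at the configured copy number, haplotype 2
derived by substituting het sites spaced ≥ k apart. The het parameter is
the fraction of genomic k-mers spanning a het site (site count =
h·G/k); spacing sites at least k apart makes that parameter what the
half-depth-peak estimator measures, mirroring real low-heterozygosity
genomes where het sites rarely co-occur within one k-mer. K-mers of both
haplotypes are counted exactly (2-bit packed, vectorized), each distinct
k-mer's depth is drawn Poisson(multiplicity × coverage/2), and sequencing
error adds error_rate × coverage × G × k singleton k-mers at depth 1.
Defaults: 21-mers, 60× coverage, error-free.

Not modelled: depth overdispersion (real spectra are wider than Poisson),
GC-coverage bias, error k-mers at depth > 1, alignment uncertainty from
repeats within barcode loci, and within-species polymorphism (one sequence
per species). Passing tests therefore demonstrate correctness of the
estimators and the design logic under the stated generative model, not
robustness to every artifact of real sequencing data.

## Benchmark problem sizes

The test suite and acceptance script use 1 kb single-locus panels of five
species (10 seeds for recall/precision, 2 for end-to-end ARMS
specificity), 0.4–0.5 Mb simulated genomes for the k-mer recovery runs
(10 seeds for genome length), 100 random instances per brute-force oracle
comparison, and the packaged seven-pair validated table for the
product-size and key computations. These sizes were chosen so each
property is exercised at realistic parameter values while the whole suite
stays comfortably interactive.

## Known limitations

- Real amplification templates (GenBank accessions) are not packaged; the
  product-size checks run on synthetic templates embedding each validated
  pair's binding sites at the recorded spacing. The `fetch` command
  retrieves the real records when network is available.
- Binding is ungapped: primer-template bulges are out of model (diagnostic
  indels are instead handled by junction-spanning primers).
- The expected pattern for two of the seven validated pairs (SD1, SD2) is
  recorded as reported in the validating study's discussion and flagged
  ambiguous, as its results and discussion sections disagree.
- The greedy key fallback (> 20 pairs) can return a non-minimum key.
- Center-star alignment is O(n²) in panel size and approximate; for large
  panels an external aligner's output can be supplied pre-aligned.
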