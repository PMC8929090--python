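"""Genome-profile estimators from a k-mer depth histogram.

A k-mer histogram (depth -> count of distinct k-mers at that depth, the
dialect jellyfish/KMC write with ``histo``) carries four recoverable genome
quantities:

* **error cutoff** — the trough separating the sharp low-depth error peak
  from genomic k-mers; everything at or below it is discarded.
* **k-mer coverage** — the depth of the main volume peak (volume = depth x
  count), refined to one decimal by quadratic interpolation so fractional
  peak depths are representable.
* **genome length** — retained k-mer volume divided by the main-peak depth.
* **heterozygosity** — the volume of the half-depth (haplotype-unique) peak
  as a fraction of half-peak plus main-peak volume.
* **repeat length** — genome length times the fraction of retained volume
  lying beyond 1.8x the main peak.

k itself is metadata: every estimator is k-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


class HistogramError(ValueError):
    pass


@dataclass(frozen=True)
class KmerHistogram:
    """Depth spectrum: parallel arrays of unique depths and distinct-k-mer counts."""

    depths: np.ndarray
    counts: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=np.int64)
        c = np.asarray(self.counts, dtype=np.float64)
        if d.shape != c.shape or d.ndim != 1:
            raise HistogramError("depths and counts must be parallel 1-D arrays")
        if len(np.unique(d)) != len(d):
            raise HistogramError("duplicate depth bins")
        if (d < 1).any() or (c < 0).any():
            raise HistogramError("depths must be >=1 and counts >=0")
        order = np.argsort(d)
        object.__setattr__(self, "depths", d[order])
        object.__setattr__(self, "counts", c[order])
        if float(self.volume().sum()) <= 0:
            raise HistogramError("histogram has zero total k-mer volume")

    @classmethod
    def from_table(cls, table: dict[int, float], k: int | None = None) -> "KmerHistogram":
        d = np.array(list(table), dtype=np.int64)
        c = np.array([table[int(x)] for x in d], dtype=np.float64)
        return cls(d, c, k)

    @classmethod
    def read(cls, path: str | Path, k: int | None = None) -> "KmerHistogram":
        """Two whitespace-separated columns: depth, distinct-k-mer count."""
        data = np.loadtxt(path, dtype=np.float64, ndmin=2, comments="#")
        if data.shape[1] < 2:
            raise HistogramError(f"{path}: expected two columns (depth, count)")
        return cls(data[:, 0].astype(np.int64), data[:, 1], k)

    def volume(self) -> np.ndarray:
        return self.depths.astype(np.float64) * self.counts


@dataclass(frozen=True)
class GenomeProfile:
    """The four headline quantities plus the error cutoff used."""

    kmer_coverage: float
    heterozygosity: float
    genome_length: int
    repeat_length: int
    error_cutoff: int
    k: int | None = None

    def __post_init__(self) -> None:
        if self.repeat_length > self.genome_length:
            raise HistogramError("repeat length cannot exceed genome length")
        if self.kmer_coverage <= self.error_cutoff:
            raise HistogramError("main peak cannot sit inside the error region")


def error_cutoff(hist: KmerHistogram) -> int:
    """Depth of the first trough of the smoothed volume curve, scanning from 1.

    The curve is the per-bin volume in depth order (bins as recorded, so a
    sparse two-peak table with nothing in between has a monotone curve and
    hence no error trough). Smoothing is a window-3 moving average, edges
    averaged over the bins available. K-mers at depths <= cutoff are treated
    as sequencing-error artifacts downstream.

    Two sanity guards keep the trough an *error* boundary: the curve must
    descend into it from the histogram's start (an error peak opens the
    spectrum, so a valley between the main and a repeat peak never
    qualifies), and the trough bin cannot itself carry the global volume
    maximum. A curve with no such minimum (no error peak) yields 0 with a
    warning.
    """
    vol = hist.volume()
    if len(vol) < 3:
        warnings.warn("histogram too short to locate an error trough; cutoff 0")
        return 0
    kernel = np.ones(3)
    smooth = np.convolve(vol, kernel, mode="same") / np.convolve(
        np.ones_like(vol), kernel, mode="same"
    )
    raw_max = float(vol.max())
    for i in range(1, len(smooth) - 1):
        if not (smooth[i - 1] > smooth[i] <= smooth[i + 1]):
            continue
        if int(np.argmax(smooth[: i + 1])) != 0:
            break  # curve rose before dipping: that peak is genomic, stop
        if vol[i] == raw_max:
            continue
        return int(hist.depths[i])
    warnings.warn("volume curve has no interior minimum (no error peak); cutoff 0")
    return 0


def main_peak_depth(hist: KmerHistogram, cutoff: int | None = None) -> float:
    """Depth of the main volume peak, refined by quadratic interpolation.

    The argmax of depth*count over depths > cutoff is refined through the
    parabola fitted to the three surrounding bins and rounded to one decimal,
    so fractional peak depths are representable.
    """
    if cutoff is None:
        cutoff = error_cutoff(hist)
    grid = hist.depths
    vol = hist.volume()
    mask = grid > cutoff
    if not mask.any() or vol[mask].sum() <= 0:
        raise HistogramError("no k-mer volume beyond the error cutoff")
    vol_masked = np.where(mask, vol, -np.inf)
    i = int(np.argmax(vol_masked))
    peak = float(grid[i])
    if 0 < i < len(vol) - 1 and mask[i - 1]:
        x = grid[i - 1 : i + 2].astype(float)
        y = vol[i - 1 : i + 2]
        a, b, _c = np.polyfit(x, y, 2)
        if a < 0:
            vertex = -b / (2 * a)
            peak = float(np.clip(vertex, x[0], x[2]))
    return round(peak, 1)


def _volume_between(hist: KmerHistogram, lo: float, hi: float) -> float:
    """Summed volume over depths d with lo < d <= hi."""
    sel = (hist.depths > lo) & (hist.depths <= hi)
    return float(hist.volume()[sel].sum())


def estimate_genome_length(hist: KmerHistogram, cutoff: int | None = None,
                           peak: float | None = None) -> int:
    """Retained k-mer volume / main-peak depth, rounded to an integer.

    Half-depth (heterozygous) k-mer volume is deliberately left in: this is
    the plain total-volume estimator, and it over-counts het content by
    construction.
    """
    if cutoff is None:
        cutoff = error_cutoff(hist)
    if peak is None:
        peak = main_peak_depth(hist, cutoff)
    total = _volume_between(hist, cutoff, float("inf"))
    return int(round(total / peak))


def estimate_heterozygosity(hist: KmerHistogram, cutoff: int | None = None,
                            peak: float | None = None) -> float:
    """Half-depth-peak volume ratio: V_half / (V_half + V_main).

    V_half sums volume over depths in (c/4, 3c/4]; V_main over (3c/4, 1.8c],
    where c is the main-peak depth. Warns when the half-peak window dips into
    the error region.
    """
    if cutoff is None:
        cutoff = error_cutoff(hist)
    if peak is None:
        peak = main_peak_depth(hist, cutoff)
    if peak / 4 < cutoff:
        warnings.warn(
            "half-depth window overlaps the error region; "
            "heterozygosity may be contaminated"
        )
    v_half = _volume_between(hist, peak / 4, 3 * peak / 4)
    v_main = _volume_between(hist, 3 * peak / 4, 1.8 * peak)
    if v_half + v_main == 0:
        return 0.0
    return v_half / (v_half + v_main)


def estimate_repeat_length(hist: KmerHistogram, genome_length: int | None = None,
                           cutoff: int | None = None, peak: float | None = None) -> int:
    """Genome length times the retained-volume fraction beyond 1.8x the peak."""
    if cutoff is None:
        cutoff = error_cutoff(hist)
    if peak is None:
        peak = main_peak_depth(hist, cutoff)
    if genome_length is None:
        genome_length = estimate_genome_length(hist, cutoff, peak)
    total = _volume_between(hist, cutoff, float("inf"))
    deep = _volume_between(hist, 1.8 * peak, float("inf"))
    return int(round(genome_length * deep / total))


def genome_profile(hist: KmerHistogram) -> GenomeProfile:
    """Run the full estimator chain on one histogram."""
    cutoff = error_cutoff(hist)
    peak = main_peak_depth(hist, cutoff)
    length = estimate_genome_length(hist, cutoff, peak)
    het = estimate_heterozygosity(hist, cutoff, peak)
    rep = estimate_repeat_length(hist, length, cutoff, peak)
    return GenomeProfile(
        kmer_coverage=peak,
        heterozygosity=het,
        genome_length=length,
        repeat_length=rep,
        error_cutoff=cutoff,
        k=hist.k,
    )
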