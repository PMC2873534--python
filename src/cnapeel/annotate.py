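"""Peak annotation, driver-gene enrichment, and s-tuning diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneTable, MarkerGrid, SegmentSet
from .peeloff import PeakRegion

logger = logging.getLogger("cnapeel")

__all__ = [
    "DriverGeneSet",
    "EnrichmentResult",
    "genes_in_peak",
    "peak_shift_test",
    "read_driver_list",
    "segment_size_histogram",
    "min_peak_distance",
]


@dataclass(frozen=True)
class DriverGeneSet:
    """Gene symbols considered likely drivers (nonempty for testing)."""

    symbols: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", frozenset(self.symbols))
        if not self.symbols:
            raise ValueError("driver gene set must be nonempty")

    def __len__(self) -> int:
        return len(self.symbols)


def read_driver_list(path) -> DriverGeneSet:
    """Read a driver list, one gene symbol per line."""
    with open(path) as fh:
        symbols = {line.strip() for line in fh if line.strip()}
    return DriverGeneSet(symbols=symbols)


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the peak-shift permutation test.

    ``p_value = (1 + #{permutation count >= observed}) / (1 + n_iter)`` — the
    +1 pseudo-count estimator, which never reports exactly zero.
    """

    observed: int
    perm_counts: np.ndarray
    p_value: float
    n_iter: int


def genes_in_peak(region: PeakRegion, genes: GeneTable) -> list[str]:
    """Symbols of genes overlapping the peak's genomic span by >= 1 bp."""
    df = genes.records
    hit = (
        (df["chrom"] == region.chrom)
        & (df["start"] <= region.end)
        & (df["end"] >= region.start)
    )
    return df.loc[hit, "symbol"].tolist()


def _count_driver_peaks(
    starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    placements: list[tuple[str, int, int]],
) -> int:
    n = 0
    for chrom, start, end in placements:
        if chrom not in starts_by_chrom:
            continue
        g_start, g_end = starts_by_chrom[chrom]
        if np.any((g_start <= end) & (g_end >= start)):
            n += 1
    return n


def peak_shift_test(
    peaks: list[PeakRegion],
    drivers: DriverGeneSet,
    genes: GeneTable,
    grid: MarkerGrid,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Permutation test: are reported peaks enriched for likely driver genes?

    Each iteration independently relocates every peak to a random genome
    position preserving its length: a chromosome is chosen with probability
    proportional to its length, then a valid start position uniformly, so
    the shifted peak lies wholly on one chromosome.  Shifted peaks may
    overlap each other (shifts are independent).  The statistic is the
    number of peaks containing at least one driver gene.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not peaks:
        raise ValueError("no peaks to test")
    df = genes.records
    driver_df = df[df["symbol"].isin(drivers.symbols)]
    starts_by_chrom = {
        str(c): (grp["start"].to_numpy(), grp["end"].to_numpy())
        for c, grp in driver_df.groupby("chrom")
    }
    chrom_len = grid.chrom_lengths()
    chroms = sorted(chrom_len, key=lambda c: c)
    lengths = np.array([chrom_len[c] for c in chroms], dtype=float)

    observed = _count_driver_peaks(
        starts_by_chrom, [(p.chrom, p.start, p.end) for p in peaks]
    )

    peak_lens = np.array([p.end - p.start + 1 for p in peaks])
    for L in peak_lens:
        if not np.any(lengths >= L):
            raise ValueError(f"peak of length {L} bp is longer than every chromosome")

    rng = np.random.default_rng(seed)
    perm_counts = np.empty(n_iter, dtype=np.int64)
    weights = lengths / lengths.sum()
    for it in range(n_iter):
        placements = []
        for L in peak_lens:
            while True:
                ci = rng.choice(len(chroms), p=weights)
                if lengths[ci] >= L:
                    break
            start = int(rng.integers(1, chrom_len[chroms[ci]] - L + 2))
            placements.append((chroms[ci], start, start + int(L) - 1))
        perm_counts[it] = _count_driver_peaks(starts_by_chrom, placements)

    p = (1 + int(np.sum(perm_counts >= observed))) / (1 + n_iter)
    return EnrichmentResult(
        observed=observed, perm_counts=perm_counts, p_value=p, n_iter=n_iter
    )


def segment_size_histogram(
    segs: SegmentSet, grid: MarkerGrid | None = None
) -> pd.Series:
    """Histogram of segment lengths in markers, for tuning ``s``.

    Lengths come from the SEG ``num_markers`` column when present, otherwise
    by counting grid markers inside each segment.  Candidate values of the
    persistence parameter are the sizes where the count drops sharply.
    """
    df = segs.records
    if "num_markers" in df.columns:
        lengths = df["num_markers"].astype(int)
    elif grid is not None:
        blocks = {c: (lo, hi) for c, lo, hi in grid.chrom_blocks()}
        vals = []
        for _, seg in df.iterrows():
            if seg["chrom"] not in blocks:
                vals.append(0)
                continue
            lo, hi = blocks[seg["chrom"]]
            pos = grid.pos[lo:hi]
            i0 = np.searchsorted(pos, seg["start"], side="left")
            i1 = np.searchsorted(pos, seg["end"], side="right")
            vals.append(int(i1 - i0))
        lengths = pd.Series(vals, dtype=int)
    else:
        raise ValueError("need a num_markers column or a marker grid")
    if len(lengths) == 0:
        return pd.Series(dtype=int, name="count")
    hist = lengths.value_counts().sort_index()
    hist.name = "count"
    hist.index.name = "segment_markers"
    return hist


def min_peak_distance(peaks: list[PeakRegion]) -> pd.DataFrame:
    """Per-peak distance (bp) to the nearest other peak on the same chromosome.

    The distance between 1-based inclusive spans [a1, b1] and [a2, b2] with
    b1 < a2 is ``a2 - b1 - 1`` (0 for adjacent or overlapping spans).  Peaks
    with no same-chromosome neighbor are omitted with a log message; a
    single peak yields an empty table.
    """
    rows = []
    for i, p in enumerate(peaks):
        best = None
        for j, o in enumerate(peaks):
            if i == j or o.chrom != p.chrom:
                continue
            if o.start > p.end:
                d = o.start - p.end - 1
            elif p.start > o.end:
                d = p.start - o.end - 1
            else:
                d = 0
            best = d if best is None else min(best, d)
        if best is None:
            logger.debug(
                "peak %s:%d-%d has no same-chromosome neighbor; omitted",
                p.chrom, p.start, p.end,
            )
            continue
        rows.append((p.chrom, p.start, p.end, p.order, best))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "order", "min_distance_bp"]
    )
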