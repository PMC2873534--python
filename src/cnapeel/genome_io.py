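"""Validated containers and readers/writers for segmented copy-number input.

All genomic coordinates are 1-based inclusive internally and in reports; the
single exception is BED export, which converts to 0-based half-open at the
point of writing.  Chromosome names are normalized by stripping a leading
``chr`` prefix; ``X``/``Y`` are kept, mitochondrial markers are excluded by
default.  Copy-number values are segmented log2 ratios centered at 0 (the
implementation assumes log2-ratio input throughout; absolute copy numbers must
be converted by the caller).

Supported formats
-----------------
* marker-level matrix: tab-delimited, header row with sample ids, first three
  columns are marker id / chromosome / position, one column per sample;
* SEG: tab-delimited ``sample  chromosome  start  end  [num_markers]  value``,
  header optional;
* gene and chromosome-arm tables: tab-delimited with headers;
* peak reports (tab-delimited) and IGV ``.igv`` / BED output tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .peeloff import PeakRegion

logger = logging.getLogger("cnapeel")

__all__ = [
    "GenomeInputError",
    "DuplicateMarkerError",
    "UnsortedMarkerError",
    "OverlappingSegmentError",
    "ArmAssignmentError",
    "MarkerGrid",
    "SegmentSet",
    "CopyNumberMatrix",
    "GeneTable",
    "ArmTable",
    "read_marker_matrix",
    "read_seg",
    "project_segments",
    "segments_from_matrix",
    "read_gene_table",
    "read_arm_table",
    "assign_arms",
    "write_peak_report",
    "read_peak_report",
    "write_igv_tracks",
    "write_marker_matrix",
]


class GenomeInputError(ValueError):
    """Base class for malformed genomic input."""


class DuplicateMarkerError(GenomeInputError):
    """A marker identifier occurs more than once."""


class UnsortedMarkerError(GenomeInputError):
    """Marker positions are not strictly increasing within a chromosome."""


class OverlappingSegmentError(GenomeInputError):
    """Two segments of one sample on one chromosome overlap."""


class ArmAssignmentError(GenomeInputError):
    """A marker's chromosome has no arm definition."""


_CHROM_SPECIAL = {"X": 23, "Y": 24}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix and canonicalize X/Y case."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("X", "Y"):
        return s.upper()
    return s


def chrom_sort_key(name: str):
    """Natural chromosome order: 1..22, X, Y, then anything else lexically."""
    if name.isdigit():
        return (0, int(name), "")
    if name in _CHROM_SPECIAL:
        return (0, _CHROM_SPECIAL[name], "")
    return (1, 0, name)


def _is_mito(name: str) -> bool:
    return name.upper() in ("M", "MT")


@dataclass(frozen=True)
class MarkerGrid:
    """Ordered genomic markers: the coordinate system every track lives on.

    Markers are sorted by (chromosome, position) with positions strictly
    increasing within a chromosome.  ``arm`` is ``None`` until
    :func:`assign_arms` has resolved each marker against an :class:`ArmTable`.
    """

    names: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    arm: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = np.asarray(self.names, dtype=object)
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        if not (len(names) == len(chrom) == len(pos)):
            raise GenomeInputError("marker grid field lengths differ")
        if np.any(pos < 1):
            raise GenomeInputError("marker positions must be >= 1 (1-based)")
        uniq, counts = np.unique(names, return_counts=True)
        if np.any(counts > 1):
            dup = uniq[counts > 1][0]
            raise DuplicateMarkerError(f"duplicate marker id {dup!r}")
        # sorted by (chromosome, position), strictly increasing within chrom
        keys = [chrom_sort_key(c) for c in chrom]
        order = sorted(range(len(pos)), key=lambda i: (keys[i], pos[i]))
        if order != list(range(len(pos))):
            raise UnsortedMarkerError("markers are not sorted by (chromosome, position)")
        for c, lo, hi in self.chrom_blocks():
            if np.any(np.diff(pos[lo:hi]) <= 0):
                raise UnsortedMarkerError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        if self.arm is not None:
            arm = np.asarray(self.arm, dtype=object)
            object.__setattr__(self, "arm", arm)
            if len(arm) != len(pos):
                raise GenomeInputError("arm array length mismatch")
            bad = set(arm) - {"p", "q"}
            if bad:
                raise ArmAssignmentError(f"invalid arm labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pos)

    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (chromosome, start, stop) index blocks, stop exclusive."""
        blocks: list[tuple[str, int, int]] = []
        chrom = self.chrom
        i = 0
        n = len(chrom)
        while i < n:
            j = i
            while j < n and chrom[j] == chrom[i]:
                j += 1
            blocks.append((str(chrom[i]), i, j))
            i = j
        return blocks

    def chrom_bounds(self, marker: int) -> tuple[int, int]:
        """(start, stop) index block of the chromosome holding ``marker``."""
        for _, lo, hi in self.chrom_blocks():
            if lo <= marker < hi:
                return lo, hi
        raise IndexError(marker)

    def chrom_lengths(self) -> dict[str, int]:
        """Chromosome length in bp, taken as the last marker position."""
        return {c: int(self.pos[hi - 1]) for c, lo, hi in self.chrom_blocks()}


@dataclass(frozen=True)
class SegmentSet:
    """Segmented copy-number records (sample, chromosome, start, end, value).

    Coordinates are 1-based inclusive; segments of one sample on one
    chromosome must not overlap.
    """

    records: pd.DataFrame  # columns: sample, chrom, start, end, value [, num_markers]

    def __post_init__(self) -> None:
        df = self.records
        required = ["sample", "chrom", "start", "end", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise GenomeInputError(f"segment table missing columns {missing}")
        if np.any(df["start"].to_numpy() > df["end"].to_numpy()):
            bad = df[df["start"] > df["end"]].iloc[0]
            raise GenomeInputError(
                f"segment start > end for sample {bad['sample']!r} "
                f"chrom {bad['chrom']} [{bad['start']}, {bad['end']}]"
            )
        for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
            g = grp.sort_values("start")
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            clash = np.flatnonzero(starts[1:] <= ends[:-1])
            if clash.size:
                k = clash[0]
                raise OverlappingSegmentError(
                    f"overlapping segments for sample {sample!r} on chromosome "
                    f"{chrom}: [{starts[k]}, {ends[k]}] and "
                    f"[{starts[k + 1]}, {ends[k + 1]}]"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CopyNumberMatrix:
    """Markers x samples segmented log2-ratio values on a :class:`MarkerGrid`.

    Missing entries are NaN — explicitly flagged, never silently zero.  They
    contribute 0 to G-score sums and are excluded from arm medians.
    """

    values: np.ndarray
    grid: MarkerGrid
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        if values.ndim != 2:
            raise GenomeInputError("copy-number values must be a 2-D array")
        if values.shape[0] != len(self.grid):
            raise GenomeInputError(
                f"row count {values.shape[0]} does not match grid length {len(self.grid)}"
            )
        if values.shape[1] != len(self.samples):
            raise GenomeInputError("column count does not match sample ids")

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneTable:
    """Gene locations: symbol, chromosome, start, end (1-based inclusive)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = ["symbol", "chrom", "start", "end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise GenomeInputError(f"gene table missing columns {missing}")
        if np.any(df["start"].to_numpy() > df["end"].to_numpy()):
            bad = df[df["start"] > df["end"]].iloc[0]
            raise GenomeInputError(f"gene {bad['symbol']!r} has start > end")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ArmTable:
    """Chromosome-arm intervals: chromosome, arm (p|q), start, end."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = ["chrom", "arm", "start", "end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise GenomeInputError(f"arm table missing columns {missing}")
        bad_arm = set(df["arm"]) - {"p", "q"}
        if bad_arm:
            raise GenomeInputError(f"arm labels must be p or q, got {sorted(bad_arm)}")
        if np.any(df["start"].to_numpy() > df["end"].to_numpy()):
            raise GenomeInputError("arm interval with start > end")
        for chrom, grp in df.groupby("chrom", sort=False):
            if grp["arm"].duplicated().any():
                raise GenomeInputError(f"chromosome {chrom} defines an arm twice")
            if set(grp["arm"]) == {"p", "q"}:
                p = grp[grp["arm"] == "p"].iloc[0]
                q = grp[grp["arm"] == "q"].iloc[0]
                if not (p["end"] < q["start"]):
                    raise GenomeInputError(
                        f"p and q intervals of chromosome {chrom} are not "
                        "disjoint and ordered"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def intervals(self, chrom: str) -> list[tuple[str, int, int]]:
        grp = self.records[self.records["chrom"] == chrom]
        return [(r["arm"], int(r["start"]), int(r["end"])) for _, r in grp.iterrows()]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_marker_matrix(path: str | Path, on_unsorted: str = "sort") -> CopyNumberMatrix:
    """Read a tab-delimited marker-level copy-number matrix.

    The file has a header row; the first three columns are marker id,
    chromosome and position, remaining columns are one sample each.
    Non-numeric cells (``NA``, blanks, ...) become missing entries.

    Parameters
    ----------
    on_unsorted:
        ``"sort"`` (default) re-orders out-of-order markers with a warning;
        ``"error"`` raises :class:`UnsortedMarkerError` instead.
    """
    if on_unsorted not in ("sort", "error"):
        raise ValueError("on_unsorted must be 'sort' or 'error'")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    if df.shape[1] < 4:
        raise GenomeInputError(
            f"{path}: need marker/chrom/pos plus at least one sample column"
        )
    names = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    chrom = np.array([normalize_chrom(c) for c in df.iloc[:, 1]], dtype=object)
    pos = pd.to_numeric(df.iloc[:, 2], errors="raise").to_numpy(dtype=np.int64)
    samples = [str(c) for c in df.columns[3:]]
    values = df.iloc[:, 3:].apply(pd.to_numeric, errors="coerce").to_numpy(np.float64)

    uniq, counts = np.unique(names, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise DuplicateMarkerError(f"{path}: duplicate marker id {dup!r}")

    keep = np.array([not _is_mito(c) for c in chrom])
    if not keep.all():
        logger.info("dropping %d mitochondrial markers", int((~keep).sum()))
        names, chrom, pos, values = names[keep], chrom[keep], pos[keep], values[keep]

    keys = [chrom_sort_key(c) for c in chrom]
    order = sorted(range(len(pos)), key=lambda i: (keys[i], pos[i]))
    if order != list(range(len(pos))):
        if on_unsorted == "error":
            raise UnsortedMarkerError(f"{path}: markers are not positionally sorted")
        logger.warning("%s: markers were not sorted; auto-sorting", path)
        order = np.asarray(order)
        names, chrom, pos, values = names[order], chrom[order], pos[order], values[order]

    grid = MarkerGrid(names=names, chrom=chrom, pos=pos)
    return CopyNumberMatrix(values=values, grid=grid, samples=tuple(samples))


def write_marker_matrix(matrix: CopyNumberMatrix, path: str | Path) -> None:
    """Write a matrix in the tab-delimited marker format (round-trips)."""
    g = matrix.grid
    df = pd.DataFrame({"marker": g.names, "chrom": g.chrom, "pos": g.pos})
    for j, s in enumerate(matrix.samples):
        df[s] = matrix.values[:, j]
    # default float formatting is the shortest round-tripping repr
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


_SEG_COLS5 = ["sample", "chrom", "start", "end", "value"]
_SEG_COLS6 = ["sample", "chrom", "start", "end", "num_markers", "value"]


def read_seg(path: str | Path) -> SegmentSet:
    """Read a SEG file (header optional, 5- or 6-column dialect)."""
    head = pd.read_csv(path, sep="\t", header=None, nrows=1)
    try:
        float(head.iloc[0, 2])
        header = None
    except (TypeError, ValueError):
        header = 0
    df = pd.read_csv(path, sep="\t", header=header)
    if df.shape[1] == 5:
        df.columns = _SEG_COLS5
    elif df.shape[1] == 6:
        df.columns = _SEG_COLS6
    else:
        raise GenomeInputError(f"{path}: SEG files have 5 or 6 columns, got {df.shape[1]}")
    df["sample"] = df["sample"].astype(str)
    df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    df["start"] = pd.to_numeric(df["start"]).astype(np.int64)
    df["end"] = pd.to_numeric(df["end"]).astype(np.int64)
    df["value"] = pd.to_numeric(df["value"]).astype(np.float64)
    n0 = len(df)
    df = df[~df["chrom"].map(_is_mito)].reset_index(drop=True)
    if len(df) < n0:
        logger.info("dropping %d mitochondrial segments", n0 - len(df))
    return SegmentSet(records=df)


def project_segments(segs: SegmentSet, grid: MarkerGrid) -> CopyNumberMatrix:
    """Assign each marker the value of the segment containing its position.

    Containment uses 1-based inclusive ``[start, end]``.  Markers covered by
    no segment for a sample are missing for that sample.
    """
    samples = tuple(dict.fromkeys(segs.records["sample"]))
    values = np.full((len(grid), len(samples)), np.nan)
    col = {s: j for j, s in enumerate(samples)}
    blocks = {c: (lo, hi) for c, lo, hi in grid.chrom_blocks()}
    for _, seg in segs.records.iterrows():
        c = seg["chrom"]
        if c not in blocks:
            continue
        lo, hi = blocks[c]
        pos = grid.pos[lo:hi]
        i0 = int(np.searchsorted(pos, seg["start"], side="left"))
        i1 = int(np.searchsorted(pos, seg["end"], side="right"))
        values[lo + i0 : lo + i1, col[seg["sample"]]] = seg["value"]
    return CopyNumberMatrix(values=values, grid=grid, samples=samples)


def segments_from_matrix(matrix: CopyNumberMatrix) -> SegmentSet:
    """Collapse a marker matrix into runs of constant value per sample.

    Inverse-ish of :func:`project_segments`: projecting the result back onto
    the same grid reproduces the matrix on covered (non-missing) markers.
    """
    g = matrix.grid
    rows = []
    for j, s in enumerate(matrix.samples):
        v = matrix.values[:, j]
        for c, lo, hi in g.chrom_blocks():
            i = lo
            while i < hi:
                if np.isnan(v[i]):
                    i += 1
                    continue
                k = i
                while k + 1 < hi and v[k + 1] == v[i]:
                    k += 1
                rows.append(
                    (s, c, int(g.pos[i]), int(g.pos[k]), k - i + 1, float(v[i]))
                )
                i = k + 1
    df = pd.DataFrame(rows, columns=_SEG_COLS6)
    return SegmentSet(records=df)


def _read_table(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = [str(c).strip().lower() for c in df.columns]
    alias = {"chromosome": "chrom", "gene": "symbol", "name": "symbol"}
    df = df.rename(columns=alias)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GenomeInputError(f"{path}: {label} table missing columns {missing}")
    df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    df["start"] = pd.to_numeric(df["start"]).astype(np.int64)
    df["end"] = pd.to_numeric(df["end"]).astype(np.int64)
    return df


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a tab-delimited gene-location table (symbol, chrom, start, end)."""
    df = _read_table(path, ["symbol", "chrom", "start", "end"], "gene")
    df["symbol"] = df["symbol"].astype(str)
    return GeneTable(records=df[["symbol", "chrom", "start", "end"]])


def read_arm_table(path: str | Path) -> ArmTable:
    """Read a tab-delimited chromosome-arm table (chrom, arm, start, end)."""
    df = _read_table(path, ["chrom", "arm", "start", "end"], "arm")
    df["arm"] = df["arm"].astype(str).str.strip().str.lower()
    return ArmTable(records=df[["chrom", "arm", "start", "end"]])


def assign_arms(matrix: CopyNumberMatrix, arms: ArmTable) -> CopyNumberMatrix:
    """Resolve each marker to a chromosome arm.

    Markers on a chromosome with no arm definition raise
    :class:`ArmAssignmentError`; markers falling in neither the p nor the q
    interval (centromere gaps) are dropped with a logged count, so that arm
    medians stay well defined.
    """
    g = matrix.grid
    arm_labels = np.empty(len(g), dtype=object)
    keep = np.ones(len(g), dtype=bool)
    for c, lo, hi in g.chrom_blocks():
        ivals = arms.intervals(c)
        if not ivals:
            raise ArmAssignmentError(f"chromosome {c} has no arm definition")
        pos = g.pos[lo:hi]
        assigned = np.zeros(hi - lo, dtype=bool)
        for arm, start, end in ivals:
            inside = (pos >= start) & (pos <= end)
            arm_labels[lo:hi][inside] = arm
            assigned |= inside
        keep[lo:hi] = assigned
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d markers outside arm intervals (centromere gaps)", n_drop)
    grid = MarkerGrid(
        names=g.names[keep], chrom=g.chrom[keep], pos=g.pos[keep], arm=arm_labels[keep]
    )
    return CopyNumberMatrix(values=matrix.values[keep], grid=grid, samples=matrix.samples)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_REPORT_COLS = [
    "direction", "chrom", "start", "end", "span", "q_value", "n_markers", "order",
    "variant", "genes",
]


def write_peak_report(
    peaks: Iterable["PeakRegion"],
    genes: GeneTable | None,
    path: str | Path,
    grid: MarkerGrid | None = None,
) -> None:
    """Write a tab-delimited peak report, one row per peak.

    Columns: direction, chromosome, genomic span (1-based inclusive), a
    cytogenetic-style span string (``start-end (chrom arm)`` when the grid
    carries arm labels), the q-value at the peak, and the symbols of contained
    genes (>= 1 bp overlap), comma-separated.
    """
    from .annotate import genes_in_peak  # local import to avoid a cycle

    rows = []
    for pk in peaks:
        if grid is not None and grid.arm is not None:
            span = f"{pk.start}-{pk.end} ({pk.chrom}{grid.arm[pk.peak_marker]})"
        else:
            span = f"{pk.start}-{pk.end} ({pk.chrom})"
        symbols = genes_in_peak(pk, genes) if genes is not None else []
        rows.append(
            (
                pk.direction, pk.chrom, pk.start, pk.end, span,
                f"{pk.q_value:.6g}", pk.last - pk.first + 1, pk.order,
                pk.variant, ",".join(symbols),
            )
        )
    df = pd.DataFrame(rows, columns=_REPORT_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_peak_report(path: str | Path) -> pd.DataFrame:
    """Read back a peak report written by :func:`write_peak_report`."""
    df = pd.read_csv(path, sep="\t", header=0, keep_default_na=False)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["q_value"] = df["q_value"].astype(float)
    return df


def write_igv_tracks(
    gscore,
    peaks: Iterable["PeakRegion"],
    grid: MarkerGrid,
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Emit a per-marker G-score ``.igv`` track and a BED track of peaks.

    The ``.igv`` file carries one marker per row (chrom, start, end, feature,
    value).  The BED file uses 0-based half-open coordinates; a 1-based
    inclusive span ``[s, e]`` becomes ``s-1, e``.
    """
    prefix = Path(path_prefix)
    igv_path = prefix.with_suffix(".igv")
    bed_path = prefix.with_suffix(".bed")
    scores = np.asarray(getattr(gscore, "scores", gscore), dtype=float)
    name = getattr(gscore, "direction", "gscore")
    with open(igv_path, "w") as fh:
        fh.write(f"Chromosome\tStart\tEnd\tFeature\tG_{name}\n")
        for m in range(len(grid)):
            fh.write(
                f"{grid.chrom[m]}\t{grid.pos[m] - 1}\t{grid.pos[m]}"
                f"\t{grid.names[m]}\t{scores[m]:.6g}\n"
            )
    with open(bed_path, "w") as fh:
        fh.write(f'track name="peaks_{name}" description="peak regions"\n')
        for pk in peaks:
            fh.write(f"{pk.chrom}\t{pk.start - 1}\t{pk.end}\tpeak_{pk.order}\t0\n")
    return igv_path, bed_path
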