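"""Seeded synthetic cohorts with known ground truth.

Cohorts are log2-ratio marker matrices: per-sample baseline 0 plus Gaussian
marker noise, with planted aberrations added on top.  A planted event is a
(chromosome, marker span, amplitude, sample fraction, direction) tuple; the
carrier subset is drawn by the seeded generator.  Broad events (at least
half a chromosome arm) exercise the focal thresholds and arm peel-off;
short high-amplitude events play the role of focal driver aberrations.

Two noise regimes exist because the persistence parameter ``s`` exists to
absorb transient fluctuations: the default is iid marker noise; the
segment-noise mode draws one noise value per random segment (geometric
segment lengths), emulating segmentation output whose steps are spurious.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import ArmTable, CopyNumberMatrix, MarkerGrid

__all__ = [
    "PlantedEvent",
    "SimSpec",
    "SimulationError",
    "build_grid",
    "arm_table_for",
    "simulate",
    "random_cohort_spec",
    "two_peak_fixture",
]


class SimulationError(ValueError):
    """Inconsistent simulation specification."""


@dataclass(frozen=True)
class PlantedEvent:
    """One planted aberration; ``start``/``end`` are chromosome-local marker
    indices (0-based, inclusive) and ``amplitude`` is a positive log2-ratio
    magnitude (negated internally for deletions)."""

    chrom: str
    start: int
    end: int
    amplitude: float
    fraction: float
    direction: str = "amp"

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 0:
            raise SimulationError("event span is empty or negative")
        if not (0.0 <= self.fraction <= 1.0):
            raise SimulationError("sample fraction must lie in [0, 1]")
        if self.amplitude <= 0:
            raise SimulationError("amplitude must be a positive magnitude")
        if self.direction not in ("amp", "del"):
            raise SimulationError("direction must be 'amp' or 'del'")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic cohort."""

    n_chromosomes: int = 4
    markers_per_chrom: int = 250
    n_samples: int = 20
    noise_sd: float = 0.1
    events: tuple[PlantedEvent, ...] = ()
    seed: int = 0
    marker_spacing: int = 10_000  # bp between adjacent markers
    segment_noise: bool = False
    segment_mean_len: int = 8  # mean segment length (markers) in segment mode

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.markers_per_chrom < 2:
            raise SimulationError("need >= 1 chromosome with >= 2 markers")
        if self.n_samples < 1:
            raise SimulationError("need >= 1 sample")
        if self.noise_sd < 0:
            raise SimulationError("noise SD must be >= 0")
        chroms = {str(c + 1) for c in range(self.n_chromosomes)}
        for ev in self.events:
            if ev.chrom not in chroms:
                raise SimulationError(f"event on unknown chromosome {ev.chrom!r}")
            if ev.end >= self.markers_per_chrom:
                raise SimulationError("event span exceeds chromosome bounds")


def build_grid(spec: SimSpec) -> MarkerGrid:
    """Evenly spaced markers on chromosomes named "1".."K"."""
    names, chroms, pos = [], [], []
    for c in range(spec.n_chromosomes):
        for m in range(spec.markers_per_chrom):
            names.append(f"mk_{c + 1}_{m}")
            chroms.append(str(c + 1))
            pos.append(1 + m * spec.marker_spacing)
    return MarkerGrid(
        names=np.array(names, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
    )


def arm_table_for(spec: SimSpec) -> ArmTable:
    """Arm table splitting each chromosome at its middle marker."""
    mid = spec.markers_per_chrom // 2
    rows = []
    for c in range(spec.n_chromosomes):
        chrom = str(c + 1)
        p_end = 1 + (mid - 1) * spec.marker_spacing
        q_start = 1 + mid * spec.marker_spacing
        q_end = 1 + (spec.markers_per_chrom - 1) * spec.marker_spacing
        rows.append((chrom, "p", 1, p_end))
        rows.append((chrom, "q", q_start, q_end))
    return ArmTable(
        records=pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])
    )


def simulate(
    spec: SimSpec,
) -> tuple[CopyNumberMatrix, list[tuple[PlantedEvent, np.ndarray]]]:
    """Generate a cohort; returns the matrix and (event, carrier indices) truth.

    Deterministic given the spec (which includes the seed).  Each event adds
    its signed amplitude over its span to ``ceil(fraction * N)`` samples
    drawn without replacement.  Overlapping events of opposite direction in
    one sample are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    grid = build_grid(spec)
    m_total = len(grid)
    n = spec.n_samples

    if spec.segment_noise:
        values = np.zeros((m_total, n))
        p_break = 1.0 / max(1, spec.segment_mean_len)
        for j in range(n):
            for _, lo, hi in grid.chrom_blocks():
                i = lo
                while i < hi:
                    length = int(rng.geometric(p_break))
                    k = min(hi, i + length)
                    values[i:k, j] = rng.normal(0.0, spec.noise_sd)
                    i = k
    else:
        values = rng.normal(0.0, spec.noise_sd, size=(m_total, n))

    offsets = {c: lo for c, lo, hi in grid.chrom_blocks()}
    truth: list[tuple[PlantedEvent, np.ndarray]] = []
    signed = np.zeros((m_total, n))  # planted signal only, for overlap checks
    for ev in spec.events:
        n_carriers = math.ceil(ev.fraction * n)
        carriers = np.sort(rng.choice(n, size=n_carriers, replace=False))
        lo = offsets[ev.chrom]
        rows = slice(lo + ev.start, lo + ev.end + 1)
        amp = ev.amplitude if ev.direction == "amp" else -ev.amplitude
        prev = signed[rows][:, carriers]
        if np.any(prev * amp < 0):
            raise SimulationError(
                f"event on chromosome {ev.chrom} overlaps an opposite-direction "
                "event in at least one sample"
            )
        for j in carriers:
            signed[rows, j] += amp
        truth.append((ev, carriers))
    values += signed
    matrix = CopyNumberMatrix(values=values, grid=grid, samples=tuple(
        f"S{j:03d}" for j in range(n)
    ))
    return matrix, truth


def random_cohort_spec(seed: int, n_samples: int = 20) -> SimSpec:
    """A randomized cohort with broad and focal events on separate chromosomes.

    Four 250-marker chromosomes: amplification events live on chromosomes 1-2
    (one broad q-arm gain with an embedded focal sub-peak, plus a lone focal
    gain), deletions mirror them on chromosomes 3-4, so opposite directions
    never collide in one sample.  Frequencies, spans and amplitudes are drawn
    by the seeded generator within ranges typical of tumor cohorts.
    """
    rng = np.random.default_rng(seed)
    m = 250
    events = []
    for chrom, direction in (("1", "amp"), ("3", "del")):
        b_start = int(rng.integers(130, 150))
        b_end = min(m - 1, b_start + int(rng.integers(85, 115)))
        events.append(PlantedEvent(
            chrom=chrom, start=b_start, end=b_end,
            amplitude=float(rng.uniform(0.35, 0.5)),
            fraction=float(rng.uniform(0.3, 0.5)), direction=direction,
        ))
        f_start = int(rng.integers(b_start + 10, b_end - 30))
        events.append(PlantedEvent(
            chrom=chrom, start=f_start, end=f_start + int(rng.integers(8, 18)),
            amplitude=float(rng.uniform(0.9, 1.2)),
            fraction=float(rng.uniform(0.2, 0.4)), direction=direction,
        ))
    for chrom, direction in (("2", "amp"), ("4", "del")):
        f_start = int(rng.integers(20, 200))
        events.append(PlantedEvent(
            chrom=chrom, start=f_start, end=f_start + int(rng.integers(8, 18)),
            amplitude=float(rng.uniform(0.9, 1.2)),
            fraction=float(rng.uniform(0.2, 0.4)), direction=direction,
        ))
    return SimSpec(
        n_chromosomes=4, markers_per_chrom=m, n_samples=n_samples,
        noise_sd=0.1, events=tuple(events), seed=int(seed),
    )


# chromosome-local marker spans of the two planted sub-peaks (0-based incl.)
_TP_BROAD = (54, 94)
_TP_PEAK_A = (59, 63)
_TP_PEAK_B = (74, 78)


def two_peak_fixture(
    seed: int = 0, decoy_chromosome: bool = False
) -> tuple[CopyNumberMatrix, ArmTable, list[tuple[int, int]]]:
    """Five-sample, single-chromosome cohort with two sub-peaks in one broad gain.

    A broad gain (log2 ratio 0.5) covers most of the q arm in samples 0-3;
    two stronger focal sub-regions sit inside it, separated by a sustained
    dip back to the broad level: peak A (+0.85, samples 0-1) and peak B
    (+0.8, samples 2-3).  Amplitudes make the global q-minimum unique at
    peak A, so the standard variant reports exactly one peak while the
    limited variant aborts the peel at peak B and reports both.  With
    ``decoy_chromosome=True`` a second chromosome carries an unrelated broad
    gain (+0.7, samples 0-1), which must not change the peaks reported on
    the test chromosome.

    Returns (matrix, arm table, ground-truth global marker spans).
    """
    n_chrom = 2 if decoy_chromosome else 1
    events = [
        PlantedEvent("1", *_TP_BROAD, amplitude=0.5, fraction=0.8),
        PlantedEvent("1", *_TP_PEAK_A, amplitude=0.85, fraction=0.4),
        PlantedEvent("1", *_TP_PEAK_B, amplitude=0.8, fraction=0.4),
    ]
    if decoy_chromosome:
        events.append(PlantedEvent("2", 55, 95, amplitude=0.7, fraction=0.4))
    spec = SimSpec(
        n_chromosomes=n_chrom, markers_per_chrom=100, n_samples=5,
        noise_sd=0.0, events=tuple(events), seed=int(seed),
    )
    # carriers must be deterministic (samples 0-3 broad, 0-1 / 2-3 sub-peaks):
    # plant by hand instead of relying on the rng's choice
    matrix, _ = simulate(replace(spec, events=()))
    values = matrix.values
    b0, b1 = _TP_BROAD
    a0, a1 = _TP_PEAK_A
    c0, c1 = _TP_PEAK_B
    values[b0 : b1 + 1, 0:4] += 0.5
    values[a0 : a1 + 1, 0:2] += 0.85
    values[c0 : c1 + 1, 2:4] += 0.8
    if decoy_chromosome:
        values[100 + 55 : 100 + 96, 0:2] += 0.7
    truth = [(a0, a1), (c0, c1)]
    return matrix, arm_table_for(spec), truth
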