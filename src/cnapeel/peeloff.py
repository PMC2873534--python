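"""Iterative peak discovery with four peel-off variants.

The driver loop repeats: score the working contribution grid, convert scores
to p/q-values against a frozen null, report the most significant marker as a
peak, extend its boundaries by leave-one-out, then *peel* the peak's
influence from the grid so independent peaks can surface.  Variants differ
only in the peel step:

* **standard** — for every sample whose aberration includes the peak, zero
  the whole contiguous run of positive contributions containing it;
* **focal** — the standard peel applied to the focal (sample-specific
  threshold) contribution grid;
* **arm** — zero the entire chromosome arm containing the peak for samples
  that include the peak;
* **limited** — the standard zeroing, but truncated: walking outward from
  the peak region, each sample's contribution is decomposed into a component
  still attributable to the peak (``G_r``, a monotone envelope that only
  accepts reductions sustained for at least ``s`` consecutive markers) and a
  peak-independent remainder (``G_n``).  At the first marker where the
  summed ``G_n`` reaches ``G_thres`` the peel aborts on that side, leaving
  everything outward untouched so a later iteration can report it as an
  independent peak.

``G_thres`` is the G-score equivalent of the significance q-threshold,
obtained by inverting the focal-variant null, so the same evidence bar
applies to a peak on baseline copy number and to a sub-peak inside a broad
aberration.  With ``G_thres = +inf`` the abort never fires and the limited
variant reproduces the standard variant peak-for-peak; every standard peak
is likewise captured (overlapped) by the limited variant at any threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import ArmTable, CopyNumberMatrix, MarkerGrid, assign_arms
from .gscore import (
    GScoreTrack,
    ScoreParams,
    compute_focal_gscore,
    compute_gscore,
)
from .significance import (
    ConfigError,
    NullDistribution,
    SignificanceTrack,
    build_null,
    gscore_for_q,
    pvalues,
    qvalues,
)

logger = logging.getLogger("cnapeel")

__all__ = [
    "VARIANTS",
    "PeakRegion",
    "PeelState",
    "ResidualDecomposition",
    "VariantResult",
    "find_peak",
    "extend_peak_loo",
    "standard_peel",
    "focal_peel",
    "arm_peel",
    "limited_residual",
    "limited_peel",
    "run_variant",
]

VARIANTS = ("standard", "focal", "limited", "arm")


@dataclass(frozen=True)
class PeakRegion:
    """A reported driver region.

    Marker indices are global grid indices, inclusive on both ends; ``start``
    and ``end`` are 1-based inclusive base-pair coordinates.
    """

    direction: str
    chrom: str
    first: int
    last: int
    start: int
    end: int
    peak_marker: int
    q_value: float
    order: int
    variant: str

    def overlaps(self, other: "PeakRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.first <= other.last
            and other.first <= self.last
        )


@dataclass
class PeelState:
    """Mutable state of one peel-off run (one direction, one variant)."""

    working: np.ndarray  # (M, N), mutated across iterations
    original: np.ndarray  # immutable reference grid
    grid: MarkerGrid
    samples: tuple[str, ...]
    direction: str
    variant: str
    null: NullDistribution
    q_threshold: float = 0.25
    s: int = 10
    g_thres: float = np.inf
    peel_mode: str = "zero"  # "zero" | "subtract"
    peaks: list[PeakRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ConfigError("persistence parameter s must be >= 0")
        if self.peel_mode not in ("zero", "subtract"):
            raise ConfigError(f"unknown peel_mode {self.peel_mode!r}")


@dataclass(frozen=True)
class ResidualDecomposition:
    """Per-sample split of contributions on one side of a peak region.

    ``g_r[k] + g_n[k]`` equals the working contribution at marker
    ``markers[k]``; ``g_r`` is non-increasing with distance from the peak.
    """

    sample: int
    markers: np.ndarray  # global indices, ordered outward from the region
    g_r: np.ndarray
    g_n: np.ndarray


# ---------------------------------------------------------------------------
# peak finding and boundary extension
# ---------------------------------------------------------------------------

def find_peak(
    q: np.ndarray, scores: np.ndarray, q_threshold: float = 0.25
) -> int | None:
    """Most significant marker, or None when nothing clears the q-threshold.

    Ties on q are broken by maximal G-score, then by smallest genomic
    coordinate (the grid is position-sorted, so smallest index).
    """
    qmin = q.min()
    if qmin >= q_threshold:
        return None
    cand = np.flatnonzero(q == qmin)
    best_g = scores[cand].max()
    return int(cand[scores[cand] == best_g][0])


def _plateau(q: np.ndarray, peak: int, lo: int, hi: int) -> tuple[int, int]:
    """Maximal contiguous run around ``peak`` with q <= q[peak], within [lo, hi)."""
    v = q[peak]
    first = peak
    while first - 1 >= lo and q[first - 1] <= v:
        first -= 1
    last = peak
    while last + 1 < hi and q[last + 1] <= v:
        last += 1
    return first, last


def extend_peak_loo(
    working: np.ndarray,
    peak: int,
    null: NullDistribution,
    grid: MarkerGrid,
    q_at_peak: float,
    direction: str,
    order: int,
    variant: str,
    q_threshold: float = 0.25,
) -> PeakRegion:
    """Extend peak boundaries by leaving each sample out in turn.

    For each left-out sample the G-score and q-values are recomputed (against
    the same frozen null) and the contiguous region around the peak attaining
    the left-out minimal q is taken; the reported region is the union of the
    leave-one-out regions and the all-samples region.  Leave-outs that erase
    the peak's significance altogether (left-out q at the peak at or above
    the q-threshold, as when the left-out sample alone defined the peak in a
    tiny cohort) carry no boundary information and are skipped with a log
    message.
    """
    lo, hi = grid.chrom_bounds(peak)
    scores = working.sum(axis=1)
    q_all = qvalues(pvalues(scores, null))
    first, last = _plateau(q_all, peak, lo, hi)
    n_samples = working.shape[1]
    if n_samples > 1:
        for j in range(n_samples):
            s_j = scores - working[:, j]
            q_j = qvalues(pvalues(s_j, null))
            if s_j[peak] <= 0 or q_j[peak] >= q_threshold:
                logger.debug(
                    "leave-one-out of sample %d erases the peak at marker %d; skipped",
                    j, peak,
                )
                continue
            f, l = _plateau(q_j, peak, lo, hi)
            first = min(first, f)
            last = max(last, l)
    else:
        logger.debug("single-sample cohort: region is the all-samples plateau")
    return PeakRegion(
        direction=direction,
        chrom=str(grid.chrom[peak]),
        first=first,
        last=last,
        start=int(grid.pos[first]),
        end=int(grid.pos[last]),
        peak_marker=peak,
        q_value=float(q_at_peak),
        order=order,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# peel steps
# ---------------------------------------------------------------------------

def _run_bounds(col: np.ndarray, m: int, lo: int, hi: int) -> tuple[int, int]:
    """Inclusive bounds of the maximal run of positive values containing m."""
    a = m
    while a - 1 >= lo and col[a - 1] > 0:
        a -= 1
    b = m
    while b + 1 < hi and col[b + 1] > 0:
        b += 1
    return a, b


def standard_peel(state: PeelState, region: PeakRegion) -> PeelState:
    """Zero, per included sample, the contiguous aberration containing the peak.

    A sample is included when its contribution at the peak marker is
    positive; other samples — including samples aberrant elsewhere on the
    chromosome — are untouched.
    """
    pm = region.peak_marker
    lo, hi = state.grid.chrom_bounds(pm)
    for j in np.flatnonzero(state.working[pm] > 0):
        a, b = _run_bounds(state.working[:, j], pm, lo, hi)
        state.working[a : b + 1, j] = 0.0
    return state


def focal_peel(state: PeelState, region: PeakRegion) -> PeelState:
    """Standard peel on the focal contribution grid (held by the state)."""
    return standard_peel(state, region)


def arm_peel(state: PeelState, region: PeakRegion) -> PeelState:
    """Zero the whole chromosome arm containing the peak for included samples."""
    pm = region.peak_marker
    if state.grid.arm is None:
        raise ConfigError("arm peel-off requires arm-annotated markers")
    lo, hi = state.grid.chrom_bounds(pm)
    arm = state.grid.arm[pm]
    rows = np.flatnonzero(state.grid.arm[lo:hi] == arm) + lo
    cols = np.flatnonzero(state.working[pm] > 0)
    state.working[np.ix_(rows, cols)] = 0.0
    return state


def _gr_envelope(g: np.ndarray, s: int) -> np.ndarray:
    """Peak-attributable component along one side of a run, walking outward.

    ``g[0]`` is the contribution at the region edge.  A reduction is accepted
    only if sustained for at least ``s`` markers: the envelope is the running
    minimum of the forward-looking windowed maximum,

        G_r[0] = g[0];  G_r[k] = min(G_r[k-1], max(g[k : k+s]))

    with a window of ``max(s, 1)`` markers including the current one (s = 0
    and s = 1 both accept instantaneous dips), truncated at the run end.
    """
    if s < 0:
        raise ConfigError("persistence parameter s must be >= 0")
    n = len(g)
    if n == 0:
        return np.empty(0)
    k = max(int(s), 1)
    padded = np.pad(g.astype(np.float64), (0, k - 1), constant_values=-np.inf)
    wmax = sliding_window_view(padded, k).max(axis=1)
    return np.minimum.accumulate(np.concatenate([g[:1], wmax[1:]]))


def _side_decomposition(
    working: np.ndarray,
    region: PeakRegion,
    side: str,
    s: int,
    lo: int,
    hi: int,
):
    """Per-sample G_r over one side of the region, plus the summed G_n.

    Returns (markers, g_r_by_sample, gn_sum): ``markers`` runs outward from
    the region edge (inclusive); ``g_r_by_sample`` maps carrier sample ->
    G_r array aligned to ``markers``; ``gn_sum[k]`` sums ``G_n`` over *all*
    samples at ``markers[k]`` (non-carriers contribute their full value,
    none of which is attributable to the peak).
    """
    pm = region.peak_marker
    if side == "right":
        m0 = region.last
        markers = np.arange(m0, hi)
    elif side == "left":
        m0 = region.first
        markers = np.arange(m0, lo - 1, -1)
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    n_samples = working.shape[1]
    carriers = np.flatnonzero(working[pm] > 0)
    g_r_by_sample: dict[int, np.ndarray] = {}
    gn_sum = np.zeros(len(markers))
    carrier_mask = np.zeros(n_samples, dtype=bool)
    carrier_mask[carriers] = True
    for j in carriers:
        a, b = _run_bounds(working[:, j], pm, lo, hi)
        if side == "right":
            run_len = b - m0 + 1
        else:
            run_len = m0 - a + 1
        seg = working[markers[:run_len], j]
        env = _gr_envelope(seg, s)
        g_r = np.zeros(len(markers))
        g_r[:run_len] = env
        g_r_by_sample[int(j)] = g_r
        gn_sum += np.maximum(0.0, working[markers, j] - g_r)
    if not carrier_mask.all():
        gn_sum += working[np.ix_(markers, np.flatnonzero(~carrier_mask))].sum(axis=1)
    return markers, g_r_by_sample, gn_sum


def limited_residual(
    state: PeelState, region: PeakRegion, sample: int, side: str = "right"
) -> ResidualDecomposition:
    """G_r / G_n decomposition for one sample on one side of a peak region.

    The sample's run must contain the peak (positive contribution at the
    peak marker).
    """
    pm = region.peak_marker
    if state.working[pm, sample] <= 0:
        raise ValueError(f"sample {sample} does not carry the peak at marker {pm}")
    lo, hi = state.grid.chrom_bounds(pm)
    markers, g_r_by_sample, _ = _side_decomposition(
        state.working, region, side, state.s, lo, hi
    )
    g_r = g_r_by_sample[int(sample)]
    g_n = np.maximum(0.0, state.working[markers, sample] - g_r)
    return ResidualDecomposition(sample=int(sample), markers=markers, g_r=g_r, g_n=g_n)


def limited_peel(state: PeelState, region: PeakRegion) -> PeelState:
    """Peel the peak, aborting on each side where independent signal remains.

    On each side the first marker ``m`` (walking outward from the region
    edge) with ``sum_i G_n(m, i) >= G_thres`` aborts the peel: markers from
    ``m`` outward keep their current contributions.  Inward of the abort the
    default mode zeroes each carrier's run (exactly the standard peel,
    truncated); ``peel_mode="subtract"`` instead removes only the
    peak-attributable component ``G_r``.  The peak region itself is always
    cleared for carrier samples.  With no abort anywhere the result is
    identical to :func:`standard_peel`.
    """
    pm = region.peak_marker
    lo, hi = state.grid.chrom_bounds(pm)
    working = state.working
    carriers = np.flatnonzero(working[pm] > 0)
    runs = {int(j): _run_bounds(working[:, j], pm, lo, hi) for j in carriers}

    # decide both abort points on the pre-peel snapshot, then mutate
    plans = []
    for side in ("right", "left"):
        markers, g_r_by_sample, gn_sum = _side_decomposition(
            working, region, side, state.s, lo, hi
        )
        hit = np.flatnonzero(gn_sum >= state.g_thres)
        n_peel = int(hit[0]) if hit.size else len(markers)
        if hit.size:
            logger.debug(
                "%s side of peak at %d: abort at marker %d (sum G_n=%.4g >= %.4g)",
                side, pm, int(markers[hit[0]]), gn_sum[hit[0]], state.g_thres,
            )
        plans.append((side, markers, g_r_by_sample, n_peel))

    for side, markers, g_r_by_sample, n_peel in plans:
        peeled = markers[:n_peel]
        for j, (a, b) in runs.items():
            if state.peel_mode == "subtract":
                g_r = g_r_by_sample[j][:n_peel]
                working[peeled, j] = np.maximum(0.0, working[peeled, j] - g_r)
            else:
                inside = peeled[(peeled >= a) & (peeled <= b)]
                working[inside, j] = 0.0
    # the region itself is always removed for carrier samples
    rows = np.arange(region.first, region.last + 1)
    working[np.ix_(rows, carriers)] = 0.0
    return state


_PEEL = {
    "standard": standard_peel,
    "focal": focal_peel,
    "arm": arm_peel,
    "limited": limited_peel,
}


# ---------------------------------------------------------------------------
# driver loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantResult:
    """Everything one peel-off run produced, for reporting and diagnostics."""

    peaks: list[PeakRegion]
    gscore: GScoreTrack
    significance: SignificanceTrack
    null: NullDistribution
    g_thres: float
    variant: str
    direction: str

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def run_variant(
    matrix: CopyNumberMatrix,
    arms: ArmTable,
    params: ScoreParams,
    variant: str = "standard",
    q_threshold: float = 0.25,
    s: int = 10,
    g_thres: float | None = None,
    null_method: str = "convolution",
    n_bins: int = 10_000,
    n_perm: int = 10_000,
    seed: int | None = None,
    peel_mode: str = "zero",
) -> VariantResult:
    """Run the full iterative analysis for one direction and one variant.

    Each iteration recomputes G-scores from the working grid and q-values
    against the null built once from the initial grid (the null models the
    chance aberration background; rebuilding it after deleting signal would
    bias it).  For the limited variant, ``g_thres`` defaults to the G-score
    threshold equivalent to ``q_threshold`` under the focal-variant null.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if matrix.grid.arm is None:
        matrix = assign_arms(matrix, arms)

    if variant == "focal":
        track = compute_focal_gscore(matrix, arms, params)
    else:
        track = compute_gscore(matrix, params)
    null = build_null(
        track.contributions, method=null_method, n_bins=n_bins,
        n_perm=n_perm, seed=seed,
    )

    if variant == "limited" and g_thres is None:
        focal_track = compute_focal_gscore(matrix, arms, params)
        focal_null = build_null(
            focal_track.contributions, method=null_method, n_bins=n_bins,
            n_perm=n_perm, seed=None if seed is None else seed + 1,
        )
        if focal_null.degenerate:
            logger.info(
                "focal null is degenerate (no focal aberration anywhere); "
                "limited peel-off will never abort"
            )
            g_thres = np.inf
        else:
            g_thres = gscore_for_q(q_threshold, focal_null, matrix.n_markers)
    if g_thres is None:
        g_thres = np.inf

    state = PeelState(
        working=track.contributions.copy(),
        original=track.contributions,
        grid=matrix.grid,
        samples=matrix.samples,
        direction=params.direction,
        variant=variant,
        null=null,
        q_threshold=q_threshold,
        s=s,
        g_thres=float(g_thres),
        peel_mode=peel_mode,
    )
    peel = _PEEL[variant]

    p0 = pvalues(track.scores, null)
    sig0 = SignificanceTrack(
        direction=params.direction, p=p0, q=qvalues(p0), q_threshold=q_threshold
    )

    iteration = 0
    while True:
        scores = state.working.sum(axis=1)
        p = pvalues(scores, null)
        q = qvalues(p)
        peak = find_peak(q, scores, q_threshold)
        if peak is None:
            break
        iteration += 1
        if iteration > matrix.n_markers:
            raise RuntimeError(
                "peel-off failed to terminate: more iterations than markers"
            )
        region = extend_peak_loo(
            state.working, peak, null, matrix.grid,
            q_at_peak=q[peak], direction=params.direction,
            order=iteration, variant=variant, q_threshold=q_threshold,
        )
        logger.info(
            "[%s/%s] iter %d: peak at marker %d (chr%s:%d-%d), G=%.4g q=%.3g",
            params.direction, variant, iteration, peak, region.chrom,
            region.start, region.end, scores[peak], q[peak],
        )
        peel(state, region)
        # the peel must remove the peak's contributions, or the loop cannot end
        assert state.working[peak].sum() == 0.0
        state.peaks.append(region)

    return VariantResult(
        peaks=state.peaks, gscore=track, significance=sig0, null=null,
        g_thres=float(g_thres), variant=variant, direction=params.direction,
    )
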