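"""Per-marker G-scores for amplification and deletion.

The G-score of a marker is the sum over samples of its copy-number value,
with sub-threshold samples set to zero:

    G_amp(m) = sum_i CN(m, i) * I[CN(m, i) >= theta_amp]
    G_del(m) = sum_i -CN(m, i) * I[CN(m, i) <= -theta_del]

so the statistic combines magnitude and frequency of the aberration.  The
threshold boundary is inclusive: a value exactly at the threshold counts as
aberrant.  Missing entries contribute 0.

The standard variant uses one fixed threshold per direction.  The focal
variant replaces it by a sample-specific high-level threshold: the standard
threshold plus the largest (for deletions, the most negative) chromosome-arm
median of that sample, so contributions riding on top of a broad (arm-scale)
event must exceed the broad level to count.  The focal threshold is never
laxer than the standard one, hence focal G-scores are bounded above by
standard G-scores marker-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .genome_io import ArmTable, CopyNumberMatrix, MarkerGrid, assign_arms

__all__ = [
    "Direction",
    "ScoreParams",
    "GScoreTrack",
    "FocalThresholds",
    "contribution",
    "compute_gscore",
    "focal_thresholds",
    "compute_focal_gscore",
]

Direction = Literal["amp", "del"]


@dataclass(frozen=True)
class ScoreParams:
    """Aberration thresholds (log2-ratio units, strictly positive)."""

    direction: Direction = "amp"
    theta_amp: float = 0.1
    theta_del: float = 0.1

    def __post_init__(self) -> None:
        if self.direction not in ("amp", "del"):
            raise ValueError(f"direction must be 'amp' or 'del', got {self.direction!r}")
        if self.theta_amp <= 0 or self.theta_del <= 0:
            raise ValueError("thresholds must be strictly positive")

    @property
    def theta(self) -> float:
        """The threshold magnitude for the active direction."""
        return self.theta_amp if self.direction == "amp" else self.theta_del


@dataclass(frozen=True)
class GScoreTrack:
    """Per-marker G-scores plus the per-(marker, sample) contribution grid.

    ``scores[m] == contributions[m].sum()`` and all contributions are >= 0;
    the grid is retained because peel-off operates on it.
    """

    direction: Direction
    scores: np.ndarray  # (M,)
    contributions: np.ndarray  # (M, N)
    samples: tuple[str, ...]
    grid: MarkerGrid

    def __post_init__(self) -> None:
        if self.contributions.shape != (len(self.scores), len(self.samples)):
            raise ValueError("contribution grid shape mismatch")


@dataclass(frozen=True)
class FocalThresholds:
    """Sample-specific high-level thresholds (positive magnitudes)."""

    direction: Direction
    thresholds: np.ndarray  # (N,)
    samples: tuple[str, ...]


def contribution(
    cn_value: float, threshold: float, direction: Direction
) -> float:
    """G-score contribution of a single copy-number value.

    AMP: ``cn`` if ``cn >= threshold`` else 0; DEL: ``-cn`` if
    ``cn <= -threshold`` else 0; missing (NaN) contributes 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be strictly positive")
    if cn_value is None or np.isnan(cn_value):
        return 0.0
    if direction == "amp":
        return float(cn_value) if cn_value >= threshold else 0.0
    return float(-cn_value) if cn_value <= -threshold else 0.0


def _contribution_grid(
    values: np.ndarray, thresholds: np.ndarray | float, direction: Direction
) -> np.ndarray:
    """Vectorized contribution; ``thresholds`` broadcasts over samples."""
    v = np.where(np.isnan(values), 0.0, values)
    if direction == "amp":
        return np.where(v >= thresholds, v, 0.0)
    return np.where(v <= -np.asarray(thresholds), -v, 0.0)


def compute_gscore(matrix: CopyNumberMatrix, params: ScoreParams) -> GScoreTrack:
    """Standard G-score track: one fixed threshold for every sample."""
    if matrix.n_samples == 0:
        raise ValueError("cannot score a matrix with no samples")
    contrib = _contribution_grid(matrix.values, params.theta, params.direction)
    return GScoreTrack(
        direction=params.direction,
        scores=contrib.sum(axis=1),
        contributions=contrib,
        samples=matrix.samples,
        grid=matrix.grid,
    )


def _arm_medians(matrix: CopyNumberMatrix, arms: ArmTable) -> np.ndarray:
    """Per (arm, sample) medians of non-missing copy number, shape (A, N).

    Entries are NaN when a sample has no data on an arm.  Markers outside any
    arm interval are excluded.  A sample with no data anywhere raises.
    """
    if matrix.grid.arm is None:
        matrix = assign_arms(matrix, arms)
    g = matrix.grid
    all_missing = np.all(np.isnan(matrix.values), axis=0)
    if all_missing.any():
        bad = matrix.samples[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"sample {bad!r} has no copy-number data")
    meds = []
    for c, lo, hi in g.chrom_blocks():
        for arm in ("p", "q"):
            rows = np.flatnonzero(g.arm[lo:hi] == arm) + lo
            if rows.size == 0:
                continue
            block = matrix.values[rows]
            with np.errstate(all="ignore"):
                meds.append(np.nanmedian(block, axis=0))
    return np.asarray(meds)


def focal_thresholds(
    matrix: CopyNumberMatrix, arms: ArmTable, params: ScoreParams
) -> FocalThresholds:
    """Sample-specific thresholds for the focal variant.

    AMP: ``theta_amp + max(0, max over arms of median(CN on arm))`` — the
    threshold is floored at the standard one so it is never laxer.  DEL is
    the sign-mirrored form with the minimum arm median.
    """
    meds = _arm_medians(matrix, arms)
    with np.errstate(all="ignore"):
        if params.direction == "amp":
            broad = np.nanmax(meds, axis=0)
            thr = params.theta_amp + np.maximum(0.0, np.nan_to_num(broad, nan=0.0))
        else:
            broad = np.nanmin(meds, axis=0)
            thr = params.theta_del + np.maximum(0.0, -np.nan_to_num(broad, nan=0.0))
    return FocalThresholds(
        direction=params.direction, thresholds=thr, samples=matrix.samples
    )


def compute_focal_gscore(
    matrix: CopyNumberMatrix, arms: ArmTable, params: ScoreParams
) -> GScoreTrack:
    """Focal G-score track: each sample scored against its own threshold."""
    if matrix.n_samples == 0:
        raise ValueError("cannot score a matrix with no samples")
    thr = focal_thresholds(matrix, arms, params).thresholds
    contrib = _contribution_grid(matrix.values, thr[np.newaxis, :], params.direction)
    return GScoreTrack(
        direction=params.direction,
        scores=contrib.sum(axis=1),
        contributions=contrib,
        samples=matrix.samples,
        grid=matrix.grid,
    )
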