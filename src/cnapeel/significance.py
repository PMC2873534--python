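"""Null distribution of G-scores, p-values, and Benjamini-Hochberg q-values.

The null model is genome-wide permutation: each sample's per-marker
contributions are shuffled independently across the genome, so a null
G-score is a sum of one independent draw per sample from that sample's
empirical contribution distribution.  Two constructions are provided:

* ``convolution`` (default): each sample's contributions are binned into a
  histogram and the per-sample histograms are convolved — the exact
  distribution of the permutation null up to binning resolution, and fully
  deterministic;
* ``montecarlo``: explicit seeded permutations, recording permuted per-marker
  sums.

Binning is right-closed (a contribution is assigned the bin whose upper edge
covers it) and score lookups round down, so tail probabilities — hence
p-values — are conservative with respect to the binning resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("cnapeel")

__all__ = [
    "ConfigError",
    "NullDistribution",
    "SignificanceTrack",
    "build_null",
    "pvalues",
    "qvalues",
    "gscore_for_q",
    "significance_track",
]


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass(frozen=True)
class NullDistribution:
    """Binned tail-probability table of the permutation null.

    ``tail[k] = Pr(G >= k * bin_width)`` under the null; ``tail[0] == 1`` and
    the table is non-increasing.  ``min_tail`` is the smallest resolvable
    tail mass, used for scores beyond the represented support.
    """

    tail: np.ndarray
    bin_width: float
    method: str
    n_samples: int
    min_tail: float

    @property
    def max_score(self) -> float:
        return (len(self.tail) - 1) * self.bin_width

    @property
    def degenerate(self) -> bool:
        """True when every contribution is zero (no aberration anywhere)."""
        return len(self.tail) == 1


def _binned_tail(pmf: np.ndarray) -> np.ndarray:
    tail = pmf[::-1].cumsum()[::-1]
    tail = np.clip(tail, 0.0, 1.0)
    tail[0] = 1.0
    return tail


def build_null(
    contributions: np.ndarray,
    method: str = "convolution",
    n_bins: int = 10_000,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> NullDistribution:
    """Build the null distribution of G-scores from a contribution grid.

    Parameters
    ----------
    contributions:
        (markers, samples) non-negative contribution grid of a G-score track.
    method:
        ``"convolution"`` or ``"montecarlo"``.
    n_bins:
        Number of score bins spanning the maximal attainable G-score.
    n_perm:
        Number of genome-wide permutations (Monte-Carlo only).
    seed:
        Mandatory for the Monte-Carlo method.
    """
    contributions = np.asarray(contributions, dtype=np.float64)
    if contributions.ndim != 2 or contributions.shape[1] < 1:
        raise ConfigError("contributions must be a (markers, samples) grid")
    if np.any(contributions < 0):
        raise ConfigError("contributions must be non-negative")
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if method not in ("convolution", "montecarlo"):
        raise ConfigError(f"unknown null method {method!r}")

    n_markers, n_samples = contributions.shape
    g_max = float(contributions.max(axis=0).sum())
    if g_max <= 0.0:
        # no aberrant marker anywhere: the null is a point mass at zero
        return NullDistribution(
            tail=np.array([1.0]), bin_width=1.0, method=method,
            n_samples=n_samples, min_tail=1.0,
        )
    width = g_max / n_bins

    if method == "convolution":
        pmf = np.array([1.0])
        for j in range(n_samples):
            idx = np.ceil(contributions[:, j] / width).astype(np.int64)
            hist = np.bincount(idx) / n_markers
            pmf = np.convolve(pmf, hist)
        tail = _binned_tail(pmf)
        positive = tail[tail > 0]
        min_tail = float(positive[-1]) if positive.size else 1.0
        return NullDistribution(
            tail=tail, bin_width=width, method="convolution",
            n_samples=n_samples, min_tail=min_tail,
        )

    if seed is None:
        raise ConfigError("the montecarlo method requires an explicit seed")
    rng = np.random.default_rng(seed)
    max_bins = n_bins + n_samples + 1
    counts = np.zeros(max_bins + 1, dtype=np.int64)
    chunk = max(1, min(n_perm, int(2e6 // max(1, n_markers))))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        sums = np.zeros((c, n_markers))
        for j in range(n_samples):
            order = rng.random((c, n_markers)).argsort(axis=1)
            sums += contributions[:, j][order]
        idx = np.ceil(sums / width).astype(np.int64)
        counts += np.bincount(idx.ravel(), minlength=max_bins + 1)
        done += c
    total = n_perm * n_markers
    last = int(np.flatnonzero(counts)[-1])
    tail = _binned_tail(counts[: last + 1] / total)
    return NullDistribution(
        tail=tail, bin_width=width, method="montecarlo",
        n_samples=n_samples, min_tail=1.0 / total,
    )


def pvalues(track, null: NullDistribution) -> np.ndarray:
    """Per-marker p-values: the null tail probability at each G-score.

    ``track`` may be a :class:`~cnapeel.gscore.GScoreTrack` or a plain score
    array.  Scores exceeding the null support get the smallest representable
    tail mass (logged).
    """
    scores = np.asarray(getattr(track, "scores", track), dtype=np.float64)
    if np.any(scores < 0):
        raise ValueError("G-scores must be non-negative")
    if null.degenerate:
        p = np.where(scores > 0, null.min_tail, 1.0)
        return p
    idx = np.floor(scores / null.bin_width).astype(np.int64)
    over = idx >= len(null.tail)
    if over.any():
        logger.info(
            "%d scores exceed the null support; assigning minimal tail mass %g",
            int(over.sum()), null.min_tail,
        )
    p = np.empty_like(scores)
    p[~over] = null.tail[idx[~over]]
    p[over] = null.min_tail
    return p


def qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over all markers of one direction.

    Sort p ascending, set ``q_(k) = min_{j >= k} p_(j) * M / j`` capped at 1,
    and map back to the original marker order.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def gscore_for_q(
    q_target: float, null: NullDistribution, n_markers: int
) -> float:
    """Invert a q-value threshold to a G-score threshold (``G_thres``).

    Returns the smallest score ``g`` whose null tail probability is at most
    ``q_target``: at the most favorable rank (M of M), the BH bound reduces
    to ``p <= q_target``, so any marker scoring ``>= g`` attains
    ``q <= q_target`` regardless of the rest of the track.
    """
    if not (0.0 < q_target < 1.0):
        raise ConfigError("q_target must lie strictly between 0 and 1")
    if n_markers < 1:
        raise ConfigError("n_markers must be >= 1")
    reachable = np.flatnonzero(null.tail <= q_target)
    if reachable.size == 0:
        raise ConfigError(
            f"q-target {q_target} is unreachable within the null support "
            f"(smallest tail {null.tail[-1]:.3g}); increase n_bins or n_perm"
        )
    g = float(reachable[0] * null.bin_width)
    logger.debug("G-score threshold for q<=%g: %g (%s null)", q_target, g, null.method)
    return g


@dataclass(frozen=True)
class SignificanceTrack:
    """Per-marker p- and q-values for one direction."""

    direction: str
    p: np.ndarray
    q: np.ndarray
    q_threshold: float = 0.25

    def __post_init__(self) -> None:
        if len(self.p) != len(self.q):
            raise ValueError("p and q lengths differ")


def significance_track(track, null: NullDistribution, q_threshold: float = 0.25):
    """Convenience: p-values then BH q-values for a G-score track."""
    p = pvalues(track, null)
    return SignificanceTrack(
        direction=getattr(track, "direction", "amp"),
        p=p,
        q=qvalues(p),
        q_threshold=q_threshold,
    )
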