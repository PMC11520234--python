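"""Exact PWM match p-values under an i.i.d. background.

The null distribution of the raw log-odds score of a random width-w window
is computed exactly by dynamic programming: per-position scores are rounded
to integer multiples of a granularity eps, and the distribution of their sum
is built by iterated convolution of the four-point per-position score
distributions (base probabilities = the motif's background).  The match
p-value of a score s is P(score >= s) under this distribution.

The p-value is per window (a match p-value); it is NOT corrected for the
number of windows scanned — callers that need a scan-wide error rate can
multiply by the reported window count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .motifs import Motif, reverse_complement


class GranularityError(ValueError):
    """Granularity too coarse: the score range collapses into one bin."""


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact discretized null distribution of a motif's raw score.

    ``support`` holds integer bins k representing scores k * granularity,
    spanning the full attainable range; ``mass[k - support[0]]`` is the
    probability of bin k and ``cumulative_upper`` the tail P(score >= k).
    """

    motif_id: str
    granularity: float
    support: np.ndarray  # int bins, contiguous ascending
    mass: np.ndarray
    cumulative_upper: np.ndarray
    min_score: float = float("-inf")  # attainable raw-score range of the motif
    max_score: float = float("inf")
    n_windows_hint: int = 0  # window count of the scan that used this, optional

    def pvalue(self, raw_score: float) -> float:
        """P(score >= raw_score): tail probability at the nearest score bin.

        Monotone non-increasing in ``raw_score``.  Scores clamp to the
        support: attainable scores whose rounded bin falls outside it (the
        per-column rounding can drift the sum by up to w/2 bins) map to the
        boundary bin, while scores strictly beyond the attainable range
        return 0 or 1 exactly.
        """
        if raw_score > self.max_score:
            return 0.0
        if raw_score <= self.min_score:
            return 1.0
        b = int(np.floor(raw_score / self.granularity + 0.5))
        lo = int(self.support[0])
        hi = int(self.support[-1])
        b = min(max(b, lo), hi)
        return float(self.cumulative_upper[b - lo])

    def score_for_pvalue(self, alpha: float) -> "ScoreThreshold":
        """Smallest binned score s with P(score >= s) <= alpha.

        When alpha is below the mass of the topmost bin no score attains it;
        the maximum bin is returned with ``attainable=False``.
        """
        if not (0 < alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        idx = np.nonzero(self.cumulative_upper <= alpha)[0]
        if idx.size == 0:
            return ScoreThreshold(
                score=float(self.support[-1] * self.granularity), attainable=False
            )
        return ScoreThreshold(
            score=float(self.support[idx[0]] * self.granularity), attainable=True
        )


class ScoreThreshold(NamedTuple):
    score: float
    attainable: bool


def default_granularity(m: Motif, bins: int = 10_000) -> float:
    """Granularity eps = attainable score span / ``bins`` (fallback for
    degenerate zero-span motifs: 1.0, a single zero bin)."""
    span = m.max_score - m.min_score
    return span / bins if span > 0 else 1.0


def build_distribution(
    m: Motif, granularity: float | None = None, background=None
) -> ScoreDistribution:
    """Exact null score distribution by score-histogram convolution.

    Per-column log-odds are rounded to integer multiples of ``granularity``
    and the distribution of the w-column sum is accumulated column by
    column in O(w * range * 4).  ``background`` defaults to the motif's own
    stored background (single source of truth per motif).
    """
    if granularity is None:
        granularity = default_granularity(m)
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bg = np.asarray(m.background if background is None else background, dtype=float)
    scaled = np.floor(m.lods / granularity + 0.5).astype(np.int64)  # w x 4
    span = m.max_score - m.min_score
    if span > 0:
        lo_total = int(scaled.min(axis=1).sum())
        hi_total = int(scaled.max(axis=1).sum())
        if lo_total == hi_total:
            raise GranularityError(
                f"granularity {granularity} collapses motif {m.id!r} "
                "score range into a single bin"
            )

    mins = scaled.min(axis=1)
    maxs = scaled.max(axis=1)
    cur_lo = 0
    arr = np.array([1.0])
    for i in range(m.width):
        new_lo = cur_lo + int(mins[i])
        new_hi = (cur_lo + len(arr) - 1) + int(maxs[i])
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(scaled[i, b]) - new_lo
            new[off : off + len(arr)] += bg[b] * arr
        arr = new
        cur_lo = new_lo

    support = np.arange(cur_lo, cur_lo + len(arr), dtype=np.int64)
    cum_upper = np.cumsum(arr[::-1])[::-1].copy()
    return ScoreDistribution(
        motif_id=m.id,
        granularity=float(granularity),
        support=support,
        mass=arr,
        cumulative_upper=cum_upper,
        min_score=m.min_score,
        max_score=m.max_score,
    )


def pvalue(sd: ScoreDistribution, raw_score: float) -> float:
    """Functional alias for :meth:`ScoreDistribution.pvalue`."""
    return sd.pvalue(raw_score)


def score_for_pvalue(sd: ScoreDistribution, alpha: float) -> ScoreThreshold:
    """Functional alias for :meth:`ScoreDistribution.score_for_pvalue`."""
    return sd.score_for_pvalue(alpha)


def distribution_for_reverse_complement(m: Motif, granularity=None):
    """Distribution of the reverse-complement motif (equal to the forward
    one whenever the background is strand-neutral in the sense bg(A)=bg(T),
    bg(C)=bg(G); exposed for tests)."""
    return build_distribution(reverse_complement(m), granularity=granularity)
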