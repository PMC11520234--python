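"""Independent brute-force oracles used to validate the fast paths.

These deliberately re-derive every quantity from first principles — full
enumeration of 4^w sequences for the null score distribution, a naive
double loop for scanning, a linear scan for interval overlap — and stay
independent of the implementation code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from motifdisrupt.motifs import ALPHABET, Motif

BASES = list(ALPHABET)


def enumerate_distribution(m: Motif, granularity: float) -> dict[int, float]:
    """Null distribution over integer score bins by full 4^w enumeration,
    with the same per-column rounding the DP applies."""
    scaled = np.floor(m.lods / granularity + 0.5).astype(np.int64)
    bg = m.background
    dist: dict[int, float] = {}
    for combo in itertools.product(range(4), repeat=m.width):
        score = int(sum(scaled[i, b] for i, b in enumerate(combo)))
        prob = math.prod(bg[b] for b in combo)
        dist[score] = dist.get(score, 0.0) + prob
    return dist


def enumerate_pvalue(m: Motif, granularity: float, raw_score: float) -> float:
    """P(binned score >= binned raw_score) from the enumeration oracle."""
    dist = enumerate_distribution(m, granularity)
    lo, hi = min(dist), max(dist)
    b = int(np.floor(raw_score / granularity + 0.5))
    if raw_score > m.max_score:
        return 0.0
    if raw_score <= m.min_score:
        return 1.0
    b = min(max(b, lo), hi)
    return sum(p for s, p in dist.items() if s >= b)


def enumerate_score_for_pvalue(m: Motif, granularity: float, alpha: float):
    """Smallest binned score whose tail probability is <= alpha, or None."""
    dist = enumerate_distribution(m, granularity)
    lo, hi = min(dist), max(dist)
    best = None
    for s in range(hi, lo - 1, -1):  # all bins, including empty ones
        tail = sum(p for b, p in dist.items() if b >= s)
        if tail <= alpha:
            best = s
        else:
            break
    return None if best is None else best * granularity


def naive_best_match(seq: str, m: Motif):
    """Exhaustive double-strand scan: returns (raw_score, strand, win_start)
    with the leftmost-then-plus-strand tie-break, or None if every window
    contains a non-ACGT base."""
    from motifdisrupt.motifs import reverse_complement

    w = m.width
    rc = reverse_complement(m)
    best = None
    for s in range(len(seq) - w + 1):
        window = seq[s : s + w].upper()
        if any(c not in ALPHABET for c in window):
            continue
        idx = [ALPHABET.index(c) for c in window]
        for strand, mm in (("+", m), ("-", rc)):
            score = float(np.sum(mm.lods[np.arange(w), idx]))
            if best is None or score > best[0]:
                best = (score, strand, s)
    return best


def brute_overlaps(peaks, chrom: str, start: int, end: int):
    """Linear-scan half-open interval overlap."""
    return [
        p
        for p in peaks
        if p.chrom == chrom and p.start < end and p.end > start
    ]


def random_count_motif(rng: np.random.Generator, width: int, motif_id="R") -> Motif:
    """A random count-matrix motif smoothed with the default pseudocount."""
    from motifdisrupt.motifs import smooth_matrix

    counts = rng.integers(0, 50, size=(width, 4)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1  # no all-zero columns
    bg = np.full(4, 0.25)
    return Motif(
        id=f"{motif_id}{width}",
        tf_name=f"{motif_id}{width}",
        ppm=smooth_matrix(counts, bg, 0.8),
        background=bg,
        pseudocount=0.8,
        counts=counts,
    )


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))
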