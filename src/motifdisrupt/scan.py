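"""Per-allele motif scanning, effect sizes and indel edge coordinates.

For a variant and a motif of width w, both allele sequences are built with
exactly w-1 bases of genomic context on each side, so every window of width
w that can overlap the varying bases is scanned and no other window is.
Both strands of both alleles are scanned; the best match per allele is the
highest-scoring window (equivalently, the lowest match p-value, since the
p-value is monotone in the raw score).  The effect size is

    effect = rel_score(best alt match) - rel_score(best ref match)

so negative effects are disruptions and positive effects are created sites.

Motif matches over indels are located in an edge-relative coordinate
system: ``coord_start`` is the signed offset of the motif start from the
variant's start edge (negative = upstream) and ``coord_end`` the signed
offset of the motif end from the variant's end edge (positive =
downstream); 0 means exact edge coincidence.  This makes matches that exist
only inside an inserted sequence — which have no reference-genome
coordinates — locatable, and classifies every indel/motif configuration
into one of four geometries: overlapping the variant's start
(upstream_overlap), entirely contained within it (contained), overlapping
its end (downstream_overlap), or spanning it (spanning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .motifs import ALPHABET, Motif, revcomp_seq, reverse_complement
from .pvalues import ScoreDistribution, build_distribution
from .variants import Variant, VariantClass

log = logging.getLogger(__name__)

STRONG_THRESHOLD = 0.4
WEAK_THRESHOLD = 0.1

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class ScanError(ValueError):
    pass


class Geometry(str, Enum):
    SNV_WINDOW = "snv_window"
    UPSTREAM_OVERLAP = "upstream_overlap"
    CONTAINED = "contained"
    DOWNSTREAM_OVERLAP = "downstream_overlap"
    SPANNING = "spanning"


@dataclass(frozen=True)
class AlleleSeq:
    """One allele's scan sequence with its variant span and genomic anchor.

    ``seq[var_start:var_end]`` are the bases this allele carries at the
    variant (an empty interval at the breakpoint for the allele lacking
    inserted bases); ``genome_offset`` is the genomic coordinate of seq[0]
    (well-defined up to the variant for the alt allele).
    """

    seq: str
    var_start: int
    var_end: int
    genome_offset: int
    chrom: str
    clipped_left: bool = False
    clipped_right: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.var_start <= self.var_end <= len(self.seq)):
            raise ScanError("variant span outside allele sequence")


@dataclass(frozen=True)
class AlleleMatch:
    """Best motif match on one allele sequence."""

    raw_score: float
    rel_score: float
    pvalue: float
    strand: str  # '+' or '-'
    win_start: int  # 0-based offset of the window within the AlleleSeq
    matched_seq: str  # forward-strand window sequence, length w
    matched: bool = True  # False for the sentinel no-match result
    overlaps_variant: bool = False

    def mirrored(self, seq_len: int, width: int) -> "AlleleMatch":
        """The same match seen on the reverse-complemented sequence."""
        return AlleleMatch(
            raw_score=self.raw_score,
            rel_score=self.rel_score,
            pvalue=self.pvalue,
            strand="-" if self.strand == "+" else "+",
            win_start=seq_len - width - self.win_start,
            matched_seq=revcomp_seq(self.matched_seq),
            matched=self.matched,
            overlaps_variant=self.overlaps_variant,
        )


@dataclass(frozen=True)
class DisruptionResult:
    """Paired ref/alt best matches for one (variant, motif)."""

    variant: Variant
    motif_id: str
    tf_name: str
    motif_width: int
    ref_match: AlleleMatch
    alt_match: AlleleMatch
    effect: float
    direction: str  # 'disrupted' | 'created'
    strength: str  # 'strong' | 'weak' | 'neutral'
    geometry: Geometry
    coord_start: int
    coord_end: int
    better_allele: str  # 'ref' | 'alt'
    motif_ref_start: int | None = None  # reference-genome motif span, when
    motif_ref_end: int | None = None  # representable; None inside insertions
    n_windows: int = 0  # windows scanned per allele pair (for corrections)
    evidence: object | None = None  # peak evidence, attached by peaks module


# ---------------------------------------------------------------------------
# allele sequence construction
# ---------------------------------------------------------------------------


def build_allele_seqs(
    v: Variant, m: Motif, genome
) -> tuple[AlleleSeq, AlleleSeq]:
    """Build ref and alt scan sequences with w-1 context bases per side.

    ``genome`` is any object with ``fetch(chrom, start, end) -> str`` and
    ``chrom_length(chrom) -> int`` (see :class:`SequenceSource`).  Windows
    are clipped at chromosome edges with a logged note.
    """
    w = m.width
    length = genome.chrom_length(v.chrom)
    if length is None:
        raise ScanError(f"chromosome {v.chrom!r} absent from genome")
    left = max(0, v.start - (w - 1))
    right = min(length, v.end + (w - 1))
    clipped_left = left != v.start - (w - 1)
    clipped_right = right != v.end + (w - 1)
    if clipped_left or clipped_right:
        log.info(
            "%s: scan window clipped at chromosome edge (%s:%d-%d)",
            v.vid,
            v.chrom,
            left,
            right,
        )
    ref_seq = genome.fetch(v.chrom, left, right).upper()
    v_s = v.start - left
    v_e = v.end - left
    alt_seq = ref_seq[:v_s] + v.alt + ref_seq[v_e:]
    if len(ref_seq) < w or len(alt_seq) < w:
        raise ScanError(
            f"{v.vid}: clipped context too short to scan a width-{w} motif"
        )
    ref_allele = AlleleSeq(
        ref_seq, v_s, v_e, left, v.chrom, clipped_left, clipped_right
    )
    alt_allele = AlleleSeq(
        alt_seq, v_s, v_s + len(v.alt), left, v.chrom, clipped_left, clipped_right
    )
    return ref_allele, alt_allele


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _window_scores(codes: np.ndarray, lods: np.ndarray) -> np.ndarray:
    """Scores of every window (NaN where the window has a non-ACGT base)."""
    w = lods.shape[0]
    n_win = len(codes) - w + 1
    out = np.empty(n_win)
    for s in range(n_win):
        win = codes[s : s + w]
        if np.any(win < 0):
            out[s] = np.nan
        else:
            out[s] = np.sum(lods[np.arange(w), win])
    return out


def best_match(
    a: AlleleSeq, m: Motif, sd: ScoreDistribution | None = None
) -> AlleleMatch:
    """Highest-scoring window over both strands of one allele sequence.

    Ties are broken deterministically: smaller window start, then the +
    strand.  Windows containing non-ACGT characters are skipped; if every
    window is skipped a flagged sentinel (p-value 1, rel_score 0) is
    returned.
    """
    w = m.width
    if len(a.seq) < w:
        raise ScanError(f"sequence shorter ({len(a.seq)}) than motif width {w}")
    codes = _CODE[np.frombuffer(a.seq.encode("ascii"), dtype=np.uint8)]
    fwd = _window_scores(codes, m.lods)
    rev = _window_scores(codes, reverse_complement(m).lods)

    best_score = -np.inf
    best_start = -1
    best_strand = "+"
    for s in range(len(fwd)):
        for strand, score in (("+", fwd[s]), ("-", rev[s])):
            if np.isnan(score):
                continue
            if score > best_score:
                best_score, best_start, best_strand = float(score), s, strand
    if best_start < 0:
        return AlleleMatch(
            raw_score=float("-inf"),
            rel_score=0.0,
            pvalue=1.0,
            strand="+",
            win_start=0,
            matched_seq="",
            matched=False,
        )
    pv = sd.pvalue(best_score) if sd is not None else float("nan")
    ov = _overlaps_span(best_start, best_start + w, a.var_start, a.var_end)
    return AlleleMatch(
        raw_score=best_score,
        rel_score=m.relative(best_score),
        pvalue=pv,
        strand=best_strand,
        win_start=best_start,
        matched_seq=a.seq[best_start : best_start + w],
        matched=True,
        overlaps_variant=ov,
    )


def _overlaps_span(m_s: int, m_end: int, v_s: int, v_e: int) -> bool:
    # half-open window vs (possibly empty) variant span; an empty span
    # overlaps iff the breakpoint is strictly inside the window
    if v_s == v_e:
        return m_s < v_s < m_end
    return m_s < v_e and m_end > v_s


# ---------------------------------------------------------------------------
# geometry / edge-relative coordinates
# ---------------------------------------------------------------------------


def indel_coordinates(
    match: AlleleMatch, a: AlleleSeq, width: int
) -> tuple[Geometry, int, int]:
    """Edge-relative motif coordinates and geometry class on one allele.

    With m_s/m_e the first/last base of the match (0-based inclusive) and
    the variant occupying ``[v_s, v_e)`` of the allele sequence:
    ``coord_start = m_s - v_s`` and ``coord_end = (m_e + 1) - v_e``; 0 means
    exact edge coincidence, negative upstream, positive downstream.
    """
    m_s = match.win_start
    m_e = m_s + width - 1
    v_s, v_e = a.var_start, a.var_end
    coord_start = m_s - v_s
    coord_end = (m_e + 1) - v_e
    if coord_start < 0 and coord_end > 0:
        geom = Geometry.SPANNING
    elif coord_start >= 0 and coord_end <= 0:
        geom = Geometry.CONTAINED
    elif coord_start < 0:
        geom = Geometry.UPSTREAM_OVERLAP
    else:
        geom = Geometry.DOWNSTREAM_OVERLAP
    return geom, coord_start, coord_end


def _pick_better(
    v: Variant, ref_match: AlleleMatch, alt_match: AlleleMatch
) -> str:
    """'ref' or 'alt' — the better-scoring allele, with a swap-invariant
    tie-break (shorter allele string, then lexicographically smaller)."""
    if ref_match.rel_score > alt_match.rel_score:
        return "ref"
    if alt_match.rel_score > ref_match.rel_score:
        return "alt"
    if len(v.ref) != len(v.alt):
        return "ref" if len(v.ref) < len(v.alt) else "alt"
    return "ref" if v.ref <= v.alt else "alt"


def _map_alt_match_to_reference(
    v: Variant, match: AlleleMatch, a: AlleleSeq, width: int
) -> tuple[int | None, int | None]:
    """Reference-genome span of an alt-allele match, or (None, None) when
    the match crosses the edit and has no reference coordinates."""
    m_s, m_end = match.win_start, match.win_start + width
    v_s, v_e = a.var_start, a.var_end
    shift = len(v.ref) - len(v.alt)
    if v.vclass in (VariantClass.SNV, VariantClass.MNV):
        return a.genome_offset + m_s, a.genome_offset + m_end
    if m_end <= v_s:
        return a.genome_offset + m_s, a.genome_offset + m_end
    if m_s >= v_e:
        return a.genome_offset + m_s + shift, a.genome_offset + m_end + shift
    return None, None


def score_variant(
    v: Variant,
    m: Motif,
    genome,
    sd: ScoreDistribution | None = None,
    strong_threshold: float = STRONG_THRESHOLD,
    weak_threshold: float = WEAK_THRESHOLD,
) -> DisruptionResult:
    """Score one variant against one motif.

    Builds both allele sequences, takes the best match on each, and reports
    the effect size (alt - ref relative score), a disrupted/created call, a
    strong/weak/neutral strength band, and the geometry and edge-relative
    coordinates of the better-scoring allele's match.
    """
    if sd is None:
        sd = build_distribution(m)
    ref_allele, alt_allele = build_allele_seqs(v, m, genome)
    ref_match = best_match(ref_allele, m, sd)
    alt_match = best_match(alt_allele, m, sd)
    effect = alt_match.rel_score - ref_match.rel_score
    direction = "disrupted" if effect < 0 else "created"
    mag = abs(effect)
    if mag >= strong_threshold:
        strength = "strong"
    elif mag >= weak_threshold:
        strength = "weak"
    else:
        strength = "neutral"

    better = _pick_better(v, ref_match, alt_match)
    b_match, b_allele = (
        (ref_match, ref_allele) if better == "ref" else (alt_match, alt_allele)
    )
    if v.vclass in (VariantClass.SNV, VariantClass.MNV):
        geom = Geometry.SNV_WINDOW
        _, coord_start, coord_end = indel_coordinates(b_match, b_allele, m.width)
    else:
        geom, coord_start, coord_end = indel_coordinates(b_match, b_allele, m.width)

    if better == "ref":
        mstart: int | None = b_allele.genome_offset + b_match.win_start
        mend: int | None = mstart + m.width
    else:
        mstart, mend = _map_alt_match_to_reference(v, b_match, b_allele, m.width)

    w = m.width
    n_windows = (len(ref_allele.seq) - w + 1) + (len(alt_allele.seq) - w + 1)
    return DisruptionResult(
        variant=v,
        motif_id=m.id,
        tf_name=m.tf_name,
        motif_width=w,
        ref_match=ref_match,
        alt_match=alt_match,
        effect=effect,
        direction=direction,
        strength=strength,
        geometry=geom,
        coord_start=coord_start,
        coord_end=coord_end,
        better_allele=better,
        motif_ref_start=mstart,
        motif_ref_end=mend,
        n_windows=n_windows,
    )


def scan_variants(
    variants,
    motifs,
    genome,
    granularity: float | None = None,
    strong_threshold: float = STRONG_THRESHOLD,
    weak_threshold: float = WEAK_THRESHOLD,
) -> list[DisruptionResult]:
    """Score every (variant, motif) pair; distributions are built once per
    motif and reused across variants."""
    results: list[DisruptionResult] = []
    dists = {m.id: build_distribution(m, granularity=granularity) for m in motifs}
    for v in variants:
        for m in motifs:
            results.append(
                score_variant(
                    v,
                    m,
                    genome,
                    sd=dists[m.id],
                    strong_threshold=strong_threshold,
                    weak_threshold=weak_threshold,
                )
            )
    return results


# ---------------------------------------------------------------------------
# sequence sources
# ---------------------------------------------------------------------------


class SequenceSource:
    """Uniform fetch interface over a pyfaidx Fasta or a plain dict."""

    def __init__(self, source):
        self._src = source

    @classmethod
    def from_fasta(cls, path: str) -> "SequenceSource":
        import pyfaidx

        return cls(pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True))

    def chrom_length(self, chrom: str) -> int | None:
        if isinstance(self._src, dict):
            seq = self._src.get(chrom)
            return None if seq is None else len(seq)
        if chrom not in self._src:
            return None
        return len(self._src[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        length = self.chrom_length(chrom)
        if length is None:
            raise ScanError(f"chromosome {chrom!r} absent from genome")
        start = max(0, start)
        end = min(length, end)
        if isinstance(self._src, dict):
            return self._src[chrom][start:end]
        return str(self._src[chrom][start:end])

    @property
    def chromosomes(self) -> list[str]:
        if isinstance(self._src, dict):
            return list(self._src)
        return list(self._src.keys())
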