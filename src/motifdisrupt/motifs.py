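"""Motif libraries: JASPAR PFM and MEME minimal parsers, smoothing, log-odds.

A motif is stored as a position probability matrix (PPM) over the fixed
alphabet ACGT, one row per position.  Raw count or frequency matrices are
smoothed with a pseudocount distributed proportionally to the background
(Bayesian smoothing), which guarantees strictly positive probabilities and
finite log-odds.  Scores are log2 odds against the background; the
consensus sequence (per-position argmax base) attains ``max_score`` exactly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_PERM = [3, 2, 1, 0]  # A<->T, C<->G
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8


_RC_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp_seq(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_RC_TABLE)[::-1]


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed."""


class MotifValidationError(ValueError):
    """Raised when parsed motif content violates an invariant."""


@dataclass(frozen=True)
class Motif:
    """A TF binding motif with derived log-odds scores.

    Parameters
    ----------
    id : str
        Motif identifier (e.g. a JASPAR accession).
    tf_name : str
        Name of the transcription factor the motif models.
    ppm : ndarray, shape (width, 4)
        Smoothed position probability matrix; rows sum to 1, entries in (0, 1].
    background : ndarray, shape (4,)
        Background base frequencies used for the log-odds and the null model.
    pseudocount : float
        Total pseudocount that was distributed over each column.
    counts : ndarray or None
        The raw matrix as read from file (counts or frequencies), kept for
        lossless round-tripping.
    """

    id: str
    tf_name: str
    ppm: np.ndarray
    background: np.ndarray
    pseudocount: float
    counts: np.ndarray | None = None
    lods: np.ndarray = field(init=False, repr=False)
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if ppm.ndim != 2 or ppm.shape[1] != 4 or ppm.shape[0] < 1:
            raise MotifValidationError(
                f"motif {self.id!r}: ppm must be width x 4, got {ppm.shape}"
            )
        if np.any(ppm <= 0) or np.any(ppm > 1):
            raise MotifValidationError(
                f"motif {self.id!r}: ppm entries must lie in (0, 1]"
            )
        if not np.allclose(ppm.sum(axis=1), 1.0, atol=1e-9):
            raise MotifValidationError(f"motif {self.id!r}: ppm rows must sum to 1")
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise MotifValidationError(
                f"motif {self.id!r}: background must be a positive length-4 "
                "probability vector"
            )
        if self.pseudocount < 0:
            raise MotifValidationError(f"motif {self.id!r}: negative pseudocount")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "background", bg)
        lods = np.log2(ppm / bg[None, :])
        object.__setattr__(self, "lods", lods)
        object.__setattr__(self, "min_score", float(lods.min(axis=1).sum()))
        object.__setattr__(self, "max_score", float(lods.max(axis=1).sum()))

    @property
    def width(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        """Per-position argmax base string; attains ``max_score`` exactly."""
        return "".join(ALPHABET[i] for i in self.ppm.argmax(axis=1))

    @property
    def anticonsensus(self) -> str:
        """Per-position argmin base string; attains ``min_score`` exactly."""
        return "".join(ALPHABET[i] for i in self.ppm.argmin(axis=1))

    def score_window(self, seq: str) -> float:
        """Log2-odds score of a single window ``seq`` of length ``width``."""
        if len(seq) != self.width:
            raise ValueError(f"window length {len(seq)} != motif width {self.width}")
        idx = [_BASE_INDEX[b] for b in seq]
        return float(np.sum(self.lods[np.arange(self.width), idx]))

    def relative(self, raw_score: float) -> float:
        """Min-max normalize a raw score into [0, 1] over the attainable range."""
        span = self.max_score - self.min_score
        if span <= 0:
            return 0.0
        return (raw_score - self.min_score) / span


def smooth_matrix(
    raw: np.ndarray, background: np.ndarray, pseudocount: float
) -> np.ndarray:
    """Convert a width x 4 count or frequency matrix into a smoothed PPM.

    Each cell receives ``pseudocount * background[b]`` and the row is
    renormalized: ``ppm[i,b] = (raw[i,b] + pc*bg[b]) / (rowsum + pc)``.
    Works identically for count matrices and frequency matrices (rows ~ 1).
    """
    raw = np.asarray(raw, dtype=float)
    bg = np.asarray(background, dtype=float)
    if np.any(raw < 0):
        raise MotifValidationError("negative entries in count/frequency matrix")
    totals = raw.sum(axis=1, keepdims=True)
    if np.any(totals <= 0) and pseudocount <= 0:
        raise MotifValidationError("zero column with zero pseudocount")
    return (raw + pseudocount * bg[None, :]) / (totals + pseudocount)


def reverse_complement(m: Motif) -> Motif:
    """Reverse-complement a motif: reverse positions, permute A<->T, C<->G.

    An involution; min/max scores are preserved.
    """
    rc = m.ppm[::-1, _COMPLEMENT_PERM]
    counts = None if m.counts is None else m.counts[::-1, _COMPLEMENT_PERM]
    return Motif(
        id=m.id,
        tf_name=m.tf_name,
        ppm=rc,
        background=m.background,
        pseudocount=m.pseudocount,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

_JASPAR_ROW = re.compile(
    r"^\s*(?P<base>[ACGT])?\s*\[?\s*(?P<vals>[-0-9.eE+\s]+?)\s*\]?\s*$"
)


def read_jaspar_pfm(
    path: str,
    background=UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[Motif]:
    """Parse a JASPAR PFM file (">ID name" header, four A/C/G/T rows).

    Count matrices are column-normalized after adding ``pseudocount *
    background[b]`` to each cell; frequency matrices are smoothed the same
    way.  Whitespace-tolerant: tabs/spaces, optional square brackets,
    optional row base labels (rows then follow A, C, G, T order).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    motifs: list[Motif] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise MotifParseError(
                f"{path}: line {i + 1}: expected '>' header, got {line!r}"
            )
        header = line[1:].strip()
        if not header:
            raise MotifParseError(f"{path}: line {i + 1}: empty motif header")
        parts = header.split(None, 1)
        motif_id = parts[0]
        tf_name = parts[1].strip() if len(parts) > 1 else motif_id
        i += 1
        rows: dict[str, list[float]] = {}
        order = []
        while i < n and len(rows) < 4:
            row_line = lines[i]
            if not row_line.strip():
                i += 1
                continue
            match = _JASPAR_ROW.match(row_line)
            if match is None:
                raise MotifParseError(
                    f"{path}: line {i + 1}: cannot parse matrix row {row_line!r}"
                )
            base = match.group("base") or ALPHABET[len(rows)]
            try:
                vals = [float(tok) for tok in match.group("vals").split()]
            except ValueError as exc:
                raise MotifParseError(
                    f"{path}: line {i + 1}: non-numeric matrix entry"
                ) from exc
            if not vals:
                raise MotifParseError(f"{path}: line {i + 1}: empty matrix row")
            if base in rows:
                raise MotifParseError(
                    f"{path}: line {i + 1}: duplicate row for base {base}"
                )
            rows[base] = vals
            order.append(base)
            i += 1
        if len(rows) < 4:
            raise MotifParseError(
                f"{path}: motif {motif_id!r}: expected 4 matrix rows, got {len(rows)}"
            )
        if sorted(order) != list(ALPHABET):
            raise MotifParseError(
                f"{path}: motif {motif_id!r}: rows must cover A, C, G, T"
            )
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise MotifParseError(
                f"{path}: motif {motif_id!r}: rows of unequal length "
                f"{sorted(len(rows[b]) for b in ALPHABET)}"
            )
        raw = np.array([rows[b] for b in ALPHABET], dtype=float).T  # width x 4
        if np.any(raw < 0):
            raise MotifValidationError(
                f"{path}: motif {motif_id!r}: negative counts"
            )
        motifs.append(
            Motif(
                id=motif_id,
                tf_name=tf_name,
                ppm=smooth_matrix(raw, np.asarray(background, float), pseudocount),
                background=np.asarray(background, dtype=float),
                pseudocount=pseudocount,
                counts=raw,
            )
        )
    return motifs


def _format_cell(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_jaspar(motifs: list[Motif], path: str) -> None:
    """Write motifs in JASPAR PFM format, reproducing raw counts exactly."""
    with open(path, "w") as fh:
        for m in motifs:
            raw = m.counts if m.counts is not None else m.ppm
            fh.write(f">{m.id} {m.tf_name}\n")
            for bi, base in enumerate(ALPHABET):
                cells = " ".join(_format_cell(x) for x in raw[:, bi])
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------


def read_meme(path: str, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[Motif]:
    """Parse a MEME minimal-format motif file.

    The background is taken from the file's "Background letter frequencies"
    line when present, else uniform.  Probability rows are smoothed exactly
    as JASPAR frequency matrices.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    background = np.asarray(UNIFORM_BACKGROUND, dtype=float)
    motifs: list[Motif] = []
    i = 0
    n = len(lines)
    saw_version = False
    while i < n:
        line = lines[i].strip()
        if line.startswith("MEME version"):
            saw_version = True
        elif line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip().replace(" ", "")
            if alpha.upper() != "ACGT":
                raise MotifParseError(
                    f"{path}: unsupported alphabet {alpha!r}; only ACGT is supported"
                )
        elif line.startswith("Background letter frequencies"):
            i += 1
            if i >= n:
                raise MotifParseError(f"{path}: truncated background line")
            toks = lines[i].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks) - 1, 2)}
            try:
                background = np.array([freq[b] for b in ALPHABET], dtype=float)
            except KeyError as exc:
                raise MotifParseError(
                    f"{path}: background line missing base {exc}"
                ) from exc
        elif line.startswith("MOTIF"):
            toks = line.split()
            if len(toks) < 2:
                raise MotifParseError(f"{path}: line {i + 1}: MOTIF without id")
            motif_id = toks[1]
            tf_name = toks[2] if len(toks) > 2 else motif_id
            # seek the letter-probability block
            j = i + 1
            while j < n and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    break
                j += 1
            if j >= n or not lines[j].strip().startswith("letter-probability matrix"):
                raise MotifParseError(
                    f"{path}: motif {motif_id!r}: missing letter-probability matrix"
                )
            header = lines[j]
            wm = re.search(r"w=\s*(\d+)", header)
            rows = []
            j += 1
            while j < n:
                row = lines[j].strip()
                if not row or row.startswith(("MOTIF", "URL", "letter-probability")):
                    break
                vals = row.split()
                if len(vals) != 4:
                    break
                rows.append([float(v) for v in vals])
                j += 1
            if not rows:
                raise MotifParseError(
                    f"{path}: motif {motif_id!r}: empty probability matrix"
                )
            if wm is not None and int(wm.group(1)) != len(rows):
                raise MotifParseError(
                    f"{path}: motif {motif_id!r}: declared w={wm.group(1)} but "
                    f"read {len(rows)} rows"
                )
            raw = np.array(rows, dtype=float)
            motifs.append(
                Motif(
                    id=motif_id,
                    tf_name=tf_name,
                    ppm=smooth_matrix(raw, background, pseudocount),
                    background=background.copy(),
                    pseudocount=pseudocount,
                    counts=raw,
                )
            )
            i = j
            continue
        i += 1
    if not saw_version and not motifs:
        raise MotifParseError(f"{path}: not a MEME minimal file (no 'MEME version')")
    if not motifs:
        raise MotifParseError(f"{path}: no MOTIF records found")
    return motifs


def read_motifs(
    path: str,
    fmt: str,
    background=UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[Motif]:
    """Dispatch on motif file format: 'jaspar' or 'meme'."""
    if fmt == "jaspar":
        return read_jaspar_pfm(path, background=background, pseudocount=pseudocount)
    if fmt == "meme":
        return read_meme(path, pseudocount=pseudocount)
    raise ValueError(f"unknown motif format {fmt!r}")
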