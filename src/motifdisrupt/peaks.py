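"""Local TF-binding peak database and disruption-result annotation.

Peak collections follow the ReMap2022 BED layout: the name field encodes
``accession.TF.biotype`` (periods beyond the first two belong to the
biotype).  The database is a sorted, deduplicated peak list serialized to a
single JSON file with a magic string and version, re-indexed per chromosome
with an interval tree on load.

Annotation attaches, to each result whose better-allele match p-value
passes the evidence filter (default p < 1e-4), every overlapping peak
whose TF matches the disrupted motif's canonical TF — optionally expanded
to the whole TF family — together with the distinct experiment biotypes
(cell lines and tissue types).  Results failing the filter are explicitly
marked not-evaluated, never silently dropped.  Pure insertions occupy a
zero-length reference interval, so their overlap query is widened by one
base on each side of the breakpoint.
"""

from __future__ import annotations

import csv
import gzip
import json
import logging
import re
from dataclasses import dataclass, replace

from intervaltree import IntervalTree

from .scan import DisruptionResult
from .variants import VariantClass

log = logging.getLogger(__name__)

DB_MAGIC = "motifdisrupt-peakdb"
DB_VERSION = 1
EVIDENCE_ALPHA = 1e-4

_NAME_NORMALIZE = re.compile(r"[-._\s]+")


def normalize_tf_name(name: str) -> str:
    """Case-insensitive TF-name key; separators (-, ., _, space) removed so
    e.g. 'NKX2-1' and 'NKX2.1' compare equal."""
    return _NAME_NORMALIZE.sub("", name.strip().lower())


class PeakDBError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Peak:
    chrom: str
    start: int
    end: int
    accession: str
    tf: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PeakDBError(f"peak {self.accession}: start must be < end")
        if not self.tf:
            raise PeakDBError(f"peak {self.accession}: empty TF name")

    @property
    def name(self) -> str:
        return f"{self.accession}.{self.tf}.{self.biotype}"


def parse_peak_name(name: str) -> tuple[str, str, str]:
    """Split an 'accession.TF.biotype' name field; periods beyond the first
    two belong to the biotype."""
    parts = name.split(".", 2)
    if len(parts) < 3:
        raise PeakDBError(f"name field {name!r} lacks accession.TF.biotype layout")
    return parts[0], parts[1], parts[2]


class PeakDB:
    """Sorted peak list with a per-chromosome interval index."""

    def __init__(self, peaks: list[Peak]):
        self.peaks = sorted(set(peaks))
        self._trees: dict[str, IntervalTree] = {}
        for i, p in enumerate(self.peaks):
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)

    def __len__(self) -> int:
        return len(self.peaks)

    def query_overlaps(self, chrom: str, start: int, end: int) -> list[Peak]:
        """All peaks with peak.start < end and peak.end > start (half-open
        overlap); empty for an unknown chromosome or an empty interval."""
        if end <= start:
            return []
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.peaks[i] for i in hits]

    def save(self, path: str) -> None:
        payload = {
            "magic": DB_MAGIC,
            "version": DB_VERSION,
            "n_peaks": len(self.peaks),
            "peaks": [
                [p.chrom, p.start, p.end, p.accession, p.tf, p.biotype]
                for p in self.peaks
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, separators=(",", ":"), sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "PeakDB":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("magic") != DB_MAGIC:
            raise PeakDBError(f"{path}: not a peak database file")
        if payload.get("version") != DB_VERSION:
            raise PeakDBError(
                f"{path}: unsupported database version {payload.get('version')}"
            )
        return cls([Peak(c, s, e, a, t, b) for c, s, e, a, t, b in payload["peaks"]])


def build_peak_db(bed_paths: list[str], out: str | None = None) -> PeakDB:
    """Parse ReMap-layout BED files into a deterministic, deduplicated DB.

    Records whose name field lacks the accession.TF.biotype layout are
    skipped with a counted warning; identical records are deduplicated.
    Input files may be gzip-compressed.
    """
    peaks: list[Peak] = []
    skipped = 0
    for path in bed_paths:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) < 4:
                    skipped += 1
                    log.warning("%s: line %d: fewer than 4 columns", path, lineno)
                    continue
                try:
                    acc, tf, biotype = parse_peak_name(cols[3])
                    peaks.append(
                        Peak(cols[0], int(cols[1]), int(cols[2]), acc, tf, biotype)
                    )
                except (PeakDBError, ValueError) as exc:
                    skipped += 1
                    log.warning("%s: line %d skipped: %s", path, lineno, exc)
    n_raw = len(peaks)
    db = PeakDB(peaks)
    if len(db) < n_raw:
        log.info("deduplicated %d identical peak records", n_raw - len(db))
    if skipped:
        log.warning("skipped %d malformed peak records", skipped)
    if out is not None:
        db.save(out)
    return db


# ---------------------------------------------------------------------------
# motif -> TF mapping
# ---------------------------------------------------------------------------


class TfMapping:
    """motif id -> canonical TF name, plus an optional TF-family relation.

    Built from two TSVs: (motif_id, tf) and (tf, family_id).  Family
    membership is symmetric within a family id.
    """

    def __init__(
        self,
        motif_to_tf: dict[str, str],
        tf_to_family: dict[str, str] | None = None,
    ):
        self.motif_to_tf = dict(motif_to_tf)
        self._tf_family: dict[str, str] = {}
        self._family_members: dict[str, set[str]] = {}
        for tf, fam in (tf_to_family or {}).items():
            key = normalize_tf_name(tf)
            self._tf_family[key] = fam
            self._family_members.setdefault(fam, set()).add(key)

    @classmethod
    def from_files(
        cls, motif_tsv: str, family_tsv: str | None = None
    ) -> "TfMapping":
        motif_to_tf: dict[str, str] = {}
        with open(motif_tsv) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "motif_id":
                    continue
                motif_to_tf[row[0]] = row[1]
        tf_to_family: dict[str, str] = {}
        if family_tsv is not None:
            with open(family_tsv) as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if not row or row[0].startswith("#") or row[0] == "tf":
                        continue
                    tf_to_family[row[0]] = row[1]
        return cls(motif_to_tf, tf_to_family)

    def canonical_tf(self, motif_id: str) -> str | None:
        return self.motif_to_tf.get(motif_id)

    def family_members(self, tf: str) -> set[str]:
        """Normalized names of all TFs sharing this TF's family (including
        itself); just the TF itself when no family is known."""
        key = normalize_tf_name(tf)
        fam = self._tf_family.get(key)
        if fam is None:
            return {key}
        return set(self._family_members[fam])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakEvidence:
    """Peak-overlap evidence for one disruption result."""

    status: str  # 'evaluated' | 'not_evaluated' | 'unmappable'
    peaks: tuple[Peak, ...] = ()
    biotypes: tuple[str, ...] = ()

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def variant_query_interval(v) -> tuple[int, int]:
    """Reference-genome interval used for the peak overlap query: the
    variant span, widened by 1 base per side for zero-length insertions."""
    if v.vclass == VariantClass.INS:
        return max(0, v.start - 1), v.end + 1
    return v.start, v.end


def annotate_results(
    results: list[DisruptionResult],
    db: PeakDB,
    mapping: TfMapping,
    family_expand: bool = False,
    alpha: float = EVIDENCE_ALPHA,
) -> list[DisruptionResult]:
    """Attach peak evidence to results passing the better-allele p-value
    filter; others get explicit not-evaluated / unmappable markers."""
    out: list[DisruptionResult] = []
    for r in results:
        better = r.ref_match if r.better_allele == "ref" else r.alt_match
        if not (better.pvalue < alpha):
            out.append(replace(r, evidence=PeakEvidence(status="not_evaluated")))
            continue
        tf = mapping.canonical_tf(r.motif_id)
        if tf is None:
            log.warning("motif %s absent from TF mapping", r.motif_id)
            out.append(replace(r, evidence=PeakEvidence(status="unmappable")))
            continue
        wanted = (
            mapping.family_members(tf) if family_expand else {normalize_tf_name(tf)}
        )
        qs, qe = variant_query_interval(r.variant)
        hits = tuple(
            p
            for p in db.query_overlaps(r.variant.chrom, qs, qe)
            if normalize_tf_name(p.tf) in wanted
        )
        biotypes = tuple(sorted({p.biotype for p in hits}))
        out.append(
            replace(
                r,
                evidence=PeakEvidence(
                    status="evaluated", peaks=hits, biotypes=biotypes
                ),
            )
        )
    return out
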