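"""Variant input and normalization.

All internal coordinates are 0-based half-open; conversions from the
1-based conventions of VCF and the custom name-field dialect happen only at
the parse boundary.  Every variant is normalized into a canonical edit:
shared prefix and suffix of ref/alt are trimmed, and pure indels are
left-aligned through repeat tracts (the VCF-normalization convention), so
that an insertion on one allele and the equivalent deletion on the other
always receive the same coordinates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


class VariantClass(str, Enum):
    SNV = "SNV"
    MNV = "MNV"
    INS = "INS"
    DEL = "DEL"
    DELINS = "DELINS"


class VariantError(ValueError):
    """Raised for unparseable or inconsistent variant records."""


@dataclass(frozen=True)
class Variant:
    """A normalized genomic edit.

    ``[start, end)`` is the replaced reference span (``start == end`` for a
    pure insertion); ``ref`` has length ``end - start`` and ``alt`` may be
    empty.  ``ref`` and ``alt`` share no common prefix or suffix.
    """

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    vid: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise VariantError(f"{self.vid}: invalid span [{self.start},{self.end})")
        if len(self.ref) != self.end - self.start:
            raise VariantError(
                f"{self.vid}: ref length {len(self.ref)} inconsistent with span "
                f"[{self.start},{self.end})"
            )
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not set(allele) <= _ACGT:
                raise VariantError(f"{self.vid}: non-ACGT {name} allele {allele!r}")

    @property
    def vclass(self) -> VariantClass:
        nr, na = len(self.ref), len(self.alt)
        if nr == 1 and na == 1:
            return VariantClass.SNV
        if nr == 0 and na > 0:
            return VariantClass.INS
        if na == 0 and nr > 0:
            return VariantClass.DEL
        if nr == na:
            return VariantClass.MNV
        return VariantClass.DELINS

    @property
    def is_indel(self) -> bool:
        return self.vclass in (VariantClass.INS, VariantClass.DEL, VariantClass.DELINS)

    def swapped(self) -> "Variant":
        """The mirrored edit (alt -> ref) at the same locus on the alt
        haplotype's coordinates; used for the ins/del symmetry property."""
        return Variant(
            chrom=self.chrom,
            start=self.start,
            end=self.start + len(self.alt),
            ref=self.alt,
            alt=self.ref,
            vid=self.vid,
        )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _trim(start: int, ref: str, alt: str) -> tuple[int, str, str]:
    # shared suffix first, then shared prefix (order does not matter for a
    # maximal trim; both are applied to exhaustion)
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    return start, ref, alt


def normalize(
    chrom: str,
    start: int,
    ref: str,
    alt: str,
    genome=None,
    vid: str = ".",
) -> Variant:
    """Canonicalize a raw edit: trim shared prefix/suffix, left-align indels.

    ``genome``, when supplied, is any object with
    ``fetch(chrom, start, end) -> str``; it enables the ref-vs-genome check
    and left-alignment through repeat tracts.  Idempotent.
    """
    ref = ref.upper()
    alt = alt.upper()
    if genome is not None and ref:
        observed = genome.fetch(chrom, start, start + len(ref)).upper()
        if observed != ref:
            raise VariantError(
                f"{vid}: ref allele {ref!r} does not match genome "
                f"{observed!r} at {chrom}:{start}-{start + len(ref)}"
            )
    start, ref, alt = _trim(start, ref, alt)
    # left-align pure indels: rotate the indel leftwards while the edit is
    # equivalent (last indel base equals the preceding genome base)
    if genome is not None and (not ref or not alt) and (ref or alt):
        moving = ref or alt
        while start > 0:
            prev = genome.fetch(chrom, start - 1, start).upper()
            if not prev or prev != moving[-1]:
                break
            moving = prev + moving[:-1]
            start -= 1
        if ref:
            ref = moving
        else:
            alt = moving
    end = start + len(ref)
    return Variant(chrom=chrom, start=start, end=end, ref=ref, alt=alt, vid=vid)


def normalize_variant(v: Variant, genome=None) -> Variant:
    return normalize(v.chrom, v.start, v.ref, v.alt, genome=genome, vid=v.vid)


def apply_edit(seq: str, offset: int, v: Variant) -> str:
    """Apply ``v`` to ``seq`` whose first base sits at genomic ``offset``."""
    s, e = v.start - offset, v.end - offset
    if not (0 <= s <= e <= len(seq)):
        raise VariantError(f"{v.vid}: edit outside the provided sequence")
    return seq[:s] + v.alt + seq[e:]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_vcf(path: str, genome=None) -> list[Variant]:
    """Read variants from a VCF 4.x file, one Variant per (record, ALT).

    The VCF anchor-base convention is undone by prefix/suffix trimming and
    coordinates become 0-based half-open.  Symbolic ALTs (<DEL>, breakends)
    and non-ACGT alleles are skipped with a logged warning.
    """
    import pysam

    variants: list[Variant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                if alt.startswith("<") or any(c in alt for c in "[]."):
                    log.warning(
                        "%s:%s skipping symbolic ALT %r", rec.chrom, rec.pos, alt
                    )
                    continue
                if not set(alt) <= _ACGT or not set(ref) <= _ACGT:
                    log.warning(
                        "%s:%s skipping non-ACGT record REF=%r ALT=%r",
                        rec.chrom,
                        rec.pos,
                        ref,
                        alt,
                    )
                    continue
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{ref}:{alt}"
                variants.append(
                    normalize(rec.chrom, rec.start, ref, alt, genome=genome, vid=vid)
                )
    return variants


def read_custom_bed(path: str, genome=None) -> list[Variant]:
    """Read the custom BED-derived variant format.

    BED6 columns chrom,start,end,name,score,strand with the name field
    encoding ``chrom:pos1based:REF:ALT``; "-" denotes an empty allele.  The
    strand column must be "+" or "." (variants are genome-forward).
    """
    variants: list[Variant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise VariantError(f"{path}: line {lineno}: expected >= 4 columns")
            chrom, start_s, end_s, name = cols[:4]
            strand = cols[5] if len(cols) > 5 else "."
            if strand not in ("+", "."):
                raise VariantError(
                    f"{path}: line {lineno}: strand must be '+' or '.', "
                    f"got {strand!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise VariantError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            fields = name.split(":")
            if len(fields) != 4:
                raise VariantError(
                    f"{path}: line {lineno}: name field {name!r} is not "
                    "'chrom:pos:REF:ALT'"
                )
            nchrom, pos_s, ref, alt = fields
            ref = "" if ref == "-" else ref.upper()
            alt = "" if alt == "-" else alt.upper()
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise VariantError(
                    f"{path}: line {lineno}: non-integer position in name field"
                ) from exc
            if nchrom != chrom:
                raise VariantError(
                    f"{path}: line {lineno}: name chrom {nchrom!r} != column "
                    f"chrom {chrom!r}"
                )
            if pos1 - 1 != start:
                raise VariantError(
                    f"{path}: line {lineno}: name position {pos1} (1-based) "
                    f"inconsistent with BED start {start}"
                )
            if end - start != len(ref):
                raise VariantError(
                    f"{path}: line {lineno}: span length {end - start} "
                    f"inconsistent with ref length {len(ref)}"
                )
            variants.append(
                normalize(chrom, start, ref, alt, genome=genome, vid=name)
            )
    return variants


def read_rsid_tsv(path: str, genome=None) -> list[Variant]:
    """Read a local rsID lookup table: columns id, chrom, pos_1based, ref, alt.

    This is the hermetic stand-in for rsID lists — the table itself carries
    the coordinates, so no external database is consulted.
    """
    variants: list[Variant] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#") or row[0] == "id":
                continue
            if len(row) < 5:
                raise VariantError(f"{path}: line {lineno}: expected 5 columns")
            vid, chrom, pos_s, ref, alt = row[:5]
            ref = "" if ref == "-" else ref.upper()
            alt = "" if alt == "-" else alt.upper()
            variants.append(
                normalize(chrom, int(pos_s) - 1, ref, alt, genome=genome, vid=vid)
            )
    return variants


def read_variants(path: str, fmt: str, genome=None) -> list[Variant]:
    """Dispatch on variant input format: vcf, custom (BED dialect) or rsid-tsv."""
    if fmt == "vcf":
        return read_vcf(path, genome=genome)
    if fmt in ("custom", "bed"):
        return read_custom_bed(path, genome=genome)
    if fmt == "rsid-tsv":
        return read_rsid_tsv(path, genome=genome)
    raise ValueError(f"unknown variant format {fmt!r}")
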