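"""Tabular and genome-browser exports of disruption results.

TSV export is lossless: every scalar field of a result, both alleles'
match statistics, the edge-relative coordinates and the peak-evidence
summary are written in a stable column order, and ``parse_tsv`` restores
the result objects exactly (floats go through repr round-tripping).

BED export produces UCSC BED9 (itemRgb dialect with a track line).  Rows
are colored either by disruptiveness (score mode: x = |effect|) or by
motif quality (p-value mode: x = 1 - p/alpha, floored at 0); the score
column is round(1000 x) and the color is drawn from a light-to-dark ramp,
darker = stronger.  Motif matches that exist only inside an inserted
sequence have no reference coordinates; they are exported over the
insertion breakpoint widened by one base, with a note in the name field.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

from .peaks import Peak, PeakEvidence
from .scan import AlleleMatch, DisruptionResult, Geometry
from .variants import Variant

# single-hue light->dark red ramp (strictly decreasing luminance)
DEFAULT_RAMP: tuple[tuple[int, int, int], ...] = (
    (254, 229, 217),
    (252, 174, 145),
    (251, 106, 74),
    (222, 45, 38),
    (165, 15, 21),
)


class ExportError(ValueError):
    pass


@dataclass(frozen=True)
class ExportConfig:
    mode: str = "score_colored"  # 'pvalue_colored' | 'score_colored'
    alpha_filter: float = 1e-4
    top_n: int | None = None  # None = all
    color_ramp: tuple[tuple[int, int, int], ...] = DEFAULT_RAMP

    def __post_init__(self) -> None:
        if self.mode not in ("pvalue_colored", "score_colored"):
            raise ExportError(f"unknown color mode {self.mode!r}")
        if not (0 < self.alpha_filter <= 1):
            raise ExportError("alpha_filter must lie in (0, 1]")
        lum = [luminance(rgb) for rgb in self.color_ramp]
        if any(b >= a for a, b in zip(lum, lum[1:])):
            raise ExportError("color ramp luminance must strictly decrease")


def luminance(rgb: tuple[int, int, int]) -> float:
    r, g, b = rgb
    return 0.299 * r + 0.587 * g + 0.114 * b


COLUMNS = [
    "vid",
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "vclass",
    "motif_id",
    "tf_name",
    "motif_width",
    "ref_raw_score",
    "ref_rel_score",
    "ref_pvalue",
    "ref_strand",
    "ref_win_start",
    "ref_matched_seq",
    "ref_matched",
    "ref_overlaps_variant",
    "alt_raw_score",
    "alt_rel_score",
    "alt_pvalue",
    "alt_strand",
    "alt_win_start",
    "alt_matched_seq",
    "alt_matched",
    "alt_overlaps_variant",
    "effect",
    "direction",
    "strength",
    "geometry",
    "coord_start",
    "coord_end",
    "better_allele",
    "motif_ref_start",
    "motif_ref_end",
    "n_windows",
    "evidence_status",
    "peak_count",
    "peaks",
    "peak_biotypes",
]


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _fmt_opt(x) -> str:
    return "" if x is None else str(x)


def _match_fields(m: AlleleMatch) -> list[str]:
    return [
        _fmt_float(m.raw_score),
        _fmt_float(m.rel_score),
        _fmt_float(m.pvalue),
        m.strand,
        str(m.win_start),
        m.matched_seq,
        str(int(m.matched)),
        str(int(m.overlaps_variant)),
    ]


def _evidence_fields(ev: PeakEvidence | None) -> list[str]:
    if ev is None:
        return ["", "", "", ""]
    peaks = ";".join(
        f"{p.chrom}:{p.start}-{p.end}:{p.name}" for p in ev.peaks
    )
    return [ev.status, str(ev.n_peaks), peaks, ",".join(ev.biotypes)]


def result_to_row(r: DisruptionResult) -> list[str]:
    v = r.variant
    row = [
        v.vid,
        v.chrom,
        str(v.start),
        str(v.end),
        v.ref,
        v.alt,
        v.vclass.value,
        r.motif_id,
        r.tf_name,
        str(r.motif_width),
        *_match_fields(r.ref_match),
        *_match_fields(r.alt_match),
        _fmt_float(r.effect),
        r.direction,
        r.strength,
        r.geometry.value,
        str(r.coord_start),
        str(r.coord_end),
        r.better_allele,
        _fmt_opt(r.motif_ref_start),
        _fmt_opt(r.motif_ref_end),
        str(r.n_windows),
        *_evidence_fields(r.evidence),
    ]
    for cell in row:
        if "\t" in cell or "\n" in cell:
            raise ExportError(f"field contains a tab/newline: {cell!r}")
    return row


def export_tsv(results: list[DisruptionResult], path: str) -> None:
    """Write one row per (variant, motif) result; header-only when empty."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for r in results:
            writer.writerow(result_to_row(r))


def _parse_match(cells: list[str]) -> AlleleMatch:
    return AlleleMatch(
        raw_score=float(cells[0]),
        rel_score=float(cells[1]),
        pvalue=float(cells[2]),
        strand=cells[3],
        win_start=int(cells[4]),
        matched_seq=cells[5],
        matched=bool(int(cells[6])),
        overlaps_variant=bool(int(cells[7])),
    )


def _parse_evidence(cells: list[str]) -> PeakEvidence | None:
    status, count, peaks_s, biotypes_s = cells
    if status == "":
        return None
    peaks = []
    if peaks_s:
        for tok in peaks_s.split(";"):
            loc, name = tok.split(":", 1)[0], tok.split(":", 2)[2]
            chrom = tok.split(":")[0]
            span = tok.split(":")[1]
            s, e = span.split("-")
            acc, tf, biotype = name.split(".", 2)
            peaks.append(Peak(chrom, int(s), int(e), acc, tf, biotype))
    biotypes = tuple(biotypes_s.split(",")) if biotypes_s else ()
    return PeakEvidence(status=status, peaks=tuple(peaks), biotypes=biotypes)


def parse_tsv(path: str) -> list[DisruptionResult]:
    """Inverse of :func:`export_tsv` (lossless round trip)."""
    results: list[DisruptionResult] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != COLUMNS:
            raise ExportError(f"{path}: unexpected column layout")
        for row in reader:
            cells = dict(zip(COLUMNS, row))
            v = Variant(
                chrom=cells["chrom"],
                start=int(cells["start"]),
                end=int(cells["end"]),
                ref=cells["ref"],
                alt=cells["alt"],
                vid=cells["vid"],
            )
            ref_match = _parse_match(row[10:18])
            alt_match = _parse_match(row[18:26])
            results.append(
                DisruptionResult(
                    variant=v,
                    motif_id=cells["motif_id"],
                    tf_name=cells["tf_name"],
                    motif_width=int(cells["motif_width"]),
                    ref_match=ref_match,
                    alt_match=alt_match,
                    effect=float(cells["effect"]),
                    direction=cells["direction"],
                    strength=cells["strength"],
                    geometry=Geometry(cells["geometry"]),
                    coord_start=int(cells["coord_start"]),
                    coord_end=int(cells["coord_end"]),
                    better_allele=cells["better_allele"],
                    motif_ref_start=(
                        int(cells["motif_ref_start"])
                        if cells["motif_ref_start"]
                        else None
                    ),
                    motif_ref_end=(
                        int(cells["motif_ref_end"]) if cells["motif_ref_end"] else None
                    ),
                    n_windows=int(cells["n_windows"]),
                    evidence=_parse_evidence(row[36:40]),
                )
            )
    return results


# ---------------------------------------------------------------------------
# filtering shared by BED/SQL export and the CLI
# ---------------------------------------------------------------------------


def better_pvalue(r: DisruptionResult) -> float:
    m = r.ref_match if r.better_allele == "ref" else r.alt_match
    return m.pvalue


def filter_results(
    results: list[DisruptionResult], alpha: float, top_n: int | None = None
) -> list[DisruptionResult]:
    """Results whose better-allele match p-value is < alpha, optionally
    truncated to the top_n largest |effect| (stable order otherwise)."""
    kept = [r for r in results if better_pvalue(r) < alpha]
    if top_n is not None:
        kept = sorted(kept, key=lambda r: -abs(r.effect))[:top_n]
    return kept


# ---------------------------------------------------------------------------
# BED9 export
# ---------------------------------------------------------------------------


def _color_value(r: DisruptionResult, cfg: ExportConfig) -> float:
    if cfg.mode == "score_colored":
        return min(1.0, abs(r.effect))
    return max(0.0, 1.0 - better_pvalue(r) / cfg.alpha_filter)


def bed_interval(r: DisruptionResult) -> tuple[int, int, str]:
    """Reference interval for a result row and a name-field note.

    The motif span is used when it is representable on the reference;
    matches inside insertions fall back to the breakpoint +/- 1 base with
    an 'ins_breakpoint' note.
    """
    if r.motif_ref_start is not None and r.motif_ref_end is not None:
        return r.motif_ref_start, r.motif_ref_end, ""
    v = r.variant
    return max(0, v.start - 1), v.end + 1, "ins_breakpoint"


def export_bed(
    results: list[DisruptionResult],
    path: str,
    cfg: ExportConfig | None = None,
    track_name: str = "motifdisrupt",
) -> None:
    """Write BED9 (itemRgb) rows for results passing the export filter."""
    cfg = cfg or ExportConfig()
    kept = filter_results(results, cfg.alpha_filter, cfg.top_n)
    ramp = cfg.color_ramp
    with open(path, "w") as fh:
        fh.write(
            f'track name="{track_name}" description="TF motif disruptions" '
            "itemRgb=\"On\"\n"
        )
        for r in kept:
            start, end, note = bed_interval(r)
            x = _color_value(r, cfg)
            score = min(1000, max(0, round(1000 * x)))
            rgb = ramp[min(len(ramp) - 1, math.floor(x * (len(ramp) - 1)))]
            name_bits = [r.variant.vid, r.motif_id, r.geometry.value]
            if note:
                name_bits.append(note)
            strand = (
                r.ref_match.strand if r.better_allele == "ref" else r.alt_match.strand
            )
            fh.write(
                "\t".join(
                    [
                        r.variant.chrom,
                        str(start),
                        str(end),
                        "|".join(name_bits),
                        str(score),
                        strand,
                        str(start),
                        str(end),
                        ",".join(map(str, rgb)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SQL export
# ---------------------------------------------------------------------------

_SQL_TYPES = {
    "start": "INTEGER",
    "end": "INTEGER",
    "motif_width": "INTEGER",
    "ref_win_start": "INTEGER",
    "alt_win_start": "INTEGER",
    "ref_matched": "INTEGER",
    "alt_matched": "INTEGER",
    "ref_overlaps_variant": "INTEGER",
    "alt_overlaps_variant": "INTEGER",
    "coord_start": "INTEGER",
    "coord_end": "INTEGER",
    "motif_ref_start": "INTEGER",
    "motif_ref_end": "INTEGER",
    "n_windows": "INTEGER",
    "peak_count": "INTEGER",
    "ref_raw_score": "REAL",
    "ref_rel_score": "REAL",
    "ref_pvalue": "REAL",
    "alt_raw_score": "REAL",
    "alt_rel_score": "REAL",
    "alt_pvalue": "REAL",
    "effect": "REAL",
}


def export_sql(
    results: list[DisruptionResult], path: str, table: str = "motif_disruptions"
) -> None:
    """Database-agnostic SQL script: CREATE TABLE plus one INSERT per row."""
    cols = ", ".join(
        f'"{c}" {_SQL_TYPES.get(c, "TEXT")}' for c in COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(f'CREATE TABLE "{table}" ({cols});\n')
        for r in results:
            vals = []
            for col, cell in zip(COLUMNS, result_to_row(r)):
                if cell == "":
                    vals.append("NULL")
                elif _SQL_TYPES.get(col) in ("INTEGER", "REAL"):
                    vals.append(cell)
                else:
                    vals.append("'" + cell.replace("'", "''") + "'")
            fh.write(f'INSERT INTO "{table}" VALUES ({", ".join(vals)});\n')
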