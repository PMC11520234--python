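"""Seeded synthetic test-data generator.

Produces a toy genome, a sharp random motif library, variants engineered to
realize each disruption/creation geometry, a matching peak BED in ReMap
layout, TF mapping tables, and a ground-truth manifest — so the whole
pipeline is testable hermetically, without any downloaded genome, motif
database or peak atlas.

Variant plans and what they engineer (motif width w, consensus C):

* ``snv_disrupt``            — substitute the most informative consensus base;
                               the reference carries a perfect site, the
                               alternate does not (direction: disrupted).
* ``del_span``               — delete interior consensus bases; the intact
                               reference match spans the deletion (spanning).
* ``ins_split``              — insert scrambled sequence mid-consensus; the
                               reference match spans the insertion point
                               (spanning).
* ``ins_create_contained``   — insert flank+C+flank into background; the
                               motif exists only inside the insertion
                               (contained; no reference coordinates).
* ``ins_create_edge``        — genome carries the consensus prefix, the
                               insertion supplies the rest, so the created
                               match overlaps the variant's start edge
                               (upstream_overlap).
* ``ins_create_edge_down``   — mirrored: insertion supplies the prefix, the
                               genome the suffix (downstream_overlap).
* ``neutral_far``            — background SNV far from any planted site.

All randomness flows from a single integer seed through one generator, so
the corpus is bit-reproducible.  Planted sites are separated by at least
3w bases to keep their scan window sets disjoint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .motifs import ALPHABET, Motif, revcomp_seq, write_jaspar
from .scan import Geometry
from .variants import Variant, normalize

PLAN_CLASSES = (
    "snv_disrupt",
    "del_span",
    "ins_split",
    "ins_create_contained",
    "ins_create_edge",
    "ins_create_edge_down",
    "neutral_far",
)

INTENDED = {
    # plan -> (direction, geometry or None when variant-class dependent)
    "snv_disrupt": ("disrupted", Geometry.SNV_WINDOW),
    "del_span": ("disrupted", Geometry.SPANNING),
    "ins_split": ("disrupted", Geometry.SPANNING),
    "ins_create_contained": ("created", Geometry.CONTAINED),
    "ins_create_edge": ("created", Geometry.UPSTREAM_OVERLAP),
    "ins_create_edge_down": ("created", Geometry.DOWNSTREAM_OVERLAP),
    "neutral_far": ("any", None),
}


@dataclass
class PlantedCase:
    """One planted (site, variant) ground-truth record."""

    motif_id: str
    tf_name: str
    plan: str
    chrom: str
    site_start: int | None  # consensus start on the reference; None when the
    strand: str  # site exists only on the alt allele
    variant: Variant
    intended_direction: str
    intended_geometry: str | None


@dataclass
class FixtureManifest:
    seed: int
    chrom_lengths: dict[str, int]
    background: tuple[float, float, float, float]
    cases: list[PlantedCase] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "chrom_lengths": self.chrom_lengths,
            "background": list(self.background),
            "cases": [
                {
                    **{
                        k: v
                        for k, v in asdict(c).items()
                        if k not in ("variant", "intended_geometry")
                    },
                    "intended_geometry": c.intended_geometry,
                    "variant": {
                        "chrom": c.variant.chrom,
                        "start": c.variant.start,
                        "end": c.variant.end,
                        "ref": c.variant.ref,
                        "alt": c.variant.alt,
                        "vid": c.variant.vid,
                    },
                }
                for c in self.cases
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "FixtureManifest":
        with open(path) as fh:
            payload = json.load(fh)
        man = cls(
            seed=payload["seed"],
            chrom_lengths=payload["chrom_lengths"],
            background=tuple(payload["background"]),
        )
        for c in payload["cases"]:
            vd = c["variant"]
            man.cases.append(
                PlantedCase(
                    motif_id=c["motif_id"],
                    tf_name=c["tf_name"],
                    plan=c["plan"],
                    chrom=c["chrom"],
                    site_start=c["site_start"],
                    strand=c["strand"],
                    variant=Variant(**vd),
                    intended_direction=c["intended_direction"],
                    intended_geometry=c["intended_geometry"],
                )
            )
        return man


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, length: int, background) -> str:
    bases = rng.choice(list(ALPHABET), size=length, p=list(background))
    return "".join(bases)


def make_genome(
    seed: int,
    chrom_lengths: dict[str, int] | None = None,
    background=(0.25, 0.25, 0.25, 0.25),
) -> dict[str, str]:
    """I.i.d. random genome, deterministic per seed."""
    chrom_lengths = chrom_lengths or {"chrS": 12_000}
    if any(n < 200 for n in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be >= 200")
    rng = np.random.default_rng(seed)
    return {
        chrom: random_sequence(rng, n, background)
        for chrom, n in sorted(chrom_lengths.items())
    }


def write_fasta(genome: dict[str, str], path: str, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    import pyfaidx

    pyfaidx.Faidx(path)  # writes the .fai alongside


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------


def make_motif_library(
    seed: int,
    n_motifs: int = 4,
    widths: tuple[int, ...] = (6, 7, 8, 9),
    sharpness: int = 85,
) -> list[Motif]:
    """Sharp random count-matrix motifs (dominant base ``sharpness`` of 100
    counts per column), with distinct dominant bases guaranteed per column."""
    from .motifs import smooth_matrix

    rng = np.random.default_rng(seed)
    motifs = []
    bg = np.full(4, 0.25)
    for i in range(n_motifs):
        w = int(widths[i % len(widths)])
        counts = np.full((w, 4), (100 - sharpness) // 3, dtype=float)
        for j in range(w):
            counts[j, rng.integers(0, 4)] = sharpness
        motifs.append(
            Motif(
                id=f"M{i + 1:03d}",
                tf_name=f"TF{i + 1}",
                ppm=smooth_matrix(counts, bg, 0.8),
                background=bg,
                pseudocount=0.8,
                counts=counts,
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def _scrambled(rng: np.random.Generator, consensus: str, length: int) -> str:
    """A random sequence of the given length guaranteed not to contain the
    consensus or its reverse complement."""
    for _ in range(100):
        s = "".join(rng.choice(list(ALPHABET), size=length))
        if consensus not in s and revcomp_seq(consensus) not in s:
            return s
    raise RuntimeError("could not draw a consensus-free sequence")


_PERTURB = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _break_chance_consensus(
    seq: list, chrom: str, m: Motif, v: Variant, allele: str, protected: set
) -> None:
    """Ensure the allele that is not supposed to carry a perfect site
    really has none: while its best match attains the maximal score, flip
    one background base inside the offending window.

    Random background can complete a planted partial consensus (or contain
    one outright) with non-negligible probability, which would turn an
    engineered disruption/creation into a tie; this removes such chance
    sites deterministically without touching planted bases, the variant
    span, or the base guarding left-alignment.
    """
    from .scan import SequenceSource, best_match, build_allele_seqs

    for _ in range(40):
        src = SequenceSource({chrom: "".join(seq)})
        ref_a, alt_a = build_allele_seqs(v, m, src)
        a = ref_a if allele == "ref" else alt_a
        bm = best_match(a, m)
        if bm.rel_score < 1.0 - 1e-9:
            return
        changed = False
        for off in range(m.width):
            p = bm.win_start + off
            if allele == "ref":
                gp = a.genome_offset + p
            elif p < a.var_start:
                gp = a.genome_offset + p
            elif p >= a.var_end:
                gp = a.genome_offset + p - len(v.alt) + len(v.ref)
            else:
                continue  # inserted base, not a genome position
            if gp in protected or not (0 <= gp < len(seq)):
                continue
            seq[gp] = _PERTURB[seq[gp]]
            changed = True
            break
        if not changed:
            raise RuntimeError(
                f"{v.vid}: chance consensus on the {allele} allele cannot be "
                "removed without touching protected bases"
            )
    raise RuntimeError(f"{v.vid}: failed to remove chance consensus sites")


def plant_and_mutate(
    genome: dict[str, str],
    motifs: list[Motif],
    plan: list[tuple[str, str]],
    seed: int,
    margin: int = 60,
) -> tuple[dict[str, str], FixtureManifest]:
    """Write consensus sites into the genome and construct plan variants.

    ``plan`` is a list of (motif_id, plan_class) pairs; sites are placed
    left to right on the first chromosome with >= 3w separation.  Returns
    the mutated genome and a manifest recording intended direction and
    geometry per case.
    """
    rng = np.random.default_rng(seed)
    by_id = {m.id: m for m in motifs}
    chrom = sorted(genome)[0]
    seq = list(genome[chrom])
    n = len(seq)
    manifest = FixtureManifest(
        seed=seed,
        chrom_lengths={c: len(s) for c, s in genome.items()},
        background=(0.25, 0.25, 0.25, 0.25),
    )

    cursor = margin
    max_w = max(m.width for m in motifs)
    step = 6 * max_w + 20
    for idx, (motif_id, plan_class) in enumerate(plan):
        if plan_class not in PLAN_CLASSES:
            raise ValueError(f"unknown plan class {plan_class!r}")
        m = by_id[motif_id]
        w = m.width
        cons = m.consensus
        pos = cursor
        cursor += step
        if cursor > n - margin:
            raise ValueError("insufficient room to place non-overlapping sites")

        site_start: int | None = pos
        vid = f"v{idx + 1:03d}_{plan_class}"
        if plan_class == "snv_disrupt":
            seq[pos : pos + w] = cons
            j = int(np.argmax(m.ppm.max(axis=1)))  # most informative column
            ref_base = cons[j]
            alt_base = ALPHABET[int(np.argmin(m.ppm[j]))]
            variant = (pos + j, ref_base, alt_base)
            protected = set(range(pos, pos + w))
        elif plan_class == "del_span":
            if w < 4:
                raise ValueError("del_span needs motif width >= 4")
            seq[pos : pos + w] = cons
            # interior deletion; pick its end so the last deleted base
            # differs from the base before the deletion start, which rules
            # out any left-alignment shift out of the motif
            ds = pos + 1
            for de in range(pos + w - 1, pos + 2, -1):
                if seq[ds - 1] != seq[de - 1]:
                    break
            else:
                raise RuntimeError(
                    f"degenerate consensus {cons!r}: cannot place a stable "
                    "interior deletion"
                )
            variant = (ds, "".join(seq[ds:de]), "")
            protected = set(range(pos, pos + w))
        elif plan_class == "ins_split":
            seq[pos : pos + w] = cons
            ins = _scrambled(rng, cons, w + 2)
            bp = pos + w // 2
            # avoid left-alignment shifting the breakpoint out of the motif
            while ins[-1] == seq[bp - 1]:
                ins = ins[:-1] + ("A" if ins[-1] != "A" else "C")
            variant = (bp, "", ins)
            protected = set(range(pos, pos + w))
        elif plan_class == "ins_create_contained":
            site_start = None
            flank = 3
            ins = (
                _scrambled(rng, cons, flank)
                + cons
                + _scrambled(rng, cons, flank)
            )
            while ins[-1] == seq[pos - 1]:
                ins = ins[:-1] + ("A" if ins[-1] != "A" else "C")
            variant = (pos, "", ins)
            protected = {pos - 1}
        elif plan_class == "ins_create_edge":
            site_start = None
            k = w // 2
            seq[pos - k : pos] = cons[:k]  # genome supplies the prefix
            tail = _scrambled(rng, cons, 5)
            ins = cons[k:] + tail
            while ins[-1] == seq[pos - 1]:
                ins = ins[:-1] + ("A" if ins[-1] != "A" else "C")
            variant = (pos, "", ins)
            protected = set(range(pos - k, pos))
        elif plan_class == "ins_create_edge_down":
            site_start = None
            k = w // 2
            seq[pos : pos + w - k] = cons[k:]  # genome supplies the suffix
            head = _scrambled(rng, cons, 5)
            ins = head + cons[:k]
            if ins[-1] == seq[pos - 1]:
                # ins ends with a fixed consensus base; break the potential
                # left-alignment shift by changing the background base before
                # the breakpoint instead
                seq[pos - 1] = "A" if ins[-1] != "A" else "C"
            variant = (pos, "", ins)
            protected = set(range(pos, pos + w - k)) | {pos - 1}
        else:  # neutral_far
            site_start = None
            ref_base = seq[pos]
            alt_base = ALPHABET[(ALPHABET.index(ref_base) + 1) % 4]
            variant = (pos, ref_base, alt_base)
            protected = set()

        vpos, vref, valt = variant
        direction, geometry = INTENDED[plan_class]
        v_obj = Variant(
            chrom=chrom,
            start=vpos,
            end=vpos + len(vref),
            ref=vref,
            alt=valt,
            vid=vid,
        )
        if direction == "disrupted":
            _break_chance_consensus(seq, chrom, m, v_obj, "alt", protected)
        elif direction == "created":
            _break_chance_consensus(seq, chrom, m, v_obj, "ref", protected)
        manifest.cases.append(
            PlantedCase(
                motif_id=motif_id,
                tf_name=m.tf_name,
                plan=plan_class,
                chrom=chrom,
                site_start=site_start,
                strand="+",
                variant=Variant(
                    chrom=chrom,
                    start=vpos,
                    end=vpos + len(vref),
                    ref=vref,
                    alt=valt,
                    vid=vid,
                ),
                intended_direction=direction,
                intended_geometry=None if geometry is None else geometry.value,
            )
        )

    mutated = dict(genome)
    mutated[chrom] = "".join(seq)
    # verify normalization stability: every planted variant must already be
    # in canonical form against the mutated genome
    from .scan import SequenceSource

    src = SequenceSource(mutated)
    for case in manifest.cases:
        norm = normalize(
            case.variant.chrom,
            case.variant.start,
            case.variant.ref,
            case.variant.alt,
            genome=src,
            vid=case.variant.vid,
        )
        if norm != case.variant:
            raise RuntimeError(
                f"fixture construction bug: {case.variant.vid} not canonical "
                f"({case.variant} -> {norm})"
            )
    return mutated, manifest


# ---------------------------------------------------------------------------
# peaks and mapping tables
# ---------------------------------------------------------------------------


def make_peaks(
    manifest: FixtureManifest,
    path: str,
    jitter: int = 0,
    n_decoys: int = 0,
    decoy_over_site_tf: str | None = None,
    half_width: int = 30,
    seed: int = 0,
) -> int:
    """Write a ReMap-layout peak BED: one peak per planted case (over the
    variant site, TF of the planted motif), optional random decoys with a
    wrong TF, and optional same-position decoys with ``decoy_over_site_tf``
    (for family-expansion tests).  Returns the number of rows written."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, case in enumerate(manifest.cases):
        if case.plan == "neutral_far":
            continue
        v = case.variant
        j1 = int(rng.integers(0, jitter + 1))
        j2 = int(rng.integers(0, jitter + 1))
        start = max(0, v.start - half_width - j1)
        end = v.end + half_width + j2
        rows.append(
            (case.chrom, start, end, f"EXP{i + 1:04d}.{case.tf_name}.synthcell")
        )
        if decoy_over_site_tf is not None:
            rows.append(
                (
                    case.chrom,
                    start,
                    end,
                    f"DEC{i + 1:04d}.{decoy_over_site_tf}.decoycell",
                )
            )
    chrom = next(iter(manifest.chrom_lengths))
    n = manifest.chrom_lengths[chrom]
    for d in range(n_decoys):
        s = int(rng.integers(0, n - 100))
        rows.append((chrom, s, s + 80, f"RND{d + 1:04d}.ZZZDECOY.randomcell"))
    with open(path, "w") as fh:
        for chrom_, s, e, name in rows:
            fh.write(f"{chrom_}\t{s}\t{e}\t{name}\t0\t.\n")
    return len(rows)


def write_tf_map(motifs: list[Motif], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttf\n")
        for m in motifs:
            fh.write(f"{m.id}\t{m.tf_name}\n")


def write_family_map(
    motifs: list[Motif], path: str, extra_member_suffix: str = "B"
) -> None:
    """Family table grouping each TF with a sibling '<TF><suffix>' (the
    sibling is the decoy TF used to exercise family expansion)."""
    with open(path, "w") as fh:
        fh.write("tf\tfamily_id\n")
        for i, m in enumerate(motifs):
            fh.write(f"{m.tf_name}\tFAM{i + 1}\n")
            fh.write(f"{m.tf_name}{extra_member_suffix}\tFAM{i + 1}\n")


# ---------------------------------------------------------------------------
# variant serialization (VCF / custom BED)
# ---------------------------------------------------------------------------


def write_vcf(
    variants: list[Variant], genome: dict[str, str], path: str
) -> None:
    """Minimal VCF 4.2 with the anchor-base convention for indels."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=motifdisrupt-fixtures",
    ]
    for chrom, seq in sorted(genome.items()):
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda x: (x.chrom, x.start)):
        if v.ref and v.alt and len(v.ref) == len(v.alt):
            pos1 = v.start + 1
            ref, alt = v.ref, v.alt
        else:  # indel: prepend the anchor base
            anchor = genome[v.chrom][v.start - 1]
            pos1 = v.start  # 1-based position of the anchor base
            ref = anchor + v.ref
            alt = anchor + v.alt
        lines.append(
            f"{v.chrom}\t{pos1}\t{v.vid}\t{ref}\t{alt}\t.\tPASS\t."
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_custom_bed(variants: list[Variant], path: str) -> None:
    with open(path, "w") as fh:
        for v in variants:
            ref = v.ref or "-"
            alt = v.alt or "-"
            name = f"{v.chrom}:{v.start + 1}:{ref}:{alt}"
            fh.write(f"{v.chrom}\t{v.start}\t{v.end}\t{name}\t0\t+\n")


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

DEFAULT_PLAN_CLASSES = (
    "snv_disrupt",
    "del_span",
    "ins_split",
    "ins_create_contained",
    "ins_create_edge",
    "ins_create_edge_down",
    "neutral_far",
    "neutral_far",
)


def make_bundle(outdir: str, seed: int = 1, n_motifs: int = 4) -> FixtureManifest:
    """Write a complete hermetic fixture bundle into ``outdir``.

    Files: genome.fa(+.fai), motifs.jaspar, variants.vcf, variants.bed,
    peaks.bed, tfmap.tsv, family.tsv, manifest.json.  Each motif receives
    one variant of each plan class (cycled), on one 12 kb chromosome.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    motifs = make_motif_library(seed + 1, n_motifs=n_motifs)
    genome = make_genome(seed, {"chrS": 12_000})
    plan = [
        (motifs[i % len(motifs)].id, cls)
        for i, cls in enumerate(DEFAULT_PLAN_CLASSES)
    ]
    mutated, manifest = plant_and_mutate(genome, motifs, plan, seed + 2)
    write_fasta(mutated, os.path.join(outdir, "genome.fa"))
    write_jaspar(motifs, os.path.join(outdir, "motifs.jaspar"))
    variants = [c.variant for c in manifest.cases]
    write_vcf(variants, mutated, os.path.join(outdir, "variants.vcf"))
    write_custom_bed(variants, os.path.join(outdir, "variants.bed"))
    make_peaks(manifest, os.path.join(outdir, "peaks.bed"), seed=seed + 3)
    write_tf_map(motifs, os.path.join(outdir, "tfmap.tsv"))
    write_family_map(motifs, os.path.join(outdir, "family.tsv"))
    manifest.to_json(os.path.join(outdir, "manifest.json"))
    return manifest
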