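# motifdisrupt

Predict whether a genetic variant disrupts — or creates — a transcription
factor (TF) binding site, for single-nucleotide variants, multi-nucleotide
variants, and short insertions/deletions.

Regulatory variants act largely by changing TF binding, and position weight
matrix (PWM) matching remains the standard first-pass hypothesis generator
for this. Most PWM-scanning tools only handle substitutions cleanly; indels
are harder because the two alleles have different lengths and a motif match
can exist *only inside an inserted sequence*, where it has no reference-genome
coordinates at all. `motifdisrupt` is a Python library and CLI for exactly
this problem: it scores both alleles of any short variant, reports exact
match p-values, locates matches over indels in an edge-relative coordinate
system, and can attach *in vivo* ChIP-seq peak evidence from a local,
ReMap-layout BED database.

## The method

For a motif of width *w* (a position probability matrix `p[i][b]` over
A/C/G/T, smoothed with a background-proportional pseudocount) and a variant
with normalized alleles REF/ALT, both allele sequences are built with exactly
*w* − 1 bases of genomic context per side — the minimal set such that every
width-*w* window that can overlap the variant is scanned, and no other.
Each window is scored on both strands with the log-odds score

    S = Σᵢ log₂( p[i][bᵢ] / q[bᵢ] )

against background frequencies *q*, and each allele's reported match is the
highest-scoring window (equivalently, the one with the lowest match
p-value, since the p-value is monotone in the score). Scores are min–max
normalized to a relative score in [0, 1] over the motif's attainable range,
and the effect size is

    effect = rel(best ALT match) − rel(best REF match)

so negative effects are disruptions and positive effects are created sites.

**Exact p-values.** The null distribution of S for a random width-*w*
window is computed exactly: per-position scores are rounded to integer
multiples of a granularity ε (default: score span / 10 000) and convolved
across positions by dynamic programming, giving P(S ≥ s) without sampling
or Gaussian approximation.

**Edge-relative indel coordinates.** A match over an indel is located by
two signed offsets: `coord_start` = motif start − variant start edge and
`coord_end` = motif end − variant end edge (negative = upstream, positive =
downstream, 0 = exact edge coincidence). This classifies every indel/motif
configuration into one of four geometries — `upstream_overlap`,
`contained`, `downstream_overlap`, `spanning` — and makes matches created
inside insertions (which have no reference coordinates) locatable.
Insertions and deletions are treated symmetrically: an insertion on one
allele is the mirrored deletion on the other, and swapping alleles exactly
negates the effect.

**Peak evidence.** Sequence preference alone over-predicts binding. Results
whose better-allele match p-value passes an evidence filter (default
P < 1e−4) can be annotated with overlapping ChIP-seq peaks from a local
database built from BED files in the ReMap layout (name field
`accession.TF.biotype`), matched to the motif's canonical TF — optionally
expanded to the whole TF family — with the experiment biotypes attached.

## Worked example

Everything below is hermetic — the `fixtures` subcommand generates a seeded
toy genome with planted consensus sites, engineered variants, and a matching
peak BED:

```bash
motifdisrupt fixtures --outdir bundle --seed 1
motifdisrupt scan --variants bundle/variants.vcf --genome bundle/genome.fa \
                  --motifs bundle/motifs.jaspar --out-prefix run
motifdisrupt builddb bundle/peaks.bed --out peaks.db.json
motifdisrupt annotate --results run.tsv --peakdb peaks.db.json \
                      --tf-map bundle/tfmap.tsv --out annotated.tsv
motifdisrupt export --results annotated.tsv --to bed --out track.bed
```

which prints

```
wrote fixture bundle with 8 planted cases to bundle
scanned 8 variants x 4 motifs -> 32 results (run.tsv)
wrote 6 peaks to peaks.db.json
annotated 4/32 results -> annotated.tsv
wrote track.bed
```

Two rows of `annotated.tsv` (selected columns):

| vid | motif | effect | direction | geometry | coords | ref_p | alt_p | peaks |
|-----|-------|--------|-----------|----------|--------|-------|-------|-------|
| v002_del_span | M002 | −0.429 | disrupted | spanning | (−1, +1) | 6.1e−05 | 1.3e−02 | 1 |
| v004_ins_create_contained | M004 | +0.556 | created | contained | (+3, −3) | 1.7e−01 | 3.8e−06 | 1 |

The first is a deletion inside a planted M002 consensus: the reference
allele carries a perfect site (relative score 1.0, match p-value
6.1e−05 = 0.25⁷ for this width-7 motif), the alternate allele's best match
drops by 0.43, and the intact match starts 1 base upstream of the deletion
start and ends 1 base downstream of its end — geometry `spanning`. The
second is an insertion that *creates* a perfect M004 site entirely within
the inserted sequence: `coord_start` +3 / `coord_end` −3 place the motif
3 bases inside each edge of the insertion, a position that cannot be
expressed in reference coordinates. Both pass the P < 1e−4 evidence filter
and pick up exactly the one ChIP-seq peak planted over them.

`track.bed` is a UCSC-ready BED9 track, colored light→dark by
disruptiveness (`--color-mode score`) or motif quality (`--color-mode
pvalue`):

```
track name="motifdisrupt" description="TF motif disruptions" itemRgb="On"
chrS	134	141	v002_del_span|M002|spanning	429	+	134	141	252,174,145
```

The same pipeline is available as a library (`read_vcf`, `read_jaspar_pfm`,
`scan_variants`, `build_peak_db`, `annotate_results`, `export_bed`, ...);
see `docs/methods.md` for the model details and conventions.

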