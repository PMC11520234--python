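# Methods

This note documents the model, the conventions every output relies on, the
numerical choices, what the synthetic data generator does and does not
emulate, and the known limitations.

## Motif model and scoring

A motif is a position probability matrix (PPM) over A/C/G/T. Count or
frequency matrices from JASPAR PFM or MEME minimal files are smoothed with
a pseudocount distributed proportionally to the background:

    ppm[i][b] = (count[i][b] + pc * q[b]) / (N_i + pc)

with column total `N_i`, background `q` and total pseudocount `pc`
(default 0.8). This keeps every probability strictly positive (finite
log-odds) and, for columns with a strict maximum, never changes the
consensus base. The default background is uniform unless the MEME file
supplies one or the caller overrides it; a per-genome background estimator
is deliberately out of scope.

Windows are scored with log2 odds, `S = Σ log2(ppm[i][bᵢ]/q[bᵢ])`. Log
base is a presentation choice only — every exposed quantity is either an
ordering, a min–max normalized relative score
`rel = (S − S_min)/(S_max − S_min)`, or a p-value, all invariant to the
base. The consensus (per-column argmax) attains `S_max` exactly; the
per-column argmin string attains `S_min` (as a single-strand window —
the double-strand best match of any sequence can exceed it via the other
strand).

Several PWM scoring variants exist (probability sums, information-content
weighting); this package standardizes on log-odds with the normalized
relative score, and the scan manifest records that convention in every run.

## Exact match p-values

The match p-value of a score s is P(S ≥ s) for a random width-w window
drawn i.i.d. from the motif's stored background (one source of truth per
motif; callers may override the null background explicitly). The
distribution is computed exactly by dynamic programming: per-column scores
are rounded to integer multiples of a granularity ε and the distribution
of their sum is built by iterated convolution — O(w · range · 4) with
range ≈ span/ε bins.

* Default ε = (S_max − S_min)/10 000, so discretization error is far below
  reporting precision while the DP stays ~10⁴ bins.
* Query scores are binned as floor(s/ε + 0.5) and clamp to the support:
  per-column rounding can drift the rounded sum of an attainable score by
  up to w/2 bins past the end bins, so scores within the attainable range
  clamp to the boundary bin, while scores strictly above `S_max` return 0
  and scores at or below `S_min` return 1.
* A granularity so coarse that a non-degenerate motif collapses to one bin
  is rejected; a truly degenerate motif (all columns uniform) is a point
  mass at 0 and threshold queries on it are flagged unattainable.
* The p-value is per window — a *match* p-value, not corrected for the
  number of windows scanned. The window count is reported in every result
  (`n_windows`) so users can apply their own multiplicity correction.
* Exactness is verified against full 4^w enumeration (bin-for-bin,
  < 1e−12) for widths up to 8 in the test suite and acceptance script.

## Variant normalization

Internal coordinates are 0-based half-open everywhere; VCF (1-based,
anchor-base convention) and the custom BED name-field dialect
(`chrom:pos1:REF:ALT`, "-" = empty allele) are converted at the parse
boundary only. Every edit is canonicalized: shared prefix/suffix trimmed
to exhaustion, then pure indels left-aligned through repeat tracts (the
VCF-normalization convention) — normalization is idempotent and never
changes the edited haplotype, which the property tests check by direct
haplotype comparison. Variants are classified SNV / MNV / INS / DEL /
DELINS from the trimmed allele lengths. rsID input is a local TSV carrying
its own coordinates; no network lookup exists. Overlapping variants are
scored independently, never as joint haplotypes.

## Scanning and the effect size

For motif width w, both allele sequences take exactly w − 1 context bases
per side: the minimal window set that contains every width-w window
overlapping the variant and nothing else. Both strands of both alleles
are scanned; ties between equal scores break to the smaller window start,
then the + strand, making every output deterministic. Windows containing
non-ACGT bases are skipped; if all windows are skipped the allele gets a
flagged sentinel (p-value 1, relative score 0).

`effect = rel(alt best) − rel(ref best)`; negative = disrupted, positive =
created. The sign convention is stated in the run manifest because the
plain phrase "difference between the best matches" is ambiguous. Strength
bands are |effect| ≥ 0.4 (strong) and ≥ 0.1 (weak) — configuration
defaults with no claim of biological calibration; both are CLI flags. The
best match is reported per allele even when it does not overlap that
allele's variant span (the window set guarantees overlap on at least one
allele); an `overlaps_variant` flag records it.

## Edge-relative indel coordinates and geometry

With m_s/m_e the first/last base (0-based inclusive) of the match and the
variant occupying [v_s, v_e) of the allele sequence:

    coord_start = m_s − v_s          coord_end = (m_e + 1) − v_e

Negative = upstream, positive = downstream, and 0 = exact edge coincidence
(start-anchored for coord_start, end-anchored half-open for coord_end).
A no-zero counting convention was considered and rejected: arithmetic on
the chosen convention is plain subtraction, and equality-to-zero is a
meaningful, testable edge case. Geometry classes follow from the signs:

| coord_start | coord_end | geometry |
|---|---|---|
| < 0 | > 0 | spanning |
| ≥ 0 | ≤ 0 | contained |
| < 0 | ≤ 0 | upstream_overlap |
| ≥ 0 | > 0 | downstream_overlap |

computed on the better-scoring allele's match (SNVs/MNVs are labelled
`snv_window`; their edge coordinates are still reported). When the two
alleles tie exactly, the "better" allele is chosen by a swap-invariant
rule — shorter allele string, then lexicographically smaller — so the
mirror symmetry (swap ref/alt ⇒ effect negates, matches swap, geometry
unchanged) holds even on ties.

## Peak database and annotation

Peak BEDs use the ReMap layout: name field `accession.TF.biotype`, periods
past the second belonging to the biotype. The database is a deduplicated,
(chrom, start)-sorted list serialized as a single JSON file with a magic
string and version — byte-identical across rebuilds from identical inputs
— re-indexed with a per-chromosome interval tree on load. Overlap is
half-open; queries match a linear-scan oracle on randomized corpora.

Annotation attaches peaks only to results whose better-allele p-value is
below the evidence threshold (default 1e−4); others are explicitly marked
`not_evaluated` (and motifs missing from the TF mapping `unmappable`) —
never silently dropped. TF names are matched case-insensitively with
separator normalization ("NKX2-1" ≡ "NKX2.1"), optionally expanded to the
TF family given a two-column (tf, family_id) TSV. Pure insertions occupy a
zero-length reference interval, so their overlap query is widened by one
base per side of the breakpoint — a documented choice, since a zero-length
interval can never overlap a half-open peak.

## Exports

TSV export is lossless (floats via repr) and `parse_tsv` restores results
exactly, so the annotate/export subcommands operate on scan output files.
BED9 export emits a UCSC `itemRgb` track; score column = round(1000·x)
with x = |effect| (score mode) or max(0, 1 − p/α) (p-value mode), color =
5-step single-hue red ramp (254,229,217 → 165,15,21), strictly decreasing
luminance so darker always means stronger. Matches contained in insertions
are exported over the breakpoint ±1 with an `ins_breakpoint` name note.
SQL export is a database-agnostic CREATE TABLE + INSERT script with the
TSV columns. Default export filter: better-allele p < 1e−4, configurable;
both alleles' statistics are always printed for reported pairs.

## Synthetic data generator

The fixture generator emulates exactly the situations the scanner must
classify: a 12 kb i.i.d. background genome (uniform base composition),
four sharp count-matrix motifs (widths 6–9, dominant base 85/100 per
column — an information content typical of curated TF motifs), and one
variant per plan class: consensus-breaking SNV, interior deletion and
mid-motif insertion (both `spanning` from the intact reference match),
insertions creating a site fully inside the insertion (`contained`) or
completing a planted half-site on either edge (`upstream_overlap` /
`downstream_overlap`), plus far-from-site background SNVs as negative
controls. Sites are separated by ≥ 6·w_max bases so scan windows never
interfere. One peak per engineered case (±30 bp) is written in ReMap
layout with decoy options for the family-expansion tests.

Because random background can, with small but real probability, complete a
planted half-site (or contain a chance consensus near the variant), the
generator verifies by scanning that the allele meant to lack a perfect
site really does, and flips single background bases — never planted bases,
the variant span, or the base that pins left-alignment — until that holds.
It also verifies every engineered variant is already in canonical
normalized form against the mutated genome, so manifest coordinates are
exactly what the pipeline sees.

What the generator does *not* emulate: realistic GC content or repeat
structure, population variant spectra, overlapping/phased variants, soft
motif matches (planted sites are perfect consensi), or ReMap-scale peak
density. Passing tests therefore demonstrate correctness of the scoring,
coordinate and annotation *mechanics* under controlled truth, not
biological accuracy of disruption calls on real genomes.

## Problem sizes and determinism

Randomized checks run at: 20 motifs × full 4^w enumeration (w ≤ 8) for
p-value exactness; 1 000 (sequence, motif) scan pairs (L ≤ 50, w ≤ 10);
200 indel mirror pairs; 50 SNV window enumerations; 1 000 interval queries
against 5 000 peaks — sizes at which the brute-force oracles remain exact
and fast. All randomness flows from one integer seed; the CLI is
deterministic given fixed inputs (the run manifest's timestamp is the only
varying byte across repeated runs).

## Known limitations

* Alphabet fixed to ACGT; no IUPAC-ambiguity motifs, no higher-order or
  dinucleotide background models.
* No joint scoring of nearby variants on one haplotype; no structural
  variants or breakends.
* The evidence filter conditions on the better allele's match p-value —
  evidence concerns whether a site exists on either allele — so a strong
  site destroyed on the alternate allele and a site created by it are
  treated symmetrically.
* P-values are per-window; genome-wide scanning multiplicity is the
  caller's responsibility (`n_windows` is provided).
* Peak databases must match the variant coordinate assembly; no liftover
  is performed.
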