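"""Allele-sequence construction, best-match scanning, effect sizes and
edge-relative indel coordinates."""

import numpy as np
import pytest

from motifdisrupt import (
    Geometry,
    SequenceSource,
    best_match,
    build_allele_seqs,
    build_distribution,
    score_variant,
)
from motifdisrupt.motifs import revcomp_seq, reverse_complement
from motifdisrupt.scan import AlleleSeq, ScanError, indel_coordinates
from motifdisrupt.variants import Variant, apply_edit, normalize

from oracles import naive_best_match, random_count_motif, random_seq


def _allele(seq, v_s=0, v_e=0):
    return AlleleSeq(seq, v_s, v_e, 0, "c")


class TestBuildAlleleSeqs:
    def test_snv_window_lengths(self, sharp_motif, dict_genome):
        g = dict_genome({"c": "A" * 30})
        v = Variant("c", 15, 16, "A", "C")
        ref, alt = build_allele_seqs(v, sharp_motif, g)  # w=6
        assert len(ref.seq) == 11 and len(alt.seq) == 11
        assert ref.seq[5] == "A" and alt.seq[5] == "C"
        assert ref.seq[:5] == alt.seq[:5] and ref.seq[6:] == alt.seq[6:]

    def test_deletion_window_lengths(self, sharp_motif, dict_genome):
        g = dict_genome({"c": "ACGT" * 10})
        v = Variant("c", 15, 19, "TACG", "")
        ref, alt = build_allele_seqs(v, sharp_motif, g)
        assert len(ref.seq) == 14 and len(alt.seq) == 10
        assert (alt.var_start, alt.var_end) == (5, 5)  # empty breakpoint span

    def test_insertion_window_lengths(self, sharp_motif, dict_genome):
        g = dict_genome({"c": "ACGT" * 10})
        v = Variant("c", 15, 15, "", "G" * 10)
        ref, alt = build_allele_seqs(v, sharp_motif, g)
        assert len(ref.seq) == 10 and len(alt.seq) == 20
        assert (ref.var_start, ref.var_end) == (5, 5)
        assert (alt.var_start, alt.var_end) == (5, 15)

    def test_unknown_chromosome_rejected(self, sharp_motif, dict_genome):
        g = dict_genome({"c": "ACGT" * 10})
        with pytest.raises(ScanError, match="absent"):
            build_allele_seqs(Variant("zz", 5, 6, "A", "C"), sharp_motif, g)

    def test_edge_clipping(self, sharp_motif, dict_genome):
        g = dict_genome({"c": "ACGTACGTACGT"})
        v = Variant("c", 1, 2, "C", "T")
        ref, alt = build_allele_seqs(v, sharp_motif, g)
        assert ref.clipped_left and not ref.clipped_right
        assert ref.genome_offset == 0 and len(ref.seq) == 7


class TestBestMatch:
    def test_consensus_attains_relative_one(self, sharp_motif):
        m = best_match(_allele(sharp_motif.consensus), sharp_motif)
        assert m.rel_score == pytest.approx(1.0)
        assert m.win_start == 0 and m.strand == "+"

    def test_anticonsensus_window_attains_min_score(self, sharp_motif):
        """The per-column-minimum sequence scores min_score (relative 0) as
        a forward window; the double-strand best match can only exceed it."""
        anti = sharp_motif.anticonsensus
        assert sharp_motif.score_window(anti) == pytest.approx(
            sharp_motif.min_score, abs=1e-12
        )
        assert sharp_motif.relative(sharp_motif.score_window(anti)) == 0.0
        m = best_match(_allele(anti), sharp_motif)
        assert m.rel_score >= 0.0

    def test_equals_naive_double_strand_scan(self, rng):
        """Exhaustive random cross-check against the naive O(L*w) scan,
        including score, strand and the leftmost/plus tie-break."""
        for _ in range(200):
            w = int(rng.integers(1, 11))
            L = int(rng.integers(w, 51))
            m = random_count_motif(rng, w)
            seq = random_seq(rng, L)
            got = best_match(_allele(seq), m)
            score, strand, start = naive_best_match(seq, m)
            assert got.raw_score == score
            assert (got.strand, got.win_start) == (strand, start)

    def test_n_windows_skipped(self, sharp_motif):
        seq = "NN" + sharp_motif.consensus + "NN"
        m = best_match(_allele(seq), sharp_motif)
        assert m.matched and m.rel_score == pytest.approx(1.0)
        assert m.win_start == 2

    def test_all_n_sentinel(self, sharp_motif):
        m = best_match(_allele("N" * 10), sharp_motif)
        assert not m.matched
        assert m.pvalue == 1.0 and m.rel_score == 0.0

    def test_reverse_complement_consistency(self, rng):
        """best_match on the reverse-complemented sequence finds the same
        match with opposite strand and mirrored position."""
        for _ in range(30):
            w = int(rng.integers(2, 9))
            L = int(rng.integers(w + 3, 40))
            m = random_count_motif(rng, w)
            seq = random_seq(rng, L)
            fwd = best_match(_allele(seq), m)
            rev = best_match(_allele(revcomp_seq(seq)), m)
            assert rev.raw_score == pytest.approx(fwd.raw_score, abs=1e-9)

    def test_pvalue_attached_and_monotone_with_score(self, rng):
        m = random_count_motif(rng, 6)
        sd = build_distribution(m)
        hits = []
        for _ in range(20):
            hit = best_match(_allele(random_seq(rng, 30)), m, sd)
            hits.append(hit)
        hits.sort(key=lambda h: h.raw_score)
        pv = [h.pvalue for h in hits]
        assert all(a >= b for a, b in zip(pv, pv[1:]))


class TestIndelCoordinates:
    """The two-number edge-relative coordinate convention: coord_start is
    the motif start minus the variant start, coord_end the motif end minus
    the variant end (half-open); 0 = exact edge coincidence."""

    def _match(self, win_start):
        from motifdisrupt.scan import AlleleMatch

        return AlleleMatch(0, 0, 1, "+", win_start, "", True, True)

    def test_contained_in_insertion(self):
        # 10-bp insertion allele, w=6 motif starting at offset 2 within it
        a = _allele("X" * 25, v_s=5, v_e=15)
        geom, cs, ce = indel_coordinates(self._match(7), a, 6)
        assert (geom, cs, ce) == (Geometry.CONTAINED, 2, -2)

    def test_upstream_overlap(self):
        # w=6 motif starting 2 bases before the insertion, ending inside it
        a = _allele("X" * 25, v_s=5, v_e=15)
        geom, cs, ce = indel_coordinates(self._match(3), a, 6)
        assert (geom, cs, ce) == (Geometry.UPSTREAM_OVERLAP, -2, -6)

    def test_downstream_overlap(self):
        a = _allele("X" * 25, v_s=5, v_e=15)
        geom, cs, ce = indel_coordinates(self._match(13), a, 6)
        assert geom == Geometry.DOWNSTREAM_OVERLAP and cs == 8 and ce == 4

    def test_spanning_deletion_seen_from_reference(self):
        # ref allele of a 4-bp deletion; motif starts 1 base before the
        # deleted span and ends 1 base after it
        a = _allele("X" * 20, v_s=5, v_e=9)
        geom, cs, ce = indel_coordinates(self._match(4), a, 6)
        assert (geom, cs, ce) == (Geometry.SPANNING, -1, 1)

    def test_exact_edge_coincidence_is_zero(self):
        a = _allele("X" * 20, v_s=5, v_e=9)
        geom, cs, ce = indel_coordinates(self._match(5), a, 4)
        assert (cs, ce) == (0, 0)
        assert geom == Geometry.CONTAINED


class TestScoreVariant:
    def test_planted_consensus_disruption(self, sharp_motif, dict_genome):
        cons = sharp_motif.consensus  # ACGTAC
        seq = "GGTTGG" + cons + "GGTTGG"
        g = dict_genome({"c": seq})
        v = normalize("c", 8, "G", "A", genome=g)  # break the max-info column
        r = score_variant(v, sharp_motif, g)
        assert r.ref_match.rel_score == pytest.approx(1.0)
        assert r.effect < 0 and r.direction == "disrupted"
        assert r.geometry == Geometry.SNV_WINDOW

    def test_equal_alleles_score_neutral(self, sharp_motif, dict_genome):
        """A substitution between two bases the motif weighs identically
        leaves the best match unchanged: effect 0, strength neutral."""
        g = dict_genome({"c": "GGGGGGTTTTTTGGGGGG"})
        v = Variant("c", 9, 10, "T", "G")
        r = score_variant(v, sharp_motif, g)
        assert r.strength in ("neutral", "weak")  # no planted site near

    def test_swap_negates_effect_exactly(self, rng, dict_genome):
        """Scoring the mirrored edit on the alternate haplotype negates the
        effect and swaps the per-allele matches (ins/del symmetry)."""
        for _ in range(40):
            w = int(rng.integers(3, 9))
            m = random_count_motif(rng, w)
            seq = random_seq(rng, 80)
            s = int(rng.integers(30, 45))
            ln = int(rng.integers(0, 5))
            ref = seq[s : s + ln]
            alt = random_seq(rng, int(rng.integers(0 if ln else 1, 6)))
            g = dict_genome({"c": seq})
            try:
                v = normalize("c", s, ref, alt, genome=g)
            except Exception:
                continue
            if not v.ref and not v.alt:
                continue
            hap = apply_edit(seq, 0, v)
            g2 = dict_genome({"c": hap})
            vs = v.swapped()
            r1 = score_variant(v, m, g)
            r2 = score_variant(vs, m, g2)
            assert r2.effect == pytest.approx(-r1.effect, abs=1e-12)
            assert r2.ref_match.raw_score == pytest.approx(
                r1.alt_match.raw_score, abs=1e-12
            )
            assert r2.alt_match.raw_score == pytest.approx(
                r1.ref_match.raw_score, abs=1e-12
            )
            # geometry computed on the same better allele agrees
            assert (r2.geometry, r2.coord_start, r2.coord_end) == (
                r1.geometry,
                r1.coord_start,
                r1.coord_end,
            )

    def test_snv_equals_window_enumeration(self, rng, dict_genome):
        """For an SNV the per-allele best equals direct enumeration of the
        2w-1 variant-overlapping windows on each haplotype."""
        for _ in range(25):
            w = int(rng.integers(2, 9))
            m = random_count_motif(rng, w)
            seq = random_seq(rng, 60)
            s = int(rng.integers(20, 40))
            alt_base = "ACGT"[("ACGT".index(seq[s]) + 1) % 4]
            g = dict_genome({"c": seq})
            v = Variant("c", s, s + 1, seq[s], alt_base)
            r = score_variant(v, m, g)
            for allele_seq, got in (
                (seq[s - (w - 1) : s + w], r.ref_match),
                (
                    seq[s - (w - 1) : s] + alt_base + seq[s + 1 : s + w],
                    r.alt_match,
                ),
            ):
                score, strand, start = naive_best_match(allele_seq, m)
                assert got.raw_score == score

    def test_strength_thresholds(self, sharp_motif, dict_genome):
        cons = sharp_motif.consensus
        seq = "GGTTGG" + cons + "GGTTGG"
        g = dict_genome({"c": seq})
        v = normalize("c", 6, cons, "", genome=g)  # delete the whole site
        r = score_variant(v, sharp_motif, g, strong_threshold=0.05)
        assert r.strength == "strong" and r.direction == "disrupted"

    def test_monotone_under_fixture_degradation(self, sharp_motif, dict_genome):
        """Degrading the alt allele point by point never increases the
        effect."""
        cons = sharp_motif.consensus
        seq = "GGTTGG" + cons + "GGTTGG"
        g = dict_genome({"c": seq})
        effects = []
        for nbreak in (1, 2, 3):
            alt = "".join(
                sharp_motif.anticonsensus[i] if i < nbreak else cons[i]
                for i in range(len(cons))
            )
            v = normalize("c", 6, cons, alt, genome=g)
            effects.append(score_variant(v, sharp_motif, g).effect)
        assert all(a >= b for a, b in zip(effects, effects[1:]))

    def test_overlap_flag_recorded(self, sharp_motif, dict_genome):
        cons = sharp_motif.consensus
        seq = "GGTTGG" + cons + "GGTTGG"
        g = dict_genome({"c": seq})
        v = normalize("c", 8, "G", "A", genome=g)
        r = score_variant(v, sharp_motif, g)
        assert r.ref_match.overlaps_variant  # SNV: every window overlaps
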