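"""Homology scan: masking, E-values, seed-and-extend, backbone profiles."""

import numpy as np
import pytest

from plastoflux._seq import random_dna, revcomp
from plastoflux.genome import AnnotatedGenome, Feature
from plastoflux.scan import (
    DepthProfile, MTPTSegment, ScanParams, barcode_overlap_report,
    classify_gene_frequency, coverage_fraction, evalue, find_mtpt_segments,
    mask_features, project_to_backbone,
)


def _seg(ps, pe, ms=0, me=None, species="mito", score=100):
    me = me if me is not None else ms + (pe - ps)
    return MTPTSegment(species, ms, me, "bb", ps, pe, "+", pe - ps, 0.95,
                       score, 1e-30)


class TestMask:
    def test_overlapping_intervals_merge(self):
        g = AnnotatedGenome("p", "A" * 500, [
            Feature("tRNA", 100, 180, "+", "t1"),
            Feature("rRNA", 150, 400, "+", "r1"),
        ])
        assert mask_features(g) == [(100, 400)]

    def test_no_features_empty_mask(self):
        g = AnnotatedGenome("p", "A" * 100)
        with pytest.warns(UserWarning):
            assert mask_features(g) == []

    def test_halfopen_adjacency_merges(self):
        g = AnnotatedGenome("p", "A" * 100, [
            Feature("tRNA", 10, 20, "+", "t1"),
            Feature("tRNA", 20, 30, "+", "t2"),
        ])
        assert mask_features(g, {"tRNA"}) == [(10, 30)]


class TestEvalue:
    def test_zero_score_is_kmn(self):
        assert evalue(0, 100, 200) == pytest.approx(0.621 * 100 * 200)

    def test_direct_arithmetic(self):
        expect = 0.621 * 1e10 * np.exp(-1.33 * 50)
        assert evalue(50, 10**5, 10**5) == pytest.approx(expect, rel=1e-12)

    def test_huge_score_underflows_to_zero(self):
        assert evalue(10**6, 10**5, 10**5) == 0.0


class TestFindSegments:
    def test_self_scan_full_identity(self):
        seq = random_dna(np.random.default_rng(0), 2500)
        segs = find_mtpt_segments(AnnotatedGenome("m", seq),
                                  AnnotatedGenome("p", seq))
        assert len(segs) == 1
        s = segs[0]
        assert (s.plastid_start, s.plastid_end) == (0, 2500)
        assert s.identity == 1.0 and s.strand == "+"

    def test_planted_block_recovered_with_tight_coordinates(self, random_genome_pair):
        mito, plastid, (ms, me, ps, pe) = random_genome_pair(4000, 4500, 8000,
                                                             identity=0.90)
        segs = find_mtpt_segments(mito, plastid)
        assert len(segs) == 1
        s = segs[0]
        assert abs(s.plastid_start - ps) <= 5 and abs(s.plastid_end - pe) <= 5
        assert abs(s.mito_start - ms) <= 5 and abs(s.mito_end - me) <= 5
        assert s.identity >= 0.88

    def test_short_perfect_block_fails_length_filter(self, random_genome_pair):
        mito, plastid, _ = random_genome_pair(100, 125, 5000)
        assert find_mtpt_segments(mito, plastid) == []

    def test_reverse_complement_block_found_on_minus_strand(self, random_genome_pair):
        mito, plastid, (ms, me, ps, pe) = random_genome_pair(
            2000, 2400, 3000, revcomp_block=True)
        segs = find_mtpt_segments(mito, plastid)
        assert len(segs) == 1
        s = segs[0]
        assert s.strand == "-"
        assert abs(s.plastid_start - ps) <= 5 and abs(s.plastid_end - pe) <= 5

    def test_strand_symmetry(self, random_genome_pair):
        """Scanning against the reverse-complemented plastid flips strands
        and mirrors plastid coordinates."""
        mito, plastid, _ = random_genome_pair(4000, 4800, 8000, identity=0.93)
        L = len(plastid.sequence)
        fwd = find_mtpt_segments(mito, plastid)
        rev = find_mtpt_segments(mito, AnnotatedGenome("p_rc",
                                                       revcomp(plastid.sequence)))
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert r.strand != f.strand
        assert (r.plastid_start, r.plastid_end) == (L - f.plastid_end,
                                                    L - f.plastid_start)
        assert (r.score, r.aligned_length) == (f.score, f.aligned_length)

    def test_filter_monotonicity(self, random_genome_pair):
        """Stricter thresholds never add segments."""
        mito, plastid, _ = random_genome_pair(1000, 1400, 6000, identity=0.85)
        base = find_mtpt_segments(mito, plastid)
        keys = {(s.plastid_start, s.plastid_end, s.strand) for s in base}
        for params in (ScanParams(min_identity=0.9),
                       ScanParams(min_length=300),
                       ScanParams(max_evalue=1e-40)):
            strict = find_mtpt_segments(mito, plastid, params)
            strict_keys = {(s.plastid_start, s.plastid_end, s.strand)
                           for s in strict}
            assert strict_keys <= keys

    def test_masked_block_dropped(self):
        rng = np.random.default_rng(5)
        pt_seq = random_dna(rng, 6000)
        bg = random_dna(rng, 8000)
        mito = AnnotatedGenome("m", bg[:4000] + pt_seq[1000:1400] + bg[4000:])
        plastid = AnnotatedGenome("p", pt_seq,
                                  [Feature("rRNA", 950, 1450, "+", "rrn")])
        assert find_mtpt_segments(mito, plastid) == []
        # same scan without the mask recovers the block
        unmasked = find_mtpt_segments(mito, AnnotatedGenome("p", pt_seq))
        assert len(unmasked) == 1

    def test_non_iupac_character_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            find_mtpt_segments(AnnotatedGenome("m", "AC!T" + "A" * 50),
                               AnnotatedGenome("p", "A" * 50))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_mtpt_segments(AnnotatedGenome("m", ""), AnnotatedGenome("p", "ACGT"))


class TestCoverage:
    def test_empty_is_zero(self):
        assert coverage_fraction([], 1000) == 0.0

    def test_overlapping_union(self):
        segs = [_seg(0, 100), _seg(50, 150)]
        assert coverage_fraction(segs, 1000) == pytest.approx(0.15)

    def test_order_and_split_invariance(self):
        whole = [_seg(100, 300)]
        halves = [_seg(200, 300), _seg(100, 200)]
        assert coverage_fraction(whole, 500) == coverage_fraction(halves, 500)

    def test_self_scan_covers_everything(self):
        seq = random_dna(np.random.default_rng(1), 2000)
        segs = find_mtpt_segments(AnnotatedGenome("m", seq),
                                  AnnotatedGenome("p", seq))
        assert coverage_fraction(segs, 2000) == 1.0


class TestBackbone:
    def test_three_species_depth(self):
        bb = AnnotatedGenome("bb", "A" * 100)
        per = {f"sp{i}": [_seg(0, 10, species=f"sp{i}")] for i in range(3)}
        profile = project_to_backbone(per, bb)
        assert (profile.depth[:10] == 3).all() and (profile.depth[10:] == 0).all()

    def test_species_counted_once_per_position(self):
        bb = AnnotatedGenome("bb", "A" * 100)
        per = {"sp1": [_seg(0, 30), _seg(20, 50)]}
        profile = project_to_backbone(per, bb)
        assert profile.depth.max() == 1

    def test_depth_bounded_by_species_count(self):
        bb = AnnotatedGenome("bb", "A" * 50)
        per = {f"sp{i}": [_seg(0, 50, species=f"sp{i}")] for i in range(81)}
        profile = project_to_backbone(per, bb)
        assert profile.depth.max() <= 81 and profile.n_species == 81

    def test_segment_beyond_backbone_rejected(self):
        bb = AnnotatedGenome("bb", "A" * 50)
        with pytest.raises(ValueError):
            project_to_backbone({"sp": [_seg(40, 60)]}, bb)


def _profile_with_counts(length, gene, counts_by_species):
    """DepthProfile where each species either fully covers the gene or not."""
    covers = {}
    for name, covered in counts_by_species.items():
        arr = np.zeros(length, dtype=bool)
        if covered:
            arr[gene.start:gene.end] = True
        covers[name] = arr
    depth = np.sum(list(covers.values()), axis=0).astype(np.int32)
    return DepthProfile("bb", length, depth, len(covers), covers)


class TestGeneFrequency:
    @pytest.mark.parametrize("n_species,expected", [
        (25, "most_frequent"), (12, "moderate"), (3, "rare")])
    def test_frequency_classes(self, n_species, expected):
        gene = Feature("gene", 100, 400, "+", "rbcL")
        covers = {f"sp{i}": i < n_species for i in range(30)}
        profile = _profile_with_counts(1000, gene, covers)
        assert classify_gene_frequency(profile, [gene])["rbcL"] == expected

    def test_half_overlap_rule(self):
        gene = Feature("gene", 0, 100, "+", "g")
        covers = {"sp0": np.zeros(200, dtype=bool)}
        covers["sp0"][0:49] = True  # 49% of the gene: below the 50% rule
        profile = DepthProfile("bb", 200, covers["sp0"].astype(np.int32), 1, covers)
        assert classify_gene_frequency(profile, [gene], high=0, mid=0)["g"] == "rare"

    def test_barcode_report(self):
        regions = [Feature("gene", 100, 200, "+", "rbcL"),
                   Feature("gene", 700, 800, "+", "psbK-psbI")]
        covers = {}
        for i in range(40):
            arr = np.zeros(1000, dtype=bool)
            if i < 30:
                arr[100:200] = True  # rbcL copied in 30 of 40 genomes
            covers[f"sp{i}"] = arr
        depth = np.sum(list(covers.values()), axis=0).astype(np.int32)
        profile = DepthProfile("bb", 1000, depth, 40, covers)
        report = barcode_overlap_report(profile, regions).set_index("region")
        assert report.loc["rbcL", "count"] == 30
        assert report.loc["rbcL", "class"] == "most_frequent"
        assert report.loc["psbK-psbI", "count"] == 0
        assert report.loc["psbK-psbI", "class"] == "rare"
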