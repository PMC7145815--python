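"""Marker design, in-silico PCR, co-amplification, copy fractions."""

import numpy as np
import pandas as pd
import pytest

from plastoflux._seq import random_dna, revcomp
from plastoflux.genome import AnnotatedGenome
from plastoflux.markers import (
    MarkerRules, VariantSite, assess_coamplification, band_visibility,
    call_variants, copy_fraction, design_markers, filter_promiscuous,
    in_silico_pcr,
)
from plastoflux.scan import find_mtpt_segments

SNP_FLIP = {"A": "G", "C": "T", "G": "A", "T": "C"}


@pytest.fixture(scope="module")
def genome_pair():
    """Two plastids differing by 3 SNPs, a 348 bp and a 15 bp deletion."""
    rng = np.random.default_rng(11)
    a = random_dna(rng, 8000)
    b = list(a)
    for pos in (2000, 3000, 3100):  # 3000/3100 are 100 bp apart
        b[pos] = SNP_FLIP[a[pos]]
    b = "".join(b)
    b = b[:5000] + b[5348:]
    b = b[:6152] + b[6167:]
    return AnnotatedGenome("A", a), AnnotatedGenome("B", b)


class TestCallVariants:
    def test_identical_genomes_no_variants(self):
        g = AnnotatedGenome("x", random_dna(np.random.default_rng(1), 5000))
        assert call_variants(g, g) == []

    def test_planted_variants_recovered(self, genome_pair):
        ga, gb = genome_pair
        sites = call_variants(ga, gb)
        snps = {s.position for s in sites if s.type == "SNP"}
        indels = {(s.position, s.indel_length) for s in sites if s.type == "InDel"}
        assert snps == {2000, 3000, 3100}
        assert {ln for _, ln in indels} == {348, 15}
        # InDel anchor within a few bp of the planted coordinate
        assert all(abs(p - q) <= 5 for (p, _), q in
                   zip(sorted(indels), (5000, 6500)))

    def test_symmetric_with_alleles_swapped(self, genome_pair):
        ga, gb = genome_pair
        fwd = {(s.position, s.type) for s in call_variants(ga, gb) if s.type == "SNP"}
        rev_sites = call_variants(gb, ga)
        assert len(fwd) == len([s for s in rev_sites if s.type == "SNP"])
        snp_fwd = {s.position: (s.allele_a, s.allele_b)
                   for s in call_variants(ga, gb) if s.type == "SNP"}
        snp_rev = {s.position: (s.allele_b, s.allele_a)
                   for s in rev_sites if s.type == "SNP"}
        # positions differ by the upstream indel offsets only for sites after them
        assert set(snp_fwd.values()) == set(snp_rev.values())

    def test_non_homologous_rejected(self):
        rng = np.random.default_rng(2)
        a = AnnotatedGenome("a", random_dna(rng, 5000))
        b = AnnotatedGenome("b", random_dna(rng, 5000))
        with pytest.raises(ValueError):
            call_variants(a, b)


class TestFilterPromiscuous:
    def _sites(self):
        return [VariantSite(100, "SNP", "A", "G")]

    @pytest.mark.parametrize("het,kept", [(0.12, False), (0.0, True), (0.03, True)])
    def test_three_percent_rule_is_strict(self, het, kept):
        support = pd.DataFrame({"position": [100], "het_a": [het], "het_b": [0.0]})
        out = filter_promiscuous(self._sites(), support)
        assert bool(out) is kept

    def test_either_accession_can_eliminate(self):
        support = pd.DataFrame({"position": [100], "het_a": [0.0], "het_b": [0.5]})
        assert filter_promiscuous(self._sites(), support) == []

    def test_missing_depth_retained_with_flag(self):
        support = pd.DataFrame({"position": [999], "het_a": [0.0], "het_b": [0.0]})
        with pytest.warns(UserWarning):
            out = filter_promiscuous(self._sites(), support)
        assert len(out) == 1 and not out[0].depth_known


class TestDesignMarkers:
    def test_large_indel_amplicons_differ_by_indel_length(self, genome_pair):
        ga, gb = genome_pair
        mk = design_markers(call_variants(ga, gb), ga)
        indel_mk = [m for m in mk if m.mode == "codominant_InDel"]
        assert len(indel_mk) == 1
        m = indel_mk[0]
        assert abs(m.amplicon_len_a - m.amplicon_len_b) == 348
        # predicted lengths must match actual PCR products on both genomes
        amp_a = in_silico_pcr(m.forward_primer, m.reverse_primer, ga)
        amp_b = in_silico_pcr(m.forward_primer, m.reverse_primer, gb)
        assert [x.length for x in amp_a] == [m.amplicon_len_a]
        assert [x.length for x in amp_b] == [m.amplicon_len_b]

    def test_small_indel_and_close_snps_excluded(self, genome_pair):
        ga, gb = genome_pair
        mk = design_markers(call_variants(ga, gb), ga)
        names = {m.name for m in mk}
        assert not any("6500" in n or "6152" in n for n in names)  # 15 bp InDel
        assert not any("3000" in n or "3100" in n for n in names)  # 100 bp apart
        snp_mk = [m for m in mk if m.mode == "codominant_SNP"]
        assert len(snp_mk) == 1 and snp_mk[0].site.position == 2000
        assert 100 <= snp_mk[0].amplicon_len_a <= 150


class TestInSilicoPCR:
    def test_unique_locus_single_amplicon(self):
        seq = random_dna(np.random.default_rng(3), 4000)
        fwd = seq[1000:1020]
        rev = revcomp(seq[1180:1200])
        amps = in_silico_pcr(fwd, rev, AnnotatedGenome("t", seq))
        assert len(amps) == 1
        assert (amps[0].start, amps[0].end, amps[0].length) == (1000, 1200, 200)

    def test_absent_reverse_primer_no_product(self):
        seq = random_dna(np.random.default_rng(4), 2000)
        amps = in_silico_pcr(seq[100:120], "ACGTACGTACGTACGTACGT",
                             AnnotatedGenome("t", seq))
        assert amps == []

    def test_duplicated_locus_two_products(self):
        rng = np.random.default_rng(5)
        locus = random_dna(rng, 300)
        seq = random_dna(rng, 1000) + locus + random_dna(rng, 1000) + locus \
            + random_dna(rng, 500)
        fwd, rev = locus[:20], revcomp(locus[-20:])
        amps = in_silico_pcr(fwd, rev, AnnotatedGenome("t", seq))
        assert [a.length for a in amps].count(300) == 2

    def test_strand_symmetry(self):
        seq = random_dna(np.random.default_rng(6), 3000)
        fwd, rev = seq[500:520], revcomp(seq[700:720])
        a1 = in_silico_pcr(fwd, rev, AnnotatedGenome("t", seq))
        a2 = in_silico_pcr(fwd, rev, AnnotatedGenome("t_rc", revcomp(seq)))
        assert [(a.start, a.end) for a in a1] == \
            [(3000 - a.end, 3000 - a.start) for a in reversed(a2)]

    def test_three_prime_mismatch_blocks_binding(self):
        seq = random_dna(np.random.default_rng(7), 2000)
        fwd = seq[300:320]
        bad = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
        rev = revcomp(seq[450:470])
        assert in_silico_pcr(bad, rev, AnnotatedGenome("t", seq)) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            in_silico_pcr("ACGTACGT", "ACGTACGTACGTACGTACGT",
                          AnnotatedGenome("t", "ACGT" * 100))


class TestCoamplification:
    def test_marker_inside_mtpt_is_paradox(self, small_pair):
        sp = small_pair.species_a
        segs = find_mtpt_segments(sp.mito, sp.plastid)
        truth = small_pair.mtpt_truth["speciesA"][0]
        ps = truth.plastid_start + 50
        fwd = sp.plastid.sequence[ps:ps + 20]
        rev = revcomp(sp.plastid.sequence[ps + 130:ps + 150])
        site = VariantSite(ps + 75, "SNP", "A", "G")
        from plastoflux.markers import MarkerDef
        marker = MarkerDef("inside", "codominant_SNP", fwd, rev, 150, 150, site)
        report = assess_coamplification(marker, sp.plastid, sp.mito, segs)
        assert report.classification == "PARADOX"
        assert report.mito_amplicons  # the paradox mechanism: a mito band

    def test_marker_outside_mtpt_is_safe(self, small_pair):
        sp = small_pair.species_a
        segs = find_mtpt_segments(sp.mito, sp.plastid)
        covered = np.zeros(len(sp.plastid.sequence), dtype=bool)
        for t in small_pair.mtpt_truth["speciesA"]:
            covered[t.plastid_start:t.plastid_end] = True
        # find a clean 200 bp window outside every planted block
        start = next(i for i in range(0, len(covered) - 200, 50)
                     if not covered[i:i + 200].any())
        fwd = sp.plastid.sequence[start:start + 20]
        rev = revcomp(sp.plastid.sequence[start + 180:start + 200])
        from plastoflux.markers import MarkerDef
        site = VariantSite(start + 100, "SNP", "A", "G")
        marker = MarkerDef("outside", "codominant_SNP", fwd, rev, 200, 200, site)
        report = assess_coamplification(marker, sp.plastid, sp.mito, segs)
        assert report.classification == "SAFE"
        assert not report.mito_amplicons


class TestCopyFraction:
    @pytest.mark.parametrize("d_pt,d_mt,pct", [
        (1045, 141, (88, 12)),
        (1889, 297, (86, 14)),
        (100, 0, (100, 0)),
    ])
    def test_percentages(self, d_pt, d_mt, pct):
        est = copy_fraction(d_pt, d_mt)
        assert (est.percent_pt, est.percent_mt) == pct

    def test_percentages_always_sum_to_hundred(self, rng):
        for _ in range(200):
            d1, d2 = int(rng.integers(0, 5000)), int(rng.integers(1, 5000))
            est = copy_fraction(d1, d2)
            assert est.percent_pt + est.percent_mt == 100
            assert est.fraction_pt + est.fraction_mt == pytest.approx(1.0)

    def test_zero_depths_rejected(self):
        with pytest.raises(ValueError):
            copy_fraction(0, 0)


class TestBandVisibility:
    def test_zero_copies_never_visible(self):
        assert not band_visibility(0, 60, 1e-6)

    def test_monotone_in_cycles_and_copies(self):
        vis_cycles = [band_visibility(10, c, 1e6) for c in range(30)]
        assert vis_cycles == sorted(vis_cycles)
        vis_copies = [band_visibility(c, 20, 1e9) for c in (0, 1, 10, 100, 10000)]
        assert vis_copies == sorted(vis_copies)

    def test_minor_template_needs_three_extra_cycles(self):
        # 88:12 copy ratio: ceil(log2(88/12)) = 3 extra cycles to parity
        threshold = 88 * 2.0 ** 20
        assert band_visibility(88, 20, threshold)
        assert not band_visibility(12, 22, threshold)
        assert band_visibility(12, 20 + 3, threshold)
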