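"""Plastid barcoding-marker design and MTPT co-amplification assessment.

The marker path mirrors the wet-lab workflow: call SNP/InDel sites
between two plastid genomes from a whole-genome pairwise alignment, drop
"promiscuous" sites whose read support is heterogeneous (> 3% minor
alleles — the signature of a co-mapping MTPT copy), convert the survivors
to markers (InDels > 20 bp become codominant size markers; SNPs need a
150 bp clean flank and a 100–150 bp amplicon), then predict PCR products
against both organelle genomes.  A marker whose amplicon has an MTPT
counterpart co-amplifies a mitochondrial band — the barcoding paradox.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._seq import gc_fraction, revcomp
from .genome import AnnotatedGenome
from .scan import MTPTSegment

__all__ = [
    "VariantSite",
    "MarkerDef",
    "MarkerRules",
    "Amplicon",
    "CopyFractionEstimate",
    "CoamplificationReport",
    "call_variants",
    "filter_promiscuous",
    "design_markers",
    "in_silico_pcr",
    "assess_coamplification",
    "copy_fraction",
    "band_visibility",
]

logger = logging.getLogger(__name__)


@dataclass
class VariantSite:
    """One polymorphic site between two plastid genomes (genome-A coords)."""

    position: int          # 0-based on genome A
    type: str              # "SNP" or "InDel"
    allele_a: str
    allele_b: str
    indel_length: int = 0  # 0 for SNPs
    het_fraction_a: float = 0.0
    het_fraction_b: float = 0.0
    depth_known: bool = True

    def __post_init__(self) -> None:
        if self.type == "SNP":
            if len(self.allele_a) != 1 or len(self.allele_b) != 1 \
                    or self.allele_a == self.allele_b:
                raise ValueError("SNP alleles must be single differing bases")
        elif self.type == "InDel":
            if self.indel_length != abs(len(self.allele_a.strip("-"))
                                        - len(self.allele_b.strip("-"))):
                raise ValueError("indel_length must equal the allele length difference")
            if self.indel_length == 0:
                raise ValueError("InDel must change length")
        else:
            raise ValueError(f"unknown variant type {self.type!r}")


@dataclass
class MarkerRules:
    """Marker-design filters: InDels must exceed min_indel bp; SNPs must
    have no other variant within snp_isolation bp; SNP amplicons fall in
    amplicon_range."""

    min_indel: int = 20          # strictly greater than
    snp_isolation: int = 150     # exclude SNPs with a neighbor closer than this
    amplicon_range: tuple[int, int] = (100, 150)
    primer_len: int = 20
    gc_range: tuple[float, float] = (0.40, 0.60)


@dataclass
class MarkerDef:
    name: str
    mode: str  # dominant_SNP / codominant_SNP / codominant_InDel
    forward_primer: str
    reverse_primer: str
    amplicon_len_a: int
    amplicon_len_b: int
    site: VariantSite = None

    def __post_init__(self) -> None:
        for p in (self.forward_primer, self.reverse_primer):
            if not 18 <= len(p) <= 27:
                raise ValueError(f"marker {self.name}: primer length {len(p)} outside 18-27 nt")


@dataclass
class Amplicon:
    template_id: str
    compartment: str  # "plastid" or "mitochondrion"
    start: int
    end: int
    length: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.length != self.end - self.start:
            raise ValueError("inconsistent amplicon interval")


@dataclass
class CopyFractionEstimate:
    """Plastid/mitochondrial genome copy share from diagnostic-site depths."""

    d_pt: int
    d_mt: int
    fraction_pt: float
    fraction_mt: float
    percent_pt: int
    percent_mt: int


@dataclass
class CoamplificationReport:
    marker: str
    classification: str  # "SAFE" or "PARADOX"
    plastid_amplicons: list[Amplicon]
    mito_amplicons: list[Amplicon]
    mtpt_overlap: bool


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        counts[w] = -1 if w in counts else i
    return {w: p for w, p in counts.items() if p >= 0}


def _anchor_chain(a: str, b: str, k: int = 20) -> list[tuple[int, int]]:
    """Collinear chain of unique shared k-mers: longest increasing
    subsequence in b-coordinates of anchors sorted by a-coordinate, then
    thinned so both coordinates advance by >= k."""
    ka = _unique_kmers(a, k)
    kb = _unique_kmers(b, k)
    shared = sorted((pa, kb[w]) for w, pa in ka.items() if w in kb)
    if not shared:
        return []
    import bisect

    tails: list[int] = []          # LIS on the b-coordinate
    tails_idx: list[int] = []
    parent = [-1] * len(shared)
    for i, (_, pb) in enumerate(shared):
        j = bisect.bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            tails_idx.append(i)
        else:
            tails[j] = pb
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(shared[i])
        i = parent[i]
    chain.reverse()
    thinned = []
    last_a = last_b = -(10 ** 9)
    for pa, pb in chain:
        if pa >= last_a + k and pb >= last_b + k:
            thinned.append((pa, pb))
            last_a, last_b = pa, pb
    return thinned


def _segment_aligner():
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def _anchored_align(a: str, b: str, k: int = 20,
                    max_segment: int = 20_000) -> tuple[str, str]:
    """Global alignment of two long homologous sequences via anchor chains.

    Unique shared k-mers fix a collinear backbone; the gaps between
    anchors are aligned with an affine-gap aligner so long InDels stay
    contiguous (a unit-cost edit-distance alignment would scatter them
    across chance matches).
    """
    anchors = _anchor_chain(a, b, k)
    if not anchors and (len(a) > 1000 or len(b) > 1000):
        raise ValueError("no alignment anchors: sequences look non-homologous")
    aligner = _segment_aligner()
    out_a, out_b = [], []
    pa = pb = 0
    for qa, qb in anchors + [(len(a), len(b))]:
        seg_a, seg_b = a[pa:qa], b[pb:qb]
        if seg_a or seg_b:
            if not seg_a:
                out_a.append("-" * len(seg_b))
                out_b.append(seg_b)
            elif not seg_b:
                out_a.append(seg_a)
                out_b.append("-" * len(seg_a))
            elif len(seg_a) > max_segment or len(seg_b) > max_segment:
                res = edlib.align(seg_b, seg_a, task="path", mode="NW")
                nice = edlib.getNiceAlignment(res, seg_b, seg_a)
                out_a.append(nice["target_aligned"])
                out_b.append(nice["query_aligned"])
            else:
                aln = aligner.align(seg_a, seg_b)[0]
                out_a.append(str(aln[0]))
                out_b.append(str(aln[1]))
        if qa < len(a):
            out_a.append(a[qa : qa + k])
            out_b.append(b[qb : qb + k])
            pa, pb = qa + k, qb + k
    return "".join(out_a), "".join(out_b)


def call_variants(plastid_a: AnnotatedGenome, plastid_b: AnnotatedGenome,
                  max_divergence: float = 0.5) -> list[VariantSite]:
    """SNPs and InDels from a whole-genome pairwise alignment.

    The alignment is anchored on unique shared 20-mers with affine-gap
    alignment in between, so an InDel is reported as one contiguous run.
    Positions are reported on genome A (insertions relative to A are
    anchored at the preceding A position).  Genomes whose aligned
    difference fraction exceeds max_divergence are rejected as
    non-homologous.
    """
    a, b = plastid_a.sequence, plastid_b.sequence
    aln_a, aln_b = _anchored_align(a, b)
    ndiff = sum(x != y for x, y in zip(aln_a, aln_b))
    if ndiff > max_divergence * max(len(a), len(b)):
        raise ValueError(f"genomes too divergent to align ({ndiff} differences)")

    sites: list[VariantSite] = []
    pos_a = 0
    i = 0
    L = len(aln_a)
    while i < L:
        ca, cb = aln_a[i], aln_b[i]
        if ca == cb:
            pos_a += 1
            i += 1
        elif ca != "-" and cb != "-":
            sites.append(VariantSite(pos_a, "SNP", ca, cb))
            pos_a += 1
            i += 1
        else:
            j = i
            run_a, run_b = [], []
            while j < L and (aln_a[j] == "-" or aln_b[j] == "-") and aln_a[j] != aln_b[j]:
                run_a.append(aln_a[j])
                run_b.append(aln_b[j])
                j += 1
            sa = "".join(run_a).replace("-", "")
            sb = "".join(run_b).replace("-", "")
            start = pos_a
            if len(sa) != len(sb):
                sites.append(VariantSite(start, "InDel", sa or "-", sb or "-",
                                         indel_length=abs(len(sa) - len(sb))))
            else:  # balanced ins+del run: report per-base substitutions
                for off, (x, y) in enumerate(zip(sa, sb)):
                    if x != y:
                        sites.append(VariantSite(start + off, "SNP", x, y))
            pos_a += len(sa)
            i = j
    return sites


def filter_promiscuous(sites: list[VariantSite],
                       support: pd.DataFrame | None = None,
                       max_het: float = 0.03) -> list[VariantSite]:
    """Drop sites with heterogeneous read support in either accession.

    ``support`` maps genome-A positions to per-accession minor-allele
    fractions (columns: position, het_a, het_b).  A site is eliminated
    when its het fraction strictly exceeds max_het (3% by default) in
    either accession — such sites flag co-mapping MTPT copies.  Sites
    without depth information are retained with a warning flag.
    """
    table = {}
    if support is not None:
        for row in support.itertuples(index=False):
            table[int(row.position)] = (float(row.het_a), float(row.het_b))
    out = []
    for s in sites:
        if s.position in table:
            het_a, het_b = table[s.position]
            if het_a > max_het or het_b > max_het:
                continue
            s.het_fraction_a, s.het_fraction_b = het_a, het_b
            s.depth_known = True
        else:
            if support is not None:
                warnings.warn(f"no read support at site {s.position}; retained",
                              stacklevel=2)
            s.depth_known = support is None
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# marker design
# ---------------------------------------------------------------------------

def _pick_primer(seq: str, lo: int, hi: int, plen: int, gc_range, genome: str,
                 reverse: bool) -> tuple[str, int] | None:
    """First unique GC-balanced plen-mer starting in [lo, hi)."""
    for start in range(lo, hi):
        if start < 0 or start + plen > len(seq):
            continue
        window = seq[start : start + plen]
        if set(window) - set("ACGT"):
            continue
        if not gc_range[0] <= gc_fraction(window) <= gc_range[1]:
            continue
        if genome.count(window) + genome.count(revcomp(window)) != 1:
            continue
        return (revcomp(window) if reverse else window), start
    return None


def design_markers(sites: list[VariantSite], plastid: AnnotatedGenome,
                   rules: MarkerRules | None = None) -> list[MarkerDef]:
    """Convert filtered variant sites to codominant markers.

    InDels longer than rules.min_indel become codominant_InDel markers
    whose two expected amplicon lengths differ by exactly indel_length.
    SNPs are used only when no other variant lies within
    rules.snp_isolation bp, with a designed amplicon inside
    rules.amplicon_range.  Sites without a workable primer window are
    skipped and logged.
    """
    rules = rules or MarkerRules()
    seq = plastid.sequence
    positions = sorted(s.position for s in sites)
    markers = []
    for s in sites:
        if s.type == "InDel":
            if s.indel_length <= rules.min_indel:
                continue
            ref_span = len(s.allele_a.strip("-"))
            lo_f = s.position - 120
            fwd = _pick_primer(seq, lo_f, s.position - rules.primer_len - 10,
                               rules.primer_len, rules.gc_range, seq, reverse=False)
            rev = _pick_primer(seq, s.position + ref_span + 10,
                               s.position + ref_span + 120,
                               rules.primer_len, rules.gc_range, seq, reverse=True)
            if not fwd or not rev:
                logger.info("no primer window for InDel at %d; skipped", s.position)
                continue
            fp, fstart = fwd
            rp, rstart = rev
            len_a = rstart + rules.primer_len - fstart
            len_b = len_a - len(s.allele_a.strip("-")) + len(s.allele_b.strip("-"))
            markers.append(MarkerDef(f"indel_{s.position}", "codominant_InDel",
                                     fp, rp, len_a, len_b, s))
        else:
            neighbors = [p for p in positions
                         if p != s.position and abs(p - s.position) < rules.snp_isolation]
            if neighbors:
                continue
            amp_lo, amp_hi = rules.amplicon_range
            target = (amp_lo + amp_hi) // 2
            fwd = _pick_primer(seq, s.position - target // 2,
                               s.position - rules.primer_len - 5,
                               rules.primer_len, rules.gc_range, seq, reverse=False)
            if not fwd:
                logger.info("no forward primer for SNP at %d; skipped", s.position)
                continue
            fp, fstart = fwd
            rev = None
            for rstart in range(fstart + amp_lo - rules.primer_len,
                                fstart + amp_hi - rules.primer_len):
                if rstart <= s.position:
                    continue
                cand = _pick_primer(seq, rstart, rstart + 1, rules.primer_len,
                                    rules.gc_range, seq, reverse=True)
                if cand:
                    rev = cand
                    break
            if not rev:
                logger.info("no reverse primer for SNP at %d; skipped", s.position)
                continue
            rp, rstart = rev
            amp_len = rstart + rules.primer_len - fstart
            if not amp_lo <= amp_len <= amp_hi:
                continue
            markers.append(MarkerDef(f"snp_{s.position}", "codominant_SNP",
                                     fp, rp, amp_len, amp_len, s))
    return markers


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def _binding_sites(primer: str, template: str, max_mismatch: int):
    """(start, end, mismatches) of primer annealing sites on both strands.

    Plus-strand sites have the primer 3' end at the high coordinate;
    minus-strand sites (primer binds the reverse complement) have it at
    the low coordinate.  The 3'-terminal 3-mer must match exactly.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    plen = len(primer)
    if len(template) < plen:
        return [], []
    tmpl = np.frombuffer(template.encode(), dtype=np.uint8)
    windows = sliding_window_view(tmpl, plen)

    def scan(pseq):
        p = np.frombuffer(pseq.encode(), dtype=np.uint8)
        mism = (windows != p).sum(axis=1)
        tail_ok = (windows[:, -3:] == p[-3:]).all(axis=1)
        return np.flatnonzero((mism <= max_mismatch) & tail_ok), mism

    plus_idx, plus_mm = scan(primer)
    rc = revcomp(primer)
    # on the minus strand the primer's 3' end maps to the window start
    p = np.frombuffer(rc.encode(), dtype=np.uint8)
    mism = (windows != p).sum(axis=1)
    head_ok = (windows[:, :3] == p[:3]).all(axis=1)
    minus_idx = np.flatnonzero((mism <= max_mismatch) & head_ok)
    plus = [(int(i), int(i) + plen, int(plus_mm[i])) for i in plus_idx]
    minus = [(int(i), int(i) + plen, int(mism[i])) for i in minus_idx]
    return plus, minus


def in_silico_pcr(forward: str, reverse: str, template: AnnotatedGenome | str,
                  max_mismatch: int = 2, max_len: int = 5000,
                  compartment: str = "unknown") -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    Binding requires <= max_mismatch mismatches and an exact 3'-terminal
    3-mer; every convergent plus/minus site pair within max_len yields an
    amplicon.  Either primer may serve in either orientation.  Output is
    sorted by (start, end).
    """
    forward, reverse = forward.upper(), reverse.upper()
    if len(forward) < 15 or len(reverse) < 15:
        raise ValueError("primers must be >= 15 nt")
    if isinstance(template, AnnotatedGenome):
        tid, seq = template.id, template.sequence
    else:
        tid, seq = "template", template.upper()

    plus, minus = [], []
    for primer in (forward, reverse):
        p, m = _binding_sites(primer, seq, max_mismatch)
        plus.extend(p)
        minus.extend(m)
    out = []
    seen = set()
    for ps, pe, pmm in plus:
        for ms, me, mmm in minus:
            if ms < pe:  # primers must converge
                continue
            length = me - ps
            if length > max_len:
                continue
            key = (ps, me)
            if key in seen:
                continue
            seen.add(key)
            out.append(Amplicon(tid, compartment, ps, me, length, pmm + mmm))
    return sorted(out, key=lambda a: (a.start, a.end))


def assess_coamplification(marker: MarkerDef, plastid: AnnotatedGenome,
                           mito: AnnotatedGenome,
                           segments: list[MTPTSegment] | None = None,
                           max_mismatch: int = 2,
                           max_len: int = 5000) -> CoamplificationReport:
    """Classify a marker as SAFE or PARADOX against the MTPT landscape.

    PARADOX when a mitochondrial amplicon is predicted, or when the
    plastid amplicon overlaps a detected MTPT segment (its template has a
    mitochondrial counterpart).
    """
    amp_pt = in_silico_pcr(marker.forward_primer, marker.reverse_primer,
                           plastid, max_mismatch, max_len, "plastid")
    amp_mt = in_silico_pcr(marker.forward_primer, marker.reverse_primer,
                           mito, max_mismatch, max_len, "mitochondrion")
    overlap = False
    for a in amp_pt:
        for seg in segments or []:
            if min(a.end, seg.plastid_end) > max(a.start, seg.plastid_start):
                overlap = True
    classification = "PARADOX" if (amp_mt or overlap) else "SAFE"
    return CoamplificationReport(marker.name, classification, amp_pt, amp_mt, overlap)


# ---------------------------------------------------------------------------
# copy fraction and band visibility
# ---------------------------------------------------------------------------

def copy_fraction(d_pt: int, d_mt: int) -> CopyFractionEstimate:
    """Plastid/mitochondrial copy share from allele depths at one site.

    Percentages are integers reconciled to sum to 100 by the
    largest-remainder rule.
    """
    if d_pt < 0 or d_mt < 0 or d_pt + d_mt == 0:
        raise ValueError("depths must be non-negative with a positive sum")
    total = d_pt + d_mt
    f_pt = d_pt / total
    raw = [100.0 * f_pt, 100.0 * (1 - f_pt)]
    floors = [int(np.floor(r)) for r in raw]
    remainder = 100 - sum(floors)
    order = sorted(range(2), key=lambda i: raw[i] - floors[i], reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return CopyFractionEstimate(d_pt, d_mt, f_pt, 1 - f_pt, floors[0], floors[1])


def band_visibility(copies: float, cycles: int, threshold: float,
                    plateau: float = 1e12) -> bool:
    """Semi-quantitative PCR band model: product = copies * 2**cycles,
    capped at a plateau; the band is visible iff product >= threshold.

    Explains why MTPT-derived bands surface only at high cycle numbers or
    template loads: a 12% minor template needs ~3 extra cycles to match
    an 88% major template's product.
    """
    if copies < 0 or cycles < 0:
        raise ValueError("copies and cycles must be non-negative")
    product = min(copies * float(2 ** cycles), plateau)
    return product >= threshold
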