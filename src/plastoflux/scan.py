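"""Seed-and-extend detection of MTPT segments.

A mitochondrial genome is scanned against a plastid genome with exact
word seeds on both strands, ungapped X-drop extension along diagonals, a
gapped banded Smith–Waterman pass to join nearby diagonals, and
Karlin–Altschul E-values.  Reported segments must clear the homology
thresholds (>= 70% identity, >= 30 bp, E <= 1e-10 by default) and survive
the plastid tRNA/rRNA mask — those regions are conserved in both organelle
genomes and would otherwise flood the scan with non-MTPT hits.

Segments from many species can then be projected onto one reference
plastid "backbone" as a per-position species-depth profile, from which
per-gene MTPT frequency classes and barcoding-region overlap reports are
derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import check_alphabet, encode, revcomp
from .genome import AnnotatedGenome, Feature

__all__ = [
    "ScanParams",
    "MTPTSegment",
    "DepthProfile",
    "mask_features",
    "evalue",
    "find_mtpt_segments",
    "coverage_fraction",
    "project_to_backbone",
    "classify_gene_frequency",
    "barcode_overlap_report",
]


@dataclass
class ScanParams:
    """Scoring scheme and homology thresholds for the MTPT scan.

    The thresholds (identity, length, E-value) are the filters applied to
    candidate alignments; the scoring scheme is a conventional nucleotide
    parameterization (+1/-2, affine gap 5+2k) with ungapped
    Karlin–Altschul constants lambda=1.33, K=0.621 for that scheme.
    word_size 8 guarantees an exact seed inside any substitution-diverged
    block of >= 50 bp at >= 90% identity.
    """

    min_identity: float = 0.70
    min_length: int = 30
    max_evalue: float = 1e-10
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5     # gap of length k costs gap_open + k*gap_extend
    gap_extend: int = -2
    word_size: int = 8
    ka_lambda: float = 1.33
    ka_K: float = 0.621
    x_drop: int = 20
    x_drop_gapped: int = 40  # X-drop for the gapped extension phase
    gap_trigger: int = 18    # min ungapped score before gapped extension
    prefilter_net: int = 8   # min net window extension kept at the seed stage
    band_pad: int = 32       # half-width of the gapped DP band
    flank_cap: int = 2000    # max gapped-extension length per side
    chain_gap: int = 100     # max seed spacing merged into one diagonal chain
    join_gap: int = 200      # max query gap between HSPs joined by the gapped pass
    mask_types: tuple[str, ...] = ("tRNA", "rRNA")

    def validate(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0,1]")
        if self.min_length < self.word_size:
            raise ValueError("min_length must be >= word_size")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


@dataclass
class MTPTSegment:
    """One homologous segment between a mitochondrial and a plastid genome."""

    mito_id: str
    mito_start: int
    mito_end: int
    plastid_id: str
    plastid_start: int
    plastid_end: int
    strand: str
    aligned_length: int
    identity: float
    score: int
    evalue: float
    # alignment columns: plastid position (-1 = gap), mito position (-1 = gap),
    # match flag; retained so mask trimming can re-score exactly
    _spos: np.ndarray = field(default=None, repr=False, compare=False)
    _mpos: np.ndarray = field(default=None, repr=False, compare=False)
    _match: np.ndarray = field(default=None, repr=False, compare=False)


@dataclass
class DepthProfile:
    """Per-position count of species with >= 1 MTPT segment covering it."""

    backbone_id: str
    length: int
    depth: np.ndarray
    n_species: int
    per_species_cover: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# masking and E-values
# ---------------------------------------------------------------------------

def mask_features(genome: AnnotatedGenome,
                  types: set[str] | tuple[str, ...] = ("tRNA", "rRNA")
                  ) -> list[tuple[int, int]]:
    """Merged, sorted 0-based half-open intervals of the requested feature types.

    Unknown feature types draw a warning and contribute nothing; abutting
    intervals merge (half-open adjacency).
    """
    known = {f.type for f in genome.features}
    for t in types:
        if t not in known:
            warnings.warn(f"no features of type {t!r} in {genome.id}", stacklevel=2)
    ivals = sorted((f.start, f.end) for f in genome.features if f.type in set(types))
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def evalue(score: float, m: int, n: int, ka_lambda: float = 1.33,
           ka_K: float = 0.621) -> float:
    """Karlin–Altschul expectation: E = K * m * n * exp(-lambda * score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    with np.errstate(under="ignore"):
        return float(ka_K * m * n * np.exp(-ka_lambda * score))


def _min_score(params: ScanParams, m: int, n: int) -> int:
    """Smallest integer score whose E-value clears max_evalue."""
    s = np.log(params.ka_K * m * n / params.max_evalue) / params.ka_lambda
    return max(int(np.ceil(s)), 1)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _word_codes(enc: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit word codes and a validity mask (no ambiguous bases)."""
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for k in range(w):
        window = enc[k : k + n]
        codes = codes * 4 + np.where(window < 4, window, 0)
        valid &= window < 4
    return codes, valid


def _seed_hits(qenc: np.ndarray, senc: np.ndarray, w: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, subject_pos) exact word matches."""
    qc, qv = _word_codes(qenc, w)
    sc, sv = _word_codes(senc, w)
    spos_all = np.flatnonzero(sv)
    s_sorted = np.sort(sc[spos_all])
    s_order = spos_all[np.argsort(sc[spos_all], kind="stable")]
    qpos_all = np.flatnonzero(qv)
    left = np.searchsorted(s_sorted, qc[qpos_all], side="left")
    right = np.searchsorted(s_sorted, qc[qpos_all], side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qhit = np.repeat(qpos_all, counts)
    # gather subject positions for each query word's [left,right) range
    offsets = np.concatenate([np.arange(c) for c in counts if c]) if total else None
    starts = np.repeat(left, counts)
    shit = s_order[starts + offsets]
    return qhit, shit


def _prefilter_hits(qenc, senc, qhit, shit, w, trigger_net=4, win=24):
    """Keep hits whose seed extends by >= trigger_net net score in a small window."""
    if qhit.size == 0:
        return np.empty(0, dtype=bool)
    offs_r = np.arange(w, w + win)
    offs_l = -np.arange(1, win + 1)

    def side_gain(offs):
        qi = qhit[:, None] + offs
        si = shit[:, None] + offs
        ok = (qi >= 0) & (qi < qenc.size) & (si >= 0) & (si < senc.size)
        m = np.zeros(qi.shape, dtype=bool)
        qi_c = np.clip(qi, 0, qenc.size - 1)
        si_c = np.clip(si, 0, senc.size - 1)
        m[ok] = qenc[qi_c][ok] == senc[si_c][ok]
        sc = np.where(m, 1, -2)
        sc[~ok] = -2
        cum = np.cumsum(sc, axis=1)
        return np.maximum(cum.max(axis=1), 0)

    return side_gain(offs_r) + side_gain(offs_l) >= trigger_net


def _xdrop_extend(qenc, senc, d, start, direction, x_drop, chunk=256):
    """Ungapped X-drop walk along diagonal d from query position `start`.

    direction +1 extends rightward starting at `start`; -1 leftward
    starting at `start`-1.  Returns (n_extended, score_gain).
    """
    best, best_k, cum, k = 0, 0, 0, 0
    qn, sn = qenc.size, senc.size
    while True:
        if direction > 0:
            q0 = start + k
            limit = min(qn - q0, sn - (q0 + d))
        else:
            q0 = start - k
            limit = min(q0, q0 + d)
        if limit <= 0:
            break
        n = min(chunk, limit)
        if direction > 0:
            qs = qenc[q0 : q0 + n]
            ss = senc[q0 + d : q0 + d + n]
        else:
            qs = qenc[q0 - n : q0][::-1]
            ss = senc[q0 + d - n : q0 + d][::-1]
        sc = np.where(qs == ss, 1, -2).astype(np.int64)
        cums = cum + np.cumsum(sc)
        run_max = np.maximum.accumulate(np.maximum(cums, best))
        dropped = np.flatnonzero(run_max - cums > x_drop)
        upto = dropped[0] + 1 if dropped.size else n
        seg = cums[:upto]
        j = int(np.argmax(seg))
        if seg[j] > best:
            best = int(seg[j])
            best_k = k + j + 1
        if dropped.size:
            break
        cum = int(cums[-1])
        k += n
    return best_k, best


def _gapped_extension(q_arr, s_arr, params: ScanParams):
    """Banded gapped X-drop extension along two sequence flanks.

    Aligns prefixes of q_arr/s_arr anchored at their first elements;
    returns (gain, cols) where cols are (iq, is, match) relative indices
    with -1 for gaps, or (0, []) when no positive-score extension exists.
    Rows are vectorized over the band; Ix (gap-in-query) uses a prefix-max
    scan to resolve the within-row dependency.
    """
    pad = params.band_pad
    xd = params.x_drop_gapped
    ma, mi = params.match, params.mismatch
    go = params.gap_open + params.gap_extend
    ge = params.gap_extend
    NEG = -1e9
    qn = int(min(len(q_arr), params.flank_cap))
    sn = int(min(len(s_arr), params.flank_cap + pad))
    if qn == 0 or sn == 0:
        return 0, []
    bw = 2 * pad + 1
    offsets = np.arange(bw) - pad  # j - i per band index

    Mr = np.full((qn + 1, bw), NEG)
    Xr = np.full((qn + 1, bw), NEG)
    Yr = np.full((qn + 1, bw), NEG)
    Mr[0, pad] = 0.0
    j0 = offsets
    lead = (j0 >= 1) & (j0 <= sn)
    Xr[0, lead] = go + (j0[lead] - 1) * ge

    best, best_cell = 0.0, None
    last_row = 0
    for i in range(1, qn + 1):
        jv = i + offsets
        valid = (jv >= 0) & (jv <= sn)
        okM = valid & (jv >= 1)
        H = np.maximum(Mr[i - 1], np.maximum(Xr[i - 1], Yr[i - 1]))
        jm1 = np.clip(jv - 1, 0, sn - 1)
        sub = np.where(q_arr[i - 1] == s_arr[jm1], float(ma), float(mi))
        Mi = np.where(okM, H + sub, NEG)
        Mi[Mi < NEG / 2] = NEG
        pMs = np.append(Mr[i - 1, 1:], NEG)
        pYs = np.append(Yr[i - 1, 1:], NEG)
        Yi = np.maximum(pMs + go, pYs + ge)
        Yi[~valid | (Yi < NEG / 2)] = NEG
        A = Mi - offsets * ge
        Arun = np.maximum.accumulate(np.concatenate(([NEG], A)))[:-1]
        Xi = Arun + offsets * ge + (go - ge)
        Xi[~valid | (Xi < NEG / 2)] = NEG
        Mr[i], Xr[i], Yr[i] = Mi, Xi, Yi
        last_row = i
        row_best = Mi.max()
        if row_best > best:
            best = float(row_best)
            best_cell = (i, int(np.argmax(Mi)))
        if row_best < best - xd:
            break

    if best_cell is None:
        return 0, []
    i, b = best_cell
    cols = []
    state = 0
    eps = 1e-6
    while not (i == 0 and b == pad and state == 0):
        j = i + b - pad
        if state == 0:
            sub = ma if q_arr[i - 1] == s_arr[j - 1] else mi
            target = Mr[i, b] - sub
            cols.append((i - 1, j - 1, bool(q_arr[i - 1] == s_arr[j - 1])))
            i -= 1
            if abs(Mr[i, b] - target) < eps:
                state = 0
            elif abs(Xr[i, b] - target) < eps:
                state = 1
            else:
                state = 2
        elif state == 1:
            nxt = 0 if abs(Mr[i, b - 1] + go - Xr[i, b]) < eps else 1
            cols.append((-1, j - 1, False))
            b -= 1
            state = nxt
        else:
            nxt = 0 if abs(Mr[i - 1, b + 1] + go - Yr[i, b]) < eps else 2
            cols.append((i - 1, -1, False))
            i -= 1
            b += 1
            state = nxt
    cols.reverse()
    return int(best), cols


def _extend_columns(spos, mpos, match, qenc, senc, params: ScanParams):
    """Splice gapped flank extensions onto a core alignment's columns."""
    sp = spos[spos >= 0]
    qp = mpos[mpos >= 0]
    q0, q1 = int(qp.min()), int(qp.max()) + 1
    s0, s1 = int(sp.min()), int(sp.max()) + 1

    gain_r, cols_r = _gapped_extension(qenc[q1:], senc[s1:], params)
    gain_l, cols_l = _gapped_extension(qenc[:q0][::-1], senc[:s0][::-1], params)

    def remap(cols, qmap, smap):
        out_s, out_m, out_f = [], [], []
        for iq, isx, f in cols:
            out_m.append(qmap(iq) if iq >= 0 else -1)
            out_s.append(smap(isx) if isx >= 0 else -1)
            out_f.append(f)
        return out_s, out_m, out_f

    rs, rm, rf = remap(cols_r, lambda i: q1 + i, lambda j: s1 + j)
    ls, lm, lf = remap(cols_l, lambda i: q0 - 1 - i, lambda j: s0 - 1 - j)
    ls, lm, lf = ls[::-1], lm[::-1], lf[::-1]
    spos = np.concatenate([np.array(ls, dtype=np.int64), spos, np.array(rs, dtype=np.int64)])
    mpos = np.concatenate([np.array(lm, dtype=np.int64), mpos, np.array(rm, dtype=np.int64)])
    match = np.concatenate([np.array(lf, dtype=bool), match, np.array(rf, dtype=bool)])
    return spos, mpos, match


def _diag_columns(q0: int, q1: int, d: int, qenc, senc):
    spos = np.arange(q0 + d, q1 + d, dtype=np.int64)
    mpos = np.arange(q0, q1, dtype=np.int64)
    match = qenc[q0:q1] == senc[q0 + d : q1 + d]
    return spos, mpos, match


# ---------------------------------------------------------------------------
# banded gapped DP (joins HSPs on nearby diagonals)
# ---------------------------------------------------------------------------

def _banded_local_align(qenc, senc, q0, q1, s0, s1, dlo, dhi, params: ScanParams):
    """Affine-gap local DP restricted to diagonals [dlo, dhi] of a window.

    Returns (score, columns) of the best local alignment, columns as
    (spos, mpos, match) arrays in global coordinates; gaps carry -1.
    """
    ma, mi = params.match, params.mismatch
    go = params.gap_open + params.gap_extend  # cost of the first gap residue
    ge = params.gap_extend
    NEG = -(10 ** 9)
    bw = dhi - dlo + 1
    nrow = q1 - q0
    M = np.full((nrow + 1, bw), NEG, dtype=np.int64)
    Ix = np.full((nrow + 1, bw), NEG, dtype=np.int64)  # gap in query (consumes subject)
    Iy = np.full((nrow + 1, bw), NEG, dtype=np.int64)  # gap in subject (consumes query)
    ptr = np.zeros((nrow + 1, bw, 3), dtype=np.int8)
    best = (0, 0, 0)  # score, row, band index

    for i in range(1, nrow + 1):
        qpos = q0 + i - 1
        for b in range(bw):
            spos = qpos + dlo + b
            if spos < s0 or spos >= s1:
                M[i, b] = Ix[i, b] = Iy[i, b] = NEG
                continue
            sub = ma if qenc[qpos] == senc[spos] else mi
            # M: diagonal move keeps the band index
            cands = (M[i - 1, b], Ix[i - 1, b], Iy[i - 1, b], 0)
            k = int(np.argmax(cands))
            M[i, b] = cands[k] + sub
            ptr[i, b, 0] = k
            # Ix: consume subject only => band index b-1, same row
            if b > 0:
                o, e = M[i, b - 1] + go, Ix[i, b - 1] + ge
                Ix[i, b] = max(o, e)
                ptr[i, b, 1] = 0 if o >= e else 1
            # Iy: consume query only => previous row, band index b+1
            if b < bw - 1:
                o, e = M[i - 1, b + 1] + go, Iy[i - 1, b + 1] + ge
                Iy[i, b] = max(o, e)
                ptr[i, b, 2] = 0 if o >= e else 1
            if M[i, b] > best[0]:
                best = (int(M[i, b]), i, b)

    score, i, b = best
    if score <= 0:
        return 0, None
    cols = []
    state = 0  # 0=M, 1=Ix (gap in query), 2=Iy (gap in subject)
    while i > 0:
        qpos = q0 + i - 1
        spos = qpos + dlo + b
        if state == 0:
            k = int(ptr[i, b, 0])
            cols.append((spos, qpos, bool(qenc[qpos] == senc[spos])))
            i -= 1  # diagonal move: band index unchanged
            if k == 3:
                break
            state = k
        elif state == 1:
            k = int(ptr[i, b, 1])
            cols.append((spos, -1, False))
            b -= 1
            state = 0 if k == 0 else 1
        else:
            k = int(ptr[i, b, 2])
            cols.append((-1, qpos, False))
            i -= 1
            b += 1
            state = 0 if k == 0 else 2
    cols.reverse()
    spos = np.array([c[0] for c in cols], dtype=np.int64)
    mpos = np.array([c[1] for c in cols], dtype=np.int64)
    match = np.array([c[2] for c in cols], dtype=bool)
    return score, (spos, mpos, match)


# ---------------------------------------------------------------------------
# segment assembly
# ---------------------------------------------------------------------------

def _columns_score(spos, mpos, match, params: ScanParams) -> int:
    score = int(match.sum()) * params.match + int((~match & (spos >= 0) & (mpos >= 0)).sum()) * params.mismatch
    # gap runs
    for arr in (spos, mpos):
        isgap = arr < 0
        if isgap.any():
            starts = np.flatnonzero(isgap & ~np.roll(isgap, 1))
            if isgap[0]:
                starts = np.union1d(starts, [0])
            ends = np.flatnonzero(isgap & ~np.roll(isgap, -1))
            if isgap[-1]:
                ends = np.union1d(ends, [isgap.size - 1])
            for s, e in zip(starts, ends):
                score += params.gap_open + (e - s + 1) * params.gap_extend
    return score


def _make_segment(spos, mpos, match, strand, mito_len, mito_id, plastid_id,
                  params, m, n, score=None):
    keep = (spos >= 0) | (mpos >= 0)
    spos, mpos, match = spos[keep], mpos[keep], match[keep]
    if spos.size == 0:
        return None
    if score is None:
        score = _columns_score(spos, mpos, match, params)
    sp = spos[spos >= 0]
    qp = mpos[mpos >= 0]
    if strand == "-":
        # query coordinates were on the reverse complement of the mito genome
        m_start = int(mito_len - (qp.max() + 1))
        m_end = int(mito_len - qp.min())
    else:
        m_start, m_end = int(qp.min()), int(qp.max() + 1)
    ident = float(match.sum()) / spos.size
    ev = evalue(score, m, n, params.ka_lambda, params.ka_K)
    return MTPTSegment(mito_id, m_start, m_end, plastid_id, int(sp.min()),
                       int(sp.max() + 1), strand, int(spos.size), ident,
                       int(score), ev, _spos=spos, _mpos=mpos, _match=match)


def _mask_overlap(seg: MTPTSegment, mask: list[tuple[int, int]]) -> int:
    ov = 0
    for s, e in mask:
        ov += max(0, min(e, seg.plastid_end) - max(s, seg.plastid_start))
    return ov


def _apply_mask(segments, mask, params, mito_len, m, n):
    """Drop segments mostly inside the mask; trim straddlers and re-filter."""
    if not mask:
        return segments
    in_mask = np.zeros(max((e for _, e in mask), default=0), dtype=bool)
    for s, e in mask:
        in_mask[s:e] = True
    out = []
    for seg in segments:
        ov = _mask_overlap(seg, mask)
        span = seg.plastid_end - seg.plastid_start
        if ov == 0:
            out.append(seg)
            continue
        if ov * 2 > span:
            continue
        masked_col = (seg._spos >= 0) & (seg._spos < in_mask.size) & in_mask[
            np.clip(seg._spos, 0, in_mask.size - 1)]
        # keep each maximal unmasked run as its own candidate
        free = ~masked_col
        idx = np.flatnonzero(free)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_bounds = np.split(idx, breaks + 1)
        for run in run_bounds:
            sub = _make_segment(seg._spos[run], seg._mpos[run], seg._match[run],
                                seg.strand, mito_len, seg.mito_id, seg.plastid_id,
                                params, m, n)
            if sub is not None:
                out.append(sub)
    return out


def _passes_filters(seg: MTPTSegment, params: ScanParams) -> bool:
    return (seg.identity >= params.min_identity
            and seg.aligned_length >= params.min_length
            and seg.evalue <= params.max_evalue)


def _dedup(segments: list[MTPTSegment]) -> list[MTPTSegment]:
    """Greedy by score (tie: leftmost plastid_start); drop near-duplicates."""
    kept: list[MTPTSegment] = []
    for seg in sorted(segments, key=lambda s: (-s.score, s.plastid_start)):
        redundant = False
        for k in kept:
            if k.strand != seg.strand:
                continue
            po = max(0, min(k.plastid_end, seg.plastid_end) - max(k.plastid_start, seg.plastid_start))
            mo = max(0, min(k.mito_end, seg.mito_end) - max(k.mito_start, seg.mito_start))
            if po * 2 > (seg.plastid_end - seg.plastid_start) and \
               mo * 2 > (seg.mito_end - seg.mito_start):
                redundant = True
                break
        if not redundant:
            kept.append(seg)
    return sorted(kept, key=lambda s: (s.plastid_start, s.plastid_end, s.mito_start))


def find_mtpt_segments(mito: AnnotatedGenome, plastid: AnnotatedGenome,
                       params: ScanParams | None = None,
                       apply_mask: bool = True) -> list[MTPTSegment]:
    """Scan a mitochondrial genome against a plastid genome for MTPTs.

    Both strands are searched with exact word seeds; diagonal chains are
    extended ungapped with an X-drop, nearby chains are joined by a banded
    gapped DP, and every reported segment passes the identity, length and
    E-value filters and survives the plastid tRNA/rRNA mask.  Segments are
    sorted by plastid_start.
    """
    params = params or ScanParams()
    params.validate()
    if not mito.sequence or not plastid.sequence:
        raise ValueError("sequences must be non-empty")
    check_alphabet(mito.sequence, mito.id)
    check_alphabet(plastid.sequence, plastid.id)

    m, n = len(mito.sequence), len(plastid.sequence)
    senc = encode(plastid.sequence)
    smin = _min_score(params, m, n)
    candidates: list[MTPTSegment] = []

    for strand in "+-":
        qseq = mito.sequence if strand == "+" else revcomp(mito.sequence)
        qenc = encode(qseq)
        qhit, shit = _seed_hits(qenc, senc, params.word_size)
        if qhit.size == 0:
            continue
        keep = _prefilter_hits(qenc, senc, qhit, shit, params.word_size,
                               trigger_net=params.prefilter_net)
        qhit, shit = qhit[keep], shit[keep]
        if qhit.size == 0:
            continue
        d = shit - qhit
        order = np.lexsort((qhit, d))
        qhit, d = qhit[order], d[order]
        new_chain = np.ones(qhit.size, dtype=bool)
        new_chain[1:] = (np.diff(d) != 0) | (np.diff(qhit) > params.chain_gap)
        bounds = np.flatnonzero(np.r_[new_chain, True])

        # ungapped X-drop extension per seed chain
        hsps = {}
        for a, b in zip(bounds[:-1], bounds[1:]):
            diag = int(d[a])
            qs0, qs1 = int(qhit[a]), int(qhit[b - 1]) + params.word_size
            lext, _ = _xdrop_extend(qenc, senc, diag, qs0, -1, params.x_drop)
            rext, _ = _xdrop_extend(qenc, senc, diag, qs1, +1, params.x_drop)
            q0, q1 = qs0 - lext, qs1 + rext
            sc = int(np.where(qenc[q0:q1] == senc[q0 + diag : q1 + diag], 1, -2).sum()
                     ) if q1 > q0 else 0
            if sc >= min(params.gap_trigger, smin):
                hsps[(diag, q0, q1)] = sc

        # cluster HSPs across nearby diagonals for the gapped pass
        items = sorted(hsps.items(), key=lambda kv: (kv[0][1], kv[0][0]))
        clusters: list[list[tuple[tuple[int, int, int], int]]] = []
        for key, sc in items:
            diag, q0, q1 = key
            placed = False
            for cl in reversed(clusters):
                (d2, p0, p1), _ = cl[-1]
                if q0 - p1 > params.join_gap:
                    break
                if abs(diag - d2) <= params.band_pad:
                    cl.append((key, sc))
                    placed = True
                    break
            if not placed:
                clusters.append([(key, sc)])

        for cl in clusters:
            if len(cl) == 1:
                (diag, q0, q1), sc = cl[0]
                if q1 <= q0 or sc < min(params.gap_trigger, smin):
                    continue
                cols = _diag_columns(q0, q1, diag, qenc, senc)
                if sc >= params.gap_trigger:
                    cols = _extend_columns(*cols, qenc, senc, params)
                seg = _make_segment(*cols, strand, m, mito.id,
                                    plastid.id, params, m, n)
                if seg is not None and seg.score < smin:
                    continue
            else:
                q0 = min(k[1] for k, _ in cl)
                q1 = max(k[2] for k, _ in cl)
                top_key, top_sc = max(cl, key=lambda kv: kv[1])
                if (top_key[2] - top_key[1]) * 10 >= (q1 - q0) * 9:
                    # one HSP dominates the cluster span: extension from it
                    # recovers the rest without a wide DP window
                    diag, a0, a1 = top_key
                    cols = _diag_columns(a0, a1, diag, qenc, senc)
                    cols = _extend_columns(*cols, qenc, senc, params)
                    seg = _make_segment(*cols, strand, m, mito.id, plastid.id,
                                        params, m, n)
                    if seg is not None and seg.score >= smin:
                        candidates.append(seg)
                    continue
                dlo = min(k[0] for k, _ in cl) - params.band_pad
                dhi = max(k[0] for k, _ in cl) + params.band_pad
                s0 = max(0, q0 + dlo)
                s1 = min(n, q1 + dhi)
                if (q1 - q0) * (dhi - dlo + 1) > 6_000_000:
                    # window too large to join: fall back to per-HSP segments
                    for (diag, a0, a1), sc in cl:
                        if sc < smin:
                            continue
                        spos, mpos, match = _diag_columns(a0, a1, diag, qenc, senc)
                        seg = _make_segment(spos, mpos, match, strand, m, mito.id,
                                            plastid.id, params, m, n, score=sc)
                        if seg is not None:
                            candidates.append(seg)
                    continue
                score, cols = _banded_local_align(qenc, senc, q0, q1, s0, s1,
                                                  dlo, dhi, params)
                if cols is None:
                    continue
                cols = _extend_columns(*cols, qenc, senc, params)
                seg = _make_segment(*cols, strand, m, mito.id, plastid.id,
                                    params, m, n)
                if seg is not None and seg.score < smin:
                    continue
            if seg is not None:
                candidates.append(seg)

    if apply_mask:
        present = {f.type for f in plastid.features}
        mask_types = tuple(t for t in params.mask_types if t in present)
        mask = mask_features(plastid, mask_types) if mask_types else []
        candidates = _apply_mask(candidates, mask, params, m, m, n)
    passed = [s for s in candidates if _passes_filters(s, params)]
    return _dedup(passed)


# ---------------------------------------------------------------------------
# aggregation onto a backbone
# ---------------------------------------------------------------------------

def coverage_fraction(segments: list[MTPTSegment], plastid_length: int) -> float:
    """Union length of plastid-side intervals divided by plastid_length."""
    if plastid_length <= 0:
        raise ValueError("plastid_length must be positive")
    if not segments:
        return 0.0
    cover = np.zeros(plastid_length, dtype=bool)
    for seg in segments:
        cover[seg.plastid_start : seg.plastid_end] = True
    return float(cover.sum()) / plastid_length


def project_to_backbone(per_species_segments: dict[str, list[MTPTSegment]],
                        backbone: AnnotatedGenome) -> DepthProfile:
    """Species-depth profile on a reference plastid backbone.

    depth[i] = number of distinct species with >= 1 segment covering
    position i; multiple segments of one species count once.
    """
    L = len(backbone.sequence)
    depth = np.zeros(L, dtype=np.int32)
    covers = {}
    for species, segs in per_species_segments.items():
        cover = np.zeros(L, dtype=bool)
        for seg in segs:
            if seg.plastid_end > L:
                raise ValueError(
                    f"{species}: segment end {seg.plastid_end} beyond backbone length {L}")
            cover[seg.plastid_start : seg.plastid_end] = True
        covers[species] = cover
        depth += cover
    return DepthProfile(backbone.id, L, depth, len(per_species_segments), covers)


def _gene_counts(profile: DepthProfile, genes: list[Feature],
                 min_overlap: float = 0.5) -> dict[str, int]:
    counts = {}
    for g in genes:
        need = min_overlap * g.length
        cnt = 0
        for cover in profile.per_species_cover.values():
            if cover[g.start : g.end].sum() >= need:
                cnt += 1
        counts[g.name] = cnt
    return counts


def classify_gene_frequency(profile: DepthProfile, genes: list[Feature],
                            high: int = 20, mid: int = 10) -> dict[str, str]:
    """MTPT frequency class per gene: most_frequent (> high species),
    moderate (> mid), rare otherwise.

    A species counts for a gene when its segment union covers >= 50% of
    the gene span.
    """
    counts = _gene_counts(profile, genes)
    out = {}
    for name, cnt in counts.items():
        out[name] = ("most_frequent" if cnt > high
                     else "moderate" if cnt > mid else "rare")
    return out


def barcode_overlap_report(profile: DepthProfile, barcode_regions: list[Feature],
                           high: int = 20, mid: int = 10) -> pd.DataFrame:
    """Frequency count and class per named barcoding region."""
    counts = _gene_counts(profile, barcode_regions)
    rows = []
    for region in barcode_regions:
        cnt = counts[region.name]
        cls = "most_frequent" if cnt > high else "moderate" if cnt > mid else "rare"
        rows.append({"region": region.name, "start": region.start,
                     "end": region.end, "count": cnt, "class": cls})
    return pd.DataFrame(rows)
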