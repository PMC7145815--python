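"""Synonymous-divergence (Ks) estimation and molecular-clock dating.

The estimator is the Nei–Gojobori (1986) counting method: synonymous and
nonsynonymous *sites* are counted per codon as the fraction of one-step
changes that preserve the amino acid (changes to stop codons count as
nonsynonymous), and synonymous *differences* between a codon pair are
averaged over all minimal substitution paths, excluding paths that pass
through a stop codon.  The proportion pS = Sd/S is corrected for multiple
hits with the Jukes–Cantor formula

    Ks = -(3/4) * ln(1 - (4/3) * pS),

undefined ("saturated") when pS >= 3/4.

Dating uses the organelle molecular clock T = Ks / (2*lambda) with
compartment-specific synonymous rates (plastid 2e-9, mitochondrion 0.6e-9
substitutions/site/year by default).  For a plastid gene versus its MTPT
copy the two lineages evolve at *different* rates after the transfer, so
the flux date divides by the rate sum by default; the 2*lambda readings
are exposed as alternatives.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from ._seq import BASES, CODON_TABLE, STOP_CODONS, translate, internal_stop_index

__all__ = [
    "KsEstimate",
    "RateModel",
    "codon_align",
    "trim_alignment",
    "ks_ng86",
    "ks_mode",
    "ks_pooled",
    "divergence_time",
    "flux_time",
    "syn_sites",
    "codon_pair_differences",
]


@dataclass
class KsEstimate:
    """Per-gene synonymous divergence with NG86 site/difference counts."""

    gene_id: str
    ks: float  # NaN when saturated
    s_sites: float  # NG86 synonymous site count (averaged over both seqs)
    sd: float  # synonymous difference count
    saturated: bool = False
    n_sites: float = 0.0
    nd: float = 0.0


@dataclass
class RateModel:
    """Compartment-specific synonymous substitution rates (subs/site/year)."""

    lambda_pt: float = 2e-9
    lambda_mt: float = 0.6e-9

    def __post_init__(self) -> None:
        if self.lambda_pt <= 0 or self.lambda_mt <= 0:
            raise ValueError("substitution rates must be positive")


# ---------------------------------------------------------------------------
# NG86 codon tables (precomputed once at import)
# ---------------------------------------------------------------------------

def syn_sites(codon: str) -> float:
    """NG86 synonymous site count of one sense codon.

    Each position contributes (# synonymous one-step changes)/3; changes
    producing a stop codon are nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal paths.

    Paths passing through a stop codon are discarded; if every path is
    blocked the average falls back to all paths.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []  # (syn?, through_stop?)
        blocked = False
        for k, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            syn = CODON_TABLE[cur] == CODON_TABLE[nxt] and CODON_TABLE[nxt] != "*"
            if nxt in STOP_CODONS and k < len(order) - 1:
                blocked = True
            steps.append(syn)
            cur = nxt
        paths.append((blocked, steps))
    valid = [steps for blocked, steps in paths if not blocked]
    if not valid:
        valid = [steps for _, steps in paths]
    sd = float(np.mean([sum(steps) for steps in valid]))
    return sd, float(len(diff)) - sd


def _codon_index(codon: str) -> int:
    idx = 0
    for c in codon:
        p = BASES.find(c)
        if p < 0:
            return -1
        idx = idx * 4 + p
    return idx


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s_tab = np.full(64, np.nan)
    sd_tab = np.full((64, 64), np.nan)
    nd_tab = np.full((64, 64), np.nan)
    sense = [c for c in CODON_TABLE if c not in STOP_CODONS]
    for c in sense:
        s_tab[_codon_index(c)] = syn_sites(c)
    for c1 in sense:
        for c2 in sense:
            sd, nd = codon_pair_differences(c1, c2)
            sd_tab[_codon_index(c1), _codon_index(c2)] = sd
            nd_tab[_codon_index(c1), _codon_index(c2)] = nd
    return s_tab, sd_tab, nd_tab


_S_TAB, _SD_TAB, _ND_TAB = _build_tables()

# synonymous one-step change options per sense codon, used by the simulator
SYNONYMOUS_OPTIONS: dict[str, list[tuple[int, str]]] = {}
for _c in CODON_TABLE:
    if _c in STOP_CODONS:
        continue
    opts = []
    for _pos in range(3):
        for _b in BASES:
            if _b == _c[_pos]:
                continue
            _alt = _c[:_pos] + _b + _c[_pos + 1 :]
            if CODON_TABLE[_alt] == CODON_TABLE[_c]:
                opts.append((_pos, _b))
    SYNONYMOUS_OPTIONS[_c] = opts


# ---------------------------------------------------------------------------
# Codon-aware alignment
# ---------------------------------------------------------------------------

def _protein_aligner(open_gap: float = -10.0, extend_gap: float = -1.0):
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _validate_cds(cds: str, name: str) -> None:
    if len(cds) % 3:
        raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
    idx = internal_stop_index(cds)
    if idx is not None:
        raise ValueError(f"{name}: internal stop codon at codon index {idx}")


def codon_align(cds_a: str, cds_b: str, open_gap: float = -10.0,
                extend_gap: float = -1.0) -> tuple[str, str]:
    """Globally align two coding sequences through their translations.

    The protein alignment (BLOSU M62, affine gaps) is back-projected onto
    the nucleotides, so every gap is a whole number of codons.  Terminal
    stop codons are carried through as a final codon column (stop vs stop,
    or stop vs gap) and removed later by :func:`trim_alignment`.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    _validate_cds(cds_a, "cds_a")
    _validate_cds(cds_b, "cds_b")

    stop_a = cds_a[-3:] in STOP_CODONS if cds_a else False
    stop_b = cds_b[-3:] in STOP_CODONS if cds_b else False
    core_a = cds_a[:-3] if stop_a else cds_a
    core_b = cds_b[:-3] if stop_b else cds_b
    prot_a = translate(core_a)
    prot_b = translate(core_b)

    aln = _protein_aligner(open_gap, extend_gap).align(prot_a, prot_b)[0]
    pa, pb = str(aln[0]), str(aln[1])

    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(pa, pb):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(core_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(core_b[3 * ib : 3 * ib + 3])
            ib += 1
    if stop_a or stop_b:
        out_a.append(cds_a[-3:] if stop_a else "---")
        out_b.append(cds_b[-3:] if stop_b else "---")
    return "".join(out_a), "".join(out_b)


def trim_alignment(aln: tuple[str, str]) -> tuple[str, str]:
    """Drop codon columns containing a gap, and terminal stop columns."""
    a, b = aln
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("expected a codon alignment of equal lengths")
    cols = [
        (a[i : i + 3], b[i : i + 3])
        for i in range(0, len(a), 3)
        if "-" not in a[i : i + 3] and "-" not in b[i : i + 3]
    ]
    while cols and (cols[-1][0] in STOP_CODONS or cols[-1][1] in STOP_CODONS):
        cols.pop()
    return "".join(c[0] for c in cols), "".join(c[1] for c in cols)


# ---------------------------------------------------------------------------
# Ks estimation
# ---------------------------------------------------------------------------

def ks_ng86(aln: tuple[str, str], gene_id: str = "") -> KsEstimate:
    """NG86 Ks with Jukes–Cantor correction on a trimmed codon alignment."""
    a, b = aln
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("expected a trimmed codon alignment of equal lengths")
    if not a:
        raise ValueError("empty alignment")
    n_codons = len(a) // 3
    ia = np.array([_codon_index(a[3 * i : 3 * i + 3]) for i in range(n_codons)])
    ib = np.array([_codon_index(b[3 * i : 3 * i + 3]) for i in range(n_codons)])
    ok = (ia >= 0) & (ib >= 0)
    ok &= ~np.isnan(_S_TAB[np.where(ok, ia, 0)]) & ~np.isnan(_S_TAB[np.where(ok, ib, 0)])
    if not ok.any():
        raise ValueError("no scorable codon columns")
    ia, ib = ia[ok], ib[ok]
    s = float((_S_TAB[ia].sum() + _S_TAB[ib].sum()) / 2.0)
    n = 3.0 * len(ia) - s
    sd = float(_SD_TAB[ia, ib].sum())
    nd = float(_ND_TAB[ia, ib].sum())
    ps = sd / s if s > 0 else 0.0
    if ps >= 0.75:
        return KsEstimate(gene_id, float("nan"), s, sd, True, n, nd)
    ks = -0.75 * np.log(1.0 - ps * 4.0 / 3.0) + 0.0  # +0.0 normalizes -0.0
    return KsEstimate(gene_id, float(ks), s, sd, False, n, nd)


def ks_pooled(estimates: list[KsEstimate], gene_id: str = "pooled") -> KsEstimate:
    """Sitewise-pooled Ks over many gene pairs: sum(Sd)/sum(S), JC-corrected.

    At organelle-scale divergence a single gene carries only a handful of
    synonymous differences, so per-gene Ks is coarsely discrete; pooling
    counts across genes before the correction gives the natural combined
    estimate.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    sd = float(sum(e.sd for e in estimates))
    s = float(sum(e.s_sites for e in estimates))
    n = float(sum(e.n_sites for e in estimates))
    nd = float(sum(e.nd for e in estimates))
    ps = sd / s if s > 0 else 0.0
    if ps >= 0.75:
        return KsEstimate(gene_id, float("nan"), s, sd, True, n, nd)
    ks = -0.75 * np.log(1.0 - ps * 4.0 / 3.0) + 0.0
    return KsEstimate(gene_id, float(ks), s, sd, False, n, nd)


def ks_mode(values, grid_step: float = 5e-4) -> float:
    """Mode of a Ks distribution via Gaussian KDE (Silverman bandwidth).

    Ties on the evaluation grid break toward the smallest value.  With
    fewer than 5 finite values falls back to the median with a warning.
    """
    vals = np.asarray([v for v in np.atleast_1d(values) if np.isfinite(v)], dtype=float)
    if vals.size < 5:
        warnings.warn("fewer than 5 finite Ks values; returning median", stacklevel=2)
        return float(np.median(vals)) if vals.size else float("nan")
    if np.ptp(vals) == 0:
        return float(vals[0])
    kde = gaussian_kde(vals, bw_method="silverman")
    h = float(kde.factor * vals.std(ddof=1))
    grid = np.arange(max(0.0, vals.min() - 3 * h), vals.max() + 3 * h + grid_step, grid_step)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])  # argmax returns first => smallest


def divergence_time(ks: float, lam: float) -> float:
    """Divergence date in years under a strict clock: T = Ks / (2*lambda)."""
    if not np.isfinite(ks):
        raise ValueError("saturated Ks: divergence time undefined")
    if ks < 0 or lam <= 0:
        raise ValueError("require ks >= 0 and lambda > 0")
    return ks / (2.0 * lam)


def flux_time(ks_pt_vs_mtpt: float, rates: RateModel | None = None,
              clock: str = "sum") -> float:
    """Date of a plastid→mitochondrion transfer from plastid-vs-MTPT Ks.

    clock='sum' (default) divides by lambda_pt + lambda_mt, the divergence
    rate of two copies evolving in different compartments; '2pt' and '2mt'
    give the single-compartment readings.
    """
    rates = rates or RateModel()
    if not np.isfinite(ks_pt_vs_mtpt):
        raise ValueError("saturated Ks: flux time undefined")
    if ks_pt_vs_mtpt < 0:
        raise ValueError("require ks >= 0")
    if clock == "sum":
        denom = rates.lambda_pt + rates.lambda_mt
    elif clock == "2pt":
        denom = 2.0 * rates.lambda_pt
    elif clock == "2mt":
        denom = 2.0 * rates.lambda_mt
    else:
        raise ValueError(f"unknown clock {clock!r} (expected sum, 2pt or 2mt)")
    return ks_pt_vs_mtpt / denom
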