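"""Synthetic organelle genomes with planted MTPTs under a two-rate clock.

The generator emulates the study system: two sister species whose common
ancestor acquired plastid-derived blocks (MTPTs) in its mitochondrial
genome at ``t_flux`` years ago, with the species splitting ``t_split``
years ago.  Coding sequences accumulate only synonymous substitutions, so
the NG86 estimator can be validated directly against lambda*t; intergenic
sequence evolves under Jukes–Cantor at three times the synonymous rate as
a neutral proxy.  Defaults mirror the study conditions: a ~160 kb plastid
with 75 protein-coding genes, 35% of the plastid copied into the
mitochondrion, plastid/mitochondrial synonymous rates of 2e-9 and 0.6e-9
per site per year, a split ~2 Mya and a flux episode ~10.7 Mya, and an
88% plastid share of organelle reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import SENSE_CODONS, STOP_CODONS, random_dna, revcomp, translate
from .genome import AnnotatedGenome, Feature
from .ks import SYNONYMOUS_OPTIONS, _S_TAB, _codon_index

__all__ = [
    "FluxScenario",
    "MTPTTruth",
    "Species",
    "SpeciesPair",
    "simulate_ancestral_plastid",
    "evolve_synonymous",
    "evolve_intergenic",
    "evolve_genome",
    "simulate_flux_scenario",
    "simulate_allele_depths",
    "simulate_genotype_table",
]

_MIN_GAP = 20  # minimal intergenic spacer when packing features
_TRNA_LEN = 72
_RRNA_LEN = 1500


@dataclass
class FluxScenario:
    """Parameters of one simulated plastid→mitochondrion flux history."""

    t_split: float = 2.0e6          # years since the two species diverged
    t_flux: float = 10.7e6          # years since MTPT insertion in the ancestor
    lambda_pt: float = 2e-9         # plastid synonymous rate (subs/site/year)
    lambda_mt: float = 0.6e-9       # mitochondrial synonymous rate
    plastid_length: int = 160_000
    n_genes: int = 75
    mtpt_fraction: float = 0.35     # fraction of the plastid copied into the mito
    copy_fraction_pt: float = 0.88  # expected plastid share of organelle reads
    seed: int = 0
    # generator mechanics (not part of the headline conditions)
    gene_codons: int = 300
    n_mtpt_blocks: int = 5
    block_size_range: tuple[int, int] = (300, 20_000)
    mito_background_factor: float = 2.0
    intergenic_factor: float = 3.0

    def validate(self) -> None:
        if not (self.t_flux >= self.t_split >= 0):
            raise ValueError("require t_flux >= t_split >= 0")
        if not (0 < self.lambda_mt <= self.lambda_pt):
            raise ValueError("require 0 < lambda_mt <= lambda_pt")
        if not (0 <= self.mtpt_fraction <= 1):
            raise ValueError("mtpt_fraction must lie in [0,1]")
        if not (0 <= self.copy_fraction_pt <= 1):
            raise ValueError("copy_fraction_pt must lie in [0,1]")
        if self.plastid_length < 1000 or self.n_genes < 1:
            raise ValueError("require plastid_length >= 1000 and n_genes >= 1")


@dataclass
class MTPTTruth:
    """One planted MTPT block: mito interval, plastid source, orientation."""

    mito_start: int
    mito_end: int
    plastid_start: int
    plastid_end: int
    strand: str
    genes: list[str] = field(default_factory=list)


@dataclass
class Species:
    plastid: AnnotatedGenome
    mito: AnnotatedGenome


@dataclass
class SpeciesPair:
    species_a: Species
    species_b: Species
    truth: FluxScenario
    mtpt_truth: dict[str, list[MTPTTruth]]
    ancestral_plastid: AnnotatedGenome | None = None
    ancestral_mito: AnnotatedGenome | None = None


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; no internal stops by construction."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons (start, body, stop)")
    body = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
    stop = sorted(STOP_CODONS)[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _pack_intervals(rng: np.random.Generator, total: int, lengths: list[int],
                    min_gap: int = _MIN_GAP) -> list[int]:
    """Random non-overlapping placement of blocks of given lengths; returns starts."""
    k = len(lengths)
    occupied = sum(lengths) + (k + 1) * min_gap
    free = total - occupied
    if free < 0:
        raise ValueError(
            f"cannot pack {k} features totaling {sum(lengths)} bp into {total} bp")
    extra = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
    starts, pos = [], 0
    for i, ln in enumerate(lengths):
        pos += min_gap + int(extra[i])
        starts.append(pos)
        pos += ln
    return starts


def simulate_ancestral_plastid(length: int, n_genes: int, seed: int | None = None,
                               gene_codons: int = 300,
                               rng: np.random.Generator | None = None,
                               genome_id: str = "ancestral_plastid") -> AnnotatedGenome:
    """Uniform-random plastid genome with non-overlapping CDS, one tRNA, one rRNA.

    Deterministic for a fixed seed.  Raises ValueError when the requested
    genes cannot fit.
    """
    if length < 1000 or n_genes < 1:
        raise ValueError("require length >= 1000 and n_genes >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)

    gene_len = 3 * gene_codons
    rrna_len = min(_RRNA_LEN, max(100, length // 20))
    lengths = [gene_len] * n_genes + [_TRNA_LEN, rrna_len]
    kinds = [("CDS", f"gene{i + 1:03d}") for i in range(n_genes)]
    kinds += [("tRNA", "trnX"), ("rRNA", "rrnX")]
    order = rng.permutation(len(lengths))
    lengths = [lengths[i] for i in order]
    kinds = [kinds[i] for i in order]
    starts = _pack_intervals(rng, length, lengths)

    seq = list(random_dna(rng, length))
    feats = []
    for (ftype, name), start, ln in zip(kinds, starts, lengths):
        strand = "+" if rng.random() < 0.5 else "-"
        if ftype == "CDS":
            cds = _random_cds(rng, ln // 3)
            ins = revcomp(cds) if strand == "-" else cds
            seq[start : start + ln] = ins
        feats.append(Feature(ftype, start, start + ln, strand, name))
    feats.sort(key=lambda f: f.start)
    g = AnnotatedGenome(genome_id, "".join(seq), feats)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# mutation processes
# ---------------------------------------------------------------------------

def ng86_site_count(cds: str) -> float:
    """Total NG86 synonymous site count of a CDS (stop codons contribute 0)."""
    total = 0.0
    for i in range(0, len(cds), 3):
        idx = _codon_index(cds[i : i + 3])
        if idx >= 0 and np.isfinite(_S_TAB[idx]):
            total += _S_TAB[idx]
    return total


def evolve_synonymous(cds: str, rate: float, years: float,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> str:
    """Apply a Poisson number of synonymous single-base changes to a CDS.

    The event count has mean rate * years * S where S is the NG86
    synonymous-site count of the input; each event picks a codon with
    probability proportional to its current number of synonymous one-step
    options, then one option uniformly.  The translation is invariant.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    if rate < 0 or years < 0:
        raise ValueError("rate and years must be non-negative")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon index {i}")
    rng = rng if rng is not None else np.random.default_rng(seed)

    s_total = ng86_site_count(cds)
    n_events = int(rng.poisson(rate * years * s_total))
    if n_events == 0:
        return cds
    counts = np.array([len(SYNONYMOUS_OPTIONS.get(c, ())) for c in codons], dtype=float)
    for _ in range(n_events):
        total = counts.sum()
        if total == 0:
            break
        i = int(rng.choice(len(codons), p=counts / total))
        pos, base = SYNONYMOUS_OPTIONS[codons[i]][rng.integers(0, int(counts[i]))]
        codons[i] = codons[i][:pos] + base + codons[i][pos + 1 :]
        counts[i] = len(SYNONYMOUS_OPTIONS.get(codons[i], ()))
    out = "".join(codons)
    assert translate(out) == translate(cds)
    return out


def evolve_intergenic(seq: str, rate: float, years: float,
                      rng: np.random.Generator) -> str:
    """Jukes–Cantor substitutions at the given per-site rate (no indels)."""
    if not seq or rate * years == 0:
        return seq
    n_events = int(rng.poisson(rate * years * len(seq)))
    if n_events == 0:
        return seq
    chars = list(seq)
    positions = rng.integers(0, len(chars), size=n_events)
    for p in positions:
        cur = chars[p]
        alts = [b for b in "ACGT" if b != cur]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars)


def evolve_genome(genome: AnnotatedGenome, syn_rate: float, years: float,
                  rng: np.random.Generator, intergenic_factor: float = 3.0,
                  new_id: str | None = None) -> AnnotatedGenome:
    """Evolve one lineage: synonymous-only in CDS, JC elsewhere.

    tRNA/rRNA features are treated as intergenic for mutation purposes;
    coordinates never change (no indel process).
    """
    seq = list(genome.sequence)
    in_cds = np.zeros(len(seq), dtype=bool)
    for f in genome.features_of_type("CDS"):
        in_cds[f.start : f.end] = True
        new_cds = evolve_synonymous(genome.feature_seq(f), syn_rate, years, rng=rng)
        if f.strand == "-":
            new_cds = revcomp(new_cds)
        seq[f.start : f.end] = new_cds
    inter_idx = np.flatnonzero(~in_cds)
    if inter_idx.size:
        n_events = int(rng.poisson(intergenic_factor * syn_rate * years * inter_idx.size))
        for p in rng.choice(inter_idx, size=n_events) if n_events else []:
            cur = seq[p]
            alts = [b for b in "ACGT" if b != cur]
            seq[p] = alts[rng.integers(0, 3)]
    return AnnotatedGenome(new_id or genome.id, "".join(seq), list(genome.features))


# ---------------------------------------------------------------------------
# flux scenario
# ---------------------------------------------------------------------------

def _draw_block_intervals(rng: np.random.Generator, scenario: FluxScenario
                          ) -> list[tuple[int, int]]:
    """Non-overlapping plastid source intervals totaling ~mtpt_fraction*L."""
    L = scenario.plastid_length
    target = scenario.mtpt_fraction * L
    if target < 1:
        return []
    lo, hi = scenario.block_size_range
    k = scenario.n_mtpt_blocks
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))
    sizes = np.maximum((sizes * target / sizes.sum()).astype(int), 30)
    # rescale once more after the floor so the planted total stays on target
    sizes = np.maximum((sizes * target / sizes.sum()).astype(int), 30)
    if sizes.sum() + (k + 1) * _MIN_GAP > L:
        raise ValueError("mtpt_fraction too large for block packing")
    starts = _pack_intervals(rng, L, [int(s) for s in sizes])
    return [(s, s + int(ln)) for s, ln in zip(starts, sizes)]


def simulate_flux_scenario(scenario: FluxScenario) -> SpeciesPair:
    """Simulate the full two-species history and return genomes plus truth.

    Timeline: the ancestral plastid exists at t_flux, when its blocks are
    copied into the ancestral mitochondrial background; both lineages
    evolve to t_split at their compartment rates, then split into species
    A and B which evolve independently to the present.
    """
    scenario.validate()
    root = np.random.SeedSequence(scenario.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(8)]

    p0 = simulate_ancestral_plastid(
        scenario.plastid_length, scenario.n_genes, rng=rngs[0],
        gene_codons=scenario.gene_codons, genome_id="ancestral_plastid")

    blocks = _draw_block_intervals(rngs[1], scenario)
    bg_len = int(scenario.mito_background_factor * scenario.plastid_length)
    background = random_dna(rngs[1], bg_len)
    ins_points = np.sort(rngs[1].choice(bg_len, size=len(blocks), replace=False)) \
        if blocks else np.array([], dtype=int)

    mito_parts, truth, feats = [], [], []
    prev = 0
    offset = 0
    for (ps, pe), ip in zip(blocks, ins_points):
        strand = "+" if rngs[1].random() < 0.5 else "-"
        block_seq = p0.sequence[ps:pe]
        if strand == "-":
            block_seq = revcomp(block_seq)
        mito_parts.append(background[prev:ip])
        m_start = offset + (ip - prev)
        mito_parts.append(block_seq)
        genes_in = []
        for f in p0.features:
            if f.start >= ps and f.end <= pe:
                if strand == "+":
                    fs, fe, fstr = m_start + f.start - ps, m_start + f.end - ps, f.strand
                else:
                    fs = m_start + (pe - f.end)
                    fe = m_start + (pe - f.start)
                    fstr = "-" if f.strand == "+" else "+"
                feats.append(Feature(f.type, fs, fe, fstr, f.name))
                if f.type == "CDS":
                    genes_in.append(f.name)
        truth.append(MTPTTruth(m_start, m_start + len(block_seq), ps, pe, strand, genes_in))
        offset = m_start + len(block_seq)
        prev = ip
    mito_parts.append(background[prev:])
    m0 = AnnotatedGenome("ancestral_mito", "".join(mito_parts),
                         sorted(feats, key=lambda f: f.start))
    m0.validate()

    dt = scenario.t_flux - scenario.t_split
    ifac = scenario.intergenic_factor
    p1 = evolve_genome(p0, scenario.lambda_pt, dt, rngs[2], ifac)
    m1 = evolve_genome(m0, scenario.lambda_mt, dt, rngs[2], ifac)

    def tip(name: str, rng: np.random.Generator) -> Species:
        pt = evolve_genome(p1, scenario.lambda_pt, scenario.t_split, rng, ifac,
                           new_id=f"{name}_plastid")
        mt = evolve_genome(m1, scenario.lambda_mt, scenario.t_split, rng, ifac,
                           new_id=f"{name}_mito")
        return Species(pt, mt)

    sp_a = tip("speciesA", rngs[3])
    sp_b = tip("speciesB", rngs[4])
    return SpeciesPair(sp_a, sp_b, replace(scenario),
                       {"speciesA": list(truth), "speciesB": list(truth)},
                       ancestral_plastid=p0, ancestral_mito=m0)


# ---------------------------------------------------------------------------
# read depths and genotype tables
# ---------------------------------------------------------------------------

def simulate_allele_depths(copy_fraction_pt: float, total_depth: int,
                           n_sites: int, seed: int | None = None,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Binomial plastid/mitochondrial allele depths at diagnostic sites.

    Each site's plastid-allele depth ~ Binomial(total_depth,
    copy_fraction_pt); the mitochondrial depth is the remainder, so the
    per-site total is conserved.
    """
    if total_depth < 1:
        raise ValueError("total_depth must be >= 1")
    if not 0 <= copy_fraction_pt <= 1:
        raise ValueError("copy_fraction_pt must lie in [0,1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    d_pt = rng.binomial(total_depth, copy_fraction_pt, size=n_sites)
    return pd.DataFrame({
        "site": np.arange(n_sites),
        "depth_pt": d_pt,
        "depth_mt": total_depth - d_pt,
    })


def simulate_genotype_table(n_target: int, n_other: int, n_markers: int,
                            seed: int | None = None,
                            off_freq=0.0, target_freq_in_other=0.0,
                            exact_target_offtype: int | None = None,
                            exact_other_target: int | None = None):
    """Collections × markers allele calls with ground-truth species labels.

    ``off_freq`` is the per-marker probability that a target-species
    collection carries the off-type allele at that marker (intraspecies
    plastid diversity); ``target_freq_in_other`` the converse.  The
    ``exact_*`` arguments force exactly that many collections of a class
    to carry at least one cross-class allele (the forced collections keep
    at least one allele of their own class, so they are heterogeneous
    rather than fully off-profile).
    """
    from .authenticate import GenotypeTable

    if n_markers < 1:
        raise ValueError("need at least one marker")
    rng = np.random.default_rng(seed)
    off_freq = np.broadcast_to(np.asarray(off_freq, dtype=float), (n_markers,))
    tgt_freq = np.broadcast_to(np.asarray(target_freq_in_other, dtype=float), (n_markers,))
    markers = [f"M{i + 1}" for i in range(n_markers)]

    def build(n_coll: int, own: str, cross: str, freqs, exact: int | None, prefix: str):
        rows, ids = [], []
        if exact is not None:
            if not 0 <= exact <= n_coll:
                raise ValueError("exact count out of range")
            carriers = set(rng.choice(n_coll, size=exact, replace=False).tolist())
        else:
            carriers = None
        for i in range(n_coll):
            calls = np.where(rng.random(n_markers) < freqs, cross, own)
            if carriers is not None:
                if i in carriers:
                    if (calls == cross).sum() == 0:
                        calls[rng.integers(0, n_markers)] = cross
                    if n_markers > 1 and (calls == own).sum() == 0:
                        calls[rng.integers(0, n_markers)] = own
                else:
                    calls[:] = own
            rows.append(list(calls))
            ids.append(f"{prefix}{i + 1:02d}")
        return ids, rows

    t_ids, t_rows = build(n_target, "target", "off", off_freq, exact_target_offtype, "T")
    o_ids, o_rows = build(n_other, "off", "target", tgt_freq, exact_other_target, "O")
    collections = [(i, "target") for i in t_ids] + [(i, "other") for i in o_ids]
    calls = pd.DataFrame(t_rows + o_rows, index=t_ids + o_ids, columns=markers)
    return GenotypeTable(collections=collections, markers=markers, calls=calls)
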