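"""End-to-end workflow: simulate → scan → backbone → ks → date → markers →
pcr → authenticate, with a machine-readable summary.

One global seed fans out to per-stage seeds by fixed offsets, so a rerun
with the same configuration reproduces every stage byte-for-byte.
Results go to files; logging goes to stderr; the summary JSON is the
single source of truth for downstream checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .authenticate import evaluate_rules
from .genome import AnnotatedGenome
from .ks import (RateModel, codon_align, divergence_time, flux_time, ks_mode,
                 ks_ng86, ks_pooled, trim_alignment)
from .markers import MarkerRules, assess_coamplification, call_variants, design_markers, filter_promiscuous
from .scan import ScanParams, classify_gene_frequency, coverage_fraction, find_mtpt_segments, project_to_backbone
from .simulate import FluxScenario, simulate_flux_scenario, simulate_genotype_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "segments_to_frame", "ks_table"]

_STAGE_OFFSETS = {"simulate": 1, "authenticate": 7}


@dataclass
class RunConfig:
    outdir: str = "plastoflux_out"
    seed: int = 0
    scenario: FluxScenario = field(default_factory=FluxScenario)
    scan_params: ScanParams = field(default_factory=ScanParams)
    rates: RateModel = field(default_factory=RateModel)
    marker_rules: MarkerRules = field(default_factory=MarkerRules)
    flux_clock: str = "sum"
    rule: str = "both"  # authentication rule(s) to report
    n_target: int = 27
    n_other: int = 26
    n_markers: int = 3
    off_freq: float = 0.2
    target_freq_in_other: float = 0.05

    def validate(self) -> None:
        self.scenario.validate()
        self.scan_params.validate()
        if self.rule not in ("positive", "negative", "both"):
            raise ValueError("rule must be positive, negative or both")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, (FluxScenario, ScanParams, RateModel, MarkerRules)):
                for k, v in value.items():
                    if not hasattr(current, k):
                        raise ValueError(f"unknown {key} key {k!r}")
                    setattr(current, k, type(getattr(current, k))(v)
                            if not isinstance(getattr(current, k), tuple) else tuple(v))
            else:
                setattr(cfg, key, type(current)(value))
        cfg.validate()
        return cfg


def segments_to_frame(segments) -> pd.DataFrame:
    return pd.DataFrame([{
        "mito_id": s.mito_id, "mito_start": s.mito_start, "mito_end": s.mito_end,
        "plastid_id": s.plastid_id, "plastid_start": s.plastid_start,
        "plastid_end": s.plastid_end, "strand": s.strand,
        "length": s.aligned_length, "identity": round(s.identity, 4),
        "score": s.score, "evalue": s.evalue,
    } for s in segments], columns=["mito_id", "mito_start", "mito_end",
                                   "plastid_id", "plastid_start", "plastid_end",
                                   "strand", "length", "identity", "score", "evalue"])


def ks_table(estimates) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": e.gene_id, "ks": e.ks, "s_sites": e.s_sites,
        "sd": e.sd, "saturated": e.saturated,
    } for e in estimates], columns=["gene_id", "ks", "s_sites", "sd", "saturated"])


def _pair_ks(genome_x: AnnotatedGenome, genome_y: AnnotatedGenome):
    """Ks per CDS name shared by two annotated genomes."""
    by_name = {f.name: f for f in genome_y.features_of_type("CDS")}
    out = []
    for f in genome_x.features_of_type("CDS"):
        g = by_name.get(f.name)
        if g is None:
            continue
        aln = trim_alignment(codon_align(genome_x.feature_seq(f), genome_y.feature_seq(g)))
        if aln[0]:
            out.append(ks_ng86(aln, f.name))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write per-stage outputs, return the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- simulate -----------------------------------------------------------
    scen = config.scenario
    scen.seed = config.seed + _STAGE_OFFSETS["simulate"]
    pair = simulate_flux_scenario(scen)
    genomes = {
        "speciesA_plastid": pair.species_a.plastid,
        "speciesA_mito": pair.species_a.mito,
        "speciesB_plastid": pair.species_b.plastid,
        "speciesB_mito": pair.species_b.mito,
    }
    pio.write_fasta(outdir / "genomes.fasta", list(genomes.values()))
    for name, g in genomes.items():
        pio.write_gff3(outdir / f"{name}.gff3", g)
    pio.write_bed(outdir / "mtpt_truth.bed", [
        (f"{sp}_mito", t.mito_start, t.mito_end, f"src:{t.plastid_start}-{t.plastid_end}({t.strand})")
        for sp, truths in pair.mtpt_truth.items() for t in truths])
    logger.info("simulated %d genomes", len(genomes))

    # --- scan ---------------------------------------------------------------
    segs = {}
    cov = {}
    for sp in ("speciesA", "speciesB"):
        mito = genomes[f"{sp}_mito"]
        plastid = genomes[f"{sp}_plastid"]
        segs[sp] = find_mtpt_segments(mito, plastid, config.scan_params)
        cov[sp] = coverage_fraction(segs[sp], len(plastid.sequence))
        pio.write_tsv(outdir / f"{sp}_segments.tsv", segments_to_frame(segs[sp]))
    summary["coverage_fraction"] = cov

    # --- backbone -----------------------------------------------------------
    backbone = genomes["speciesA_plastid"]
    per_species = {
        "speciesA": segs["speciesA"],
        "speciesB": find_mtpt_segments(genomes["speciesB_mito"], backbone,
                                       config.scan_params),
    }
    profile = project_to_backbone(per_species, backbone)
    pio.write_tsv(outdir / "depth_profile.tsv", pd.DataFrame({
        "position": np.arange(profile.length), "depth": profile.depth}))
    gene_class = classify_gene_frequency(profile, backbone.features_of_type("CDS"),
                                         high=1, mid=0)
    pio.write_tsv(outdir / "gene_frequency.tsv", pd.DataFrame(
        [{"gene": k, "class": v} for k, v in sorted(gene_class.items())]))
    summary["max_depth"] = int(profile.depth.max()) if profile.length else 0

    # --- ks + dating --------------------------------------------------------
    ks_split = _pair_ks(pair.species_a.plastid, pair.species_b.plastid)
    ks_flux = _pair_ks(pair.species_a.mito, pair.species_a.plastid)
    pio.write_tsv(outdir / "ks_plastid_AB.tsv", ks_table(ks_split))
    pio.write_tsv(outdir / "ks_mtpt_vs_plastid_A.tsv", ks_table(ks_flux))
    dating = {}
    finite_split = [e for e in ks_split if not e.saturated]
    if finite_split:
        mode = ks_mode([e.ks for e in finite_split])
        pooled = ks_pooled(finite_split)
        dating["ks_mode_plastid_AB"] = mode
        dating["ks_pooled_plastid_AB"] = pooled.ks
        dating["t_split_years"] = divergence_time(pooled.ks, config.rates.lambda_pt)
    finite_flux = [e for e in ks_flux if not e.saturated]
    if finite_flux:
        mode = ks_mode([e.ks for e in finite_flux])
        pooled = ks_pooled(finite_flux)
        dating["ks_mode_mtpt_vs_plastid"] = mode
        dating["ks_pooled_mtpt_vs_plastid"] = pooled.ks
        dating["t_flux_years"] = flux_time(pooled.ks, config.rates, config.flux_clock)
    summary["dating"] = dating
    (outdir / "dating.json").write_text(json.dumps(dating, indent=2))

    # --- markers + pcr ------------------------------------------------------
    sites = call_variants(pair.species_a.plastid, pair.species_b.plastid)
    sites = filter_promiscuous(sites)
    mk = design_markers(sites, pair.species_a.plastid, config.marker_rules)
    reports = [assess_coamplification(m, pair.species_a.plastid,
                                      pair.species_a.mito, segs["speciesA"])
               for m in mk]
    pio.write_tsv(outdir / "markers.tsv", pd.DataFrame([{
        "name": m.name, "mode": m.mode, "forward": m.forward_primer,
        "reverse": m.reverse_primer, "len_a": m.amplicon_len_a,
        "len_b": m.amplicon_len_b,
        "class": r.classification} for m, r in zip(mk, reports)]))
    summary["n_variants"] = len(sites)
    summary["markers"] = {m.name: r.classification for m, r in zip(mk, reports)}

    # --- authenticate -------------------------------------------------------
    table = simulate_genotype_table(
        config.n_target, config.n_other, config.n_markers,
        seed=config.seed + _STAGE_OFFSETS["authenticate"],
        off_freq=config.off_freq, target_freq_in_other=config.target_freq_in_other)
    pio.write_genotype_tsv(outdir / "genotypes.tsv", table)
    pos, neg = evaluate_rules(table)
    rules = {}
    if config.rule in ("positive", "both"):
        rules["positive"] = asdict(pos)
    if config.rule in ("negative", "both"):
        rules["negative"] = asdict(neg)
    summary["authentication"] = rules

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
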