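"""File formats: FASTA, GFF3, BED, TSV tables.

Internal coordinates are 0-based half-open; GFF3 is written 1-based
inclusive and BED 0-based half-open, with the conversions centralized in
:func:`to_gff3_coords` / :func:`from_gff3_coords` so no other module does
its own arithmetic.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, Feature

__all__ = [
    "read_fasta", "write_fasta", "read_gff3", "write_gff3",
    "read_bed", "write_bed", "read_tsv", "write_tsv",
    "read_genotype_tsv", "write_genotype_tsv",
    "to_gff3_coords", "from_gff3_coords",
]


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def from_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences by record id; soft-masked/lower-case input is upper-cased
    with a warning."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{rec.id}: lower-case bases upper-cased", stacklevel=2)
            seq = seq.upper()
        out[rec.id] = seq
    return out


def write_fasta(path, sequences: dict[str, str] | list[AnnotatedGenome]) -> None:
    if isinstance(sequences, dict):
        records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    else:
        records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in sequences]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(path, genome: AnnotatedGenome) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for f in genome.features:
            g_start, g_end = to_gff3_coords(f.start, f.end)
            fh.write("\t".join([
                genome.id, "plastoflux", f.type, str(g_start), str(g_end),
                ".", f.strand, ".", f"ID={f.name};Name={f.name}",
            ]) + "\n")


def read_gff3(path, sequences: dict[str, str]) -> dict[str, AnnotatedGenome]:
    """Parse GFF3 features onto the given sequences (keyed by seqid)."""
    feats: dict[str, list[Feature]] = {k: [] for k in sequences}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
        if seqid not in feats:
            raise ValueError(f"{path}:{lineno}: unknown sequence id {seqid!r}")
        try:
            i_start, i_end = from_gff3_coords(int(start), int(end))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
        name = seqid
        for kv in attrs.split(";"):
            if kv.startswith("ID="):
                name = kv[3:]
        feats[seqid].append(Feature(ftype, i_start, i_end, strand, name))
    return {k: AnnotatedGenome(k, sequences[k], v) for k, v in feats.items()}


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_bed(path, intervals: list[tuple[str, int, int, str]]) -> None:
    """(chrom, start, end, name) rows, 0-based half-open per the standard."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        name = parts[3] if len(parts) > 3 else "."
        out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotype_tsv(path, table) -> None:
    """Header ``collection<TAB>label<TAB>marker1...``; one row per collection."""
    with open(path, "w") as fh:
        fh.write("collection\tlabel\t" + "\t".join(table.markers) + "\n")
        for cid, label in table.collections:
            fh.write(cid + "\t" + label + "\t"
                     + "\t".join(table.calls.loc[cid]) + "\n")


def read_genotype_tsv(path):
    from .authenticate import GenotypeTable

    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["collection", "label"]:
        raise ValueError(f"{path}: expected header collection<TAB>label<TAB>markers...")
    markers = list(frame.columns[2:])
    collections = list(zip(frame["collection"], frame["label"]))
    calls = frame.set_index("collection")[markers]
    return GenotypeTable(collections=collections, markers=markers, calls=calls)
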