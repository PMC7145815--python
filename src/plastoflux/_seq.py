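"""Low-level DNA utilities shared across modules.

All sequences are plain upper-case ``str`` over A/C/G/T internally; IUPAC
ambiguity codes are tolerated only where an operation explicitly says so.
Coordinates are 0-based half-open everywhere inside the package.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn", "TGCAYRMKVHDBNtgcayrmkvhdbn")

IUPAC = set("ACGTRYSWKMBDHVN")

# standard genetic code (NCBI table 1)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) to amino acids, stops as '*'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3))


def internal_stop_index(cds: str) -> int | None:
    """Index (codon units) of the first internal stop codon, or None."""
    n = len(cds) // 3
    for i in range(n - 1):
        if cds[3 * i : 3 * i + 3] in STOP_CODONS:
            return i
    return None


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else -> 4 (never matches in comparisons)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def check_alphabet(seq: str, name: str = "sequence") -> None:
    """Reject characters outside the IUPAC nucleotide set, reporting position."""
    for i, c in enumerate(seq):
        if c not in IUPAC:
            raise ValueError(f"{name}: non-IUPAC character {c!r} at position {i}")
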