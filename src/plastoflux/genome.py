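"""Annotated genome container used across the pipeline.

Coordinates are 0-based half-open; strand is '+' or '-'.  Feature types in
use are CDS, gene, tRNA and rRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp, internal_stop_index

FEATURE_TYPES = ("CDS", "gene", "tRNA", "rRNA")


@dataclass
class Feature:
    type: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"feature {self.name}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feat: Feature) -> str:
        """Spliced-out feature sequence, reverse-complemented on '-'."""
        s = self.sequence[feat.start : feat.end]
        return revcomp(s) if feat.strand == "-" else s

    def features_of_type(self, *types: str) -> list[Feature]:
        return [f for f in self.features if f.type in types]

    def validate(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(f"feature {f.name} extends past genome end ({f.end} > {n})")
            if f.type == "CDS":
                if f.length % 3:
                    raise ValueError(f"CDS {f.name}: length {f.length} not divisible by 3")
                idx = internal_stop_index(self.feature_seq(f))
                if idx is not None:
                    raise ValueError(f"CDS {f.name}: internal stop at codon {idx}")
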