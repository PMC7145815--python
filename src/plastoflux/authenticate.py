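"""Multi-marker authentication decision rules and their error tradeoff.

Two decision rules over a collections × markers genotype table:

* positive rule — a collection is *genuine* iff at least one marker shows
  the target-species allele;
* negative rule — a collection is *counterfeit* iff at least one marker
  shows an off-type allele.

For heterogeneous genotypes (e.g. A1 B1 C2) the rules disagree: the
positive rule accepts, the negative rule rejects.  Because "no target
allele anywhere" implies "some off allele somewhere" (missing calls
aside), the positive rule's counterfeit set is always a subset of the
negative rule's — the negative rule buys detection power at the price of
false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GenotypeTable", "RuleMetrics", "classify", "evaluate_rules",
           "CALL_VALUES"]

#: allowed per-locus calls; "both" records a locus showing both alleles
#: (mixed bands / heteroplasmy) and counts as target-present AND off-present
CALL_VALUES = ("target", "off", "both", "missing")


@dataclass
class GenotypeTable:
    """Rectangular allele-call table with truth labels per collection."""

    collections: list[tuple[str, str]]  # (id, truth label in {target, other})
    markers: list[str]
    calls: pd.DataFrame  # index: collection ids; columns: marker ids

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("need at least one marker")
        if list(self.calls.columns) != list(self.markers):
            raise ValueError("calls columns must match markers")
        ids = [c for c, _ in self.collections]
        if list(self.calls.index) != ids:
            raise ValueError("calls index must match collection ids")
        bad = set(self.calls.values.ravel()) - set(CALL_VALUES)
        if bad:
            raise ValueError(f"unknown call values: {sorted(bad)}")

    def truth(self, cid: str) -> str:
        return dict(self.collections)[cid]


@dataclass
class RuleMetrics:
    rule: str  # "positive" or "negative"
    n_flagged_counterfeit: int
    power: float | None  # flagged among true "other" / total "other"
    fpr: float | None    # flagged among true "target" / total "target"


def classify(table: GenotypeTable, rule: str,
             strict_missing: bool = False) -> dict[str, str]:
    """Label every collection genuine/counterfeit under one rule.

    Missing calls are ignored by default (strict_missing treats them as
    off-type).  A collection whose calls are all missing is labeled
    ``"unclassifiable"``.
    """
    if rule not in ("positive", "negative"):
        raise ValueError("rule must be 'positive' or 'negative'")
    out = {}
    for cid, _ in table.collections:
        row = table.calls.loc[cid]
        has_target = ((row == "target") | (row == "both")).any()
        has_off = ((row == "off") | (row == "both")).any()
        if strict_missing:
            has_off = has_off or (row == "missing").any()
        if (row == "missing").all():
            out[cid] = "unclassifiable"
        elif rule == "positive":
            out[cid] = "genuine" if has_target else "counterfeit"
        else:
            out[cid] = "counterfeit" if has_off else "genuine"
    return out


def evaluate_rules(table: GenotypeTable,
                   strict_missing: bool = False) -> tuple[RuleMetrics, RuleMetrics]:
    """Detection power and false-positive rate of both rules on one table.

    power = flagged counterfeits among true "other" collections / total
    "other"; fpr = flagged among true "target" / total "target".  A metric
    whose truth class is absent is reported as None.
    """
    metrics = []
    for rule in ("positive", "negative"):
        labels = classify(table, rule, strict_missing)
        flagged = {cid for cid, lab in labels.items() if lab == "counterfeit"}
        others = [cid for cid, t in table.collections if t == "other"]
        targets = [cid for cid, t in table.collections if t == "target"]
        power = len(flagged & set(others)) / len(others) if others else None
        fpr = len(flagged & set(targets)) / len(targets) if targets else None
        metrics.append(RuleMetrics(rule, len(flagged), power, fpr))
    return metrics[0], metrics[1]
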