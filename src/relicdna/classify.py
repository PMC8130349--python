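"""Paleoecological calls: living vs. fossil, per metagenomic bin.

Integrates the per-fraction evidence (presence, terminal C->T damage score
with and without repair, repair gain in completeness) into one of four
labels.  The decision table, evaluated in order:

1. present only in the eDNA fraction            -> fossil_extracellular
2. present in iDNA (with or without eDNA), every present fraction shows
   damage < damage_max AND |delta completeness| < delta_max  -> living
3. present in iDNA, some present fraction shows damage >= damage_max or a
   repair gain >= delta_max                      -> fossil_intracellular
4. anything else (conflicts, undefined scores)   -> ambiguous; expressed
   protein may upgrade to living when the damage clause of rule 2 holds.

Protein evidence is advisory (upgrade-only): metaproteomes corroborate but
never veto a DNA-based call.  Also provides the balanced-spectral-count
aggregator: unique spectra count 1, a spectrum matching n proteins counts
1/n to each, so totals are conserved.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LABELS",
    "Thresholds",
    "FractionEvidence",
    "BinEvidence",
    "PaleoecologicalCall",
    "ProteinEvidence",
    "balanced_spectral_counts",
    "classify_population",
    "summarize_assemblage",
    "EXPECTED_LABEL",
]

LABELS = ("living", "fossil_intracellular", "fossil_extracellular",
          "ambiguous")

#: ground-truth vitality -> the label a perfect classifier assigns
EXPECTED_LABEL = {"living": "living", "dead_intact": "fossil_intracellular",
                  "lysed": "fossil_extracellular"}


@dataclass(frozen=True)
class Thresholds:
    damage_max: float = 0.1  # descriptive bound: "low" deamination is < 0.1
    delta_max: float = 0.05  # |repair gain| below this is "negligible"

    def __post_init__(self) -> None:
        for v in (self.damage_max, self.delta_max):
            if not (0.0 < v < 1.0):
                raise ValueError("thresholds must be in (0, 1)")


@dataclass(frozen=True)
class FractionEvidence:
    """Evidence from one extraction fraction (iDNA or eDNA)."""

    present: bool = False
    damage_unrepaired: float | None = None  # None = undefined (no C seen)
    damage_repaired: float | None = None
    delta_completeness: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.damage_unrepaired, self.damage_repaired):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("damage scores must be in [0, 1]")
        if not (-1.0 <= self.delta_completeness <= 1.0):
            raise ValueError("delta_completeness must be in [-1, 1]")


@dataclass(frozen=True)
class BinEvidence:
    bin_id: str
    idna: FractionEvidence = field(default_factory=FractionEvidence)
    edna: FractionEvidence = field(default_factory=FractionEvidence)
    protein_expressed: bool | None = None
    growth_valid: bool | None = None

    def __post_init__(self) -> None:
        if not (self.idna.present or self.edna.present):
            raise ValueError("bin must be present in at least one fraction")

    def present_fractions(self) -> list[tuple[str, FractionEvidence]]:
        out = []
        if self.idna.present:
            out.append(("iDNA", self.idna))
        if self.edna.present:
            out.append(("eDNA", self.edna))
        return out


@dataclass(frozen=True)
class PaleoecologicalCall:
    bin_id: str
    label: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")


@dataclass(frozen=True)
class ProteinEvidence:
    protein_id: str
    unique_count: int
    shared: tuple[tuple[int, int], ...] = ()  # (spectrum_count, n_matching)

    @property
    def balanced_count(self) -> float:
        return self.unique_count + sum(c / n for c, n in self.shared)


def balanced_spectral_counts(peptide_map: Mapping[str, Iterable[str]]
                             ) -> dict[str, float]:
    """Apportion spectra to proteins: 1/n to each of its n matches.

    ``peptide_map``: spectrum id -> set of matching protein ids.  The sum of
    balanced counts equals the number of spectra (conservation).
    """
    out: dict[str, float] = {}
    for spectrum, proteins in peptide_map.items():
        prots = list(proteins)
        if not prots:
            raise ValueError(f"spectrum {spectrum!r} matches no protein")
        share = 1.0 / len(prots)
        for p in prots:
            out[p] = out.get(p, 0.0) + share
    return out


def _damage_clause(fracs: Sequence[tuple[str, FractionEvidence]],
                   th: Thresholds) -> tuple[bool, list[str]]:
    """True iff every present fraction has a defined damage score < damage_max."""
    notes = []
    ok = True
    for name, ev in fracs:
        if ev.damage_unrepaired is None:
            notes.append(f"{name}: damage undefined")
            ok = False
        elif ev.damage_unrepaired < th.damage_max:
            notes.append(f"{name}: damage {ev.damage_unrepaired:.3g} < "
                         f"{th.damage_max:g}")
        else:
            notes.append(f"{name}: damage {ev.damage_unrepaired:.3g} >= "
                         f"{th.damage_max:g}")
            ok = False
    return ok, notes


def classify_population(e: BinEvidence,
                        thresholds: Thresholds = Thresholds()
                        ) -> PaleoecologicalCall:
    """Apply the decision table; total and deterministic over evidence."""
    th = thresholds
    rationale: list[str] = []
    fracs = e.present_fractions()

    # rule 1: relic DNA only in the extracellular pool
    if e.edna.present and not e.idna.present:
        rationale.append("rule1: presence in eDNA only")
        return PaleoecologicalCall(e.bin_id, "fossil_extracellular",
                                   tuple(rationale))
    rationale.append("rule1: not eDNA-only")

    damage_ok, damage_notes = _damage_clause(fracs, th)
    delta_ok = all(abs(ev.delta_completeness) < th.delta_max
                   for _, ev in fracs)
    rationale.extend("rule2: " + n for n in damage_notes)
    rationale.append(
        "rule2: |delta completeness| "
        + ("< " if delta_ok else ">= ") + f"{th.delta_max:g} in "
        + ("every" if delta_ok else "some") + " present fraction")

    # rule 2: intact, low-damage, repair-insensitive -> living
    if e.idna.present and damage_ok and delta_ok:
        return PaleoecologicalCall(e.bin_id, "living", tuple(rationale))

    # rule 3: in iDNA with a clear damage or repair-gain signal -> fossil
    fossil_signal = any(
        (ev.damage_unrepaired is not None
         and ev.damage_unrepaired >= th.damage_max)
        or ev.delta_completeness >= th.delta_max
        for _, ev in fracs)
    if e.idna.present and fossil_signal:
        rationale.append("rule3: damage or repair gain above threshold")
        return PaleoecologicalCall(e.bin_id, "fossil_intracellular",
                                   tuple(rationale))
    rationale.append("rule3: no clear fossil signal")

    # rule 4: conflicting or undefined evidence
    if e.protein_expressed and damage_ok:
        rationale.append("rule4: protein expressed with low damage -> "
                         "upgraded to living")
        return PaleoecologicalCall(e.bin_id, "living", tuple(rationale))
    rationale.append("rule4: ambiguous evidence")
    return PaleoecologicalCall(e.bin_id, "ambiguous", tuple(rationale))


def summarize_assemblage(calls: Sequence[PaleoecologicalCall],
                         ground_truth: Mapping[str, str] | None = None
                         ) -> dict:
    """Label tallies, plus a vitality x label confusion matrix when truth
    (bin_id -> vitality) is provided."""
    if not calls:
        raise ValueError("no calls to summarize")
    counts = dict(Counter(c.label for c in calls))
    out: dict = {"n_bins": len(calls), "label_counts": counts}
    if ground_truth is not None:
        rows = []
        correct = 0
        for c in calls:
            vit = ground_truth.get(c.bin_id)
            if vit is None:
                continue
            rows.append({"vitality": vit, "label": c.label})
            if EXPECTED_LABEL.get(vit) == c.label:
                correct += 1
        conf = (pd.DataFrame(rows).groupby(["vitality", "label"])
                .size().unstack(fill_value=0)) if rows else pd.DataFrame()
        out["confusion"] = conf
        out["accuracy"] = correct / len(rows) if rows else math.nan
    return out
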