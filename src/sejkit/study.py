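"""Domain types for quantile-based expert elicitation studies.

An elicitation study consists of panels of experts who each state three
marker quantiles (5%, 50%, 95%) for every item their panel assesses.
Calibration items have known realizations and are used to score experts;
target items are the quantities of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

#: Cumulative probabilities of the three elicited marker quantiles.
QUANTILE_PROBS = (0.05, 0.50, 0.95)

#: Theoretical inter-quantile bin probabilities implied by the marker quantiles:
#: below q05, [q05, q50), [q50, q95), and at-or-above q95.
BIN_PROBS = (0.05, 0.45, 0.45, 0.05)

ITEM_KINDS = ("calibration", "target")
ITEM_SCALES = ("uniform", "log")
WEIGHT_SCHEMES = ("equal", "global", "item")
ITEM_SETS = ("all_items", "calibration_only")


@dataclass(frozen=True)
class QuantileTriple:
    """An expert's 5/50/95% quantiles for one item, in the item's units."""

    q05: float
    q50: float
    q95: float

    def is_strictly_increasing(self) -> bool:
        return self.q05 < self.q50 < self.q95

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q05, self.q50, self.q95)


@dataclass
class Item:
    """A single elicited quantity.

    Calibration items carry a ``realization`` (the value that became known
    post hoc); target items normally do not.  ``bounds`` is the natural
    domain of the quantity, e.g. ``(0, 100)`` for a percentage.
    """

    id: str
    kind: str = "calibration"
    scale: str = "uniform"
    units: str = ""
    realization: Optional[float] = None
    bounds: Optional[tuple[float, float]] = None


@dataclass
class Panel:
    """A group of experts who assessed a common set of items.

    ``assessments`` maps ``(expert_id, item_id)`` to the expert's triple and
    must be complete: every expert has a triple for every item.
    """

    id: str
    hazard: str
    region: str
    experts: list[str]
    items: list[Item]
    assessments: dict[tuple[str, str], QuantileTriple]

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(f"panel {self.id!r}: no item {item_id!r}")

    @property
    def calibration_items(self) -> list[Item]:
        return [it for it in self.items if it.kind == "calibration"]

    @property
    def target_items(self) -> list[Item]:
        return [it for it in self.items if it.kind == "target"]

    def triples_for_item(self, item_id: str) -> list[QuantileTriple]:
        return [self.assessments[(e, item_id)] for e in self.experts]

    def triple(self, expert_id: str, item_id: str) -> QuantileTriple:
        return self.assessments[(expert_id, item_id)]


@dataclass
class Study:
    """A collection of panels plus an id -> display-label registry.

    Experts may sit on many panels; ids are unique study-wide and the label
    map supports anonymized export.
    """

    panels: list[Panel]
    expert_labels: dict[str, str] = field(default_factory=dict)

    @property
    def expert_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.panels:
            for e in p.experts:
                seen.setdefault(e)
        return list(seen)

    def panels_of_expert(self, expert_id: str) -> Iterator[Panel]:
        for p in self.panels:
            if expert_id in p.experts:
                yield p


@dataclass(frozen=True)
class ScoreRecord:
    """Performance scores of one assessor (an expert or a pooled DM)."""

    assessor: str
    statistical_accuracy: float
    informativeness: float
    combined: float

    @classmethod
    def from_scores(
        cls, assessor: str, statistical_accuracy: float, informativeness: float
    ) -> "ScoreRecord":
        return cls(
            assessor=assessor,
            statistical_accuracy=statistical_accuracy,
            informativeness=informativeness,
            combined=statistical_accuracy * informativeness,
        )


@dataclass(frozen=True)
class CalibrationCounts:
    """Realization counts per inter-quantile bin over N calibration items."""

    counts: tuple[int, int, int, int]

    @property
    def N(self) -> int:
        return sum(self.counts)

    @property
    def p(self) -> tuple[float, ...]:
        return BIN_PROBS

    @property
    def s(self) -> tuple[float, ...]:
        n = self.N
        return tuple(c / n for c in self.counts)


@dataclass
class WeightingConfig:
    """How a pooled decision maker weights its experts.

    ``alpha`` is the statistical-accuracy cut-off: experts scoring below it
    receive zero weight.  ``informativeness_item_set`` selects whether global
    informativeness averages over all items or calibration items only.
    """

    scheme: str = "global"
    alpha: float = 0.0
    optimize: bool = True
    informativeness_item_set: str = "all_items"

    def __post_init__(self) -> None:
        if self.scheme not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        if self.informativeness_item_set not in ITEM_SETS:
            raise ValueError(f"unknown item set {self.informativeness_item_set!r}")
        if self.scheme == "equal" and self.alpha != 0.0:
            raise ValueError("equal weighting requires alpha = 0")


@dataclass
class RangeConfig:
    """Intrinsic-range construction: overshoot fraction and bound clipping."""

    overshoot_k: float = 0.10
    clip_to_bounds: bool = True

    def __post_init__(self) -> None:
        if self.overshoot_k < 0:
            raise ValueError("overshoot_k must be >= 0")


def _check_triple(
    violations: list[str], panel_id: str, expert: str, item: str, t: QuantileTriple
) -> None:
    vals = t.as_tuple()
    if any(not math.isfinite(v) for v in vals):
        violations.append(
            f"panel {panel_id!r}, expert {expert!r}, item {item!r}: "
            f"non-finite quantile in {vals}"
        )
    elif not t.is_strictly_increasing():
        violations.append(
            f"panel {panel_id!r}, expert {expert!r}, item {item!r}: "
            f"quantiles not strictly increasing: {vals}"
        )


def validate_study(study: Study) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Total on syntactically valid input: reports problems, never raises.
    An empty return value means the study is valid.
    """
    violations: list[str] = []
    for panel in study.panels:
        pid = panel.id
        if not panel.experts:
            violations.append(f"panel {pid!r}: no experts")
        if not panel.calibration_items:
            violations.append(f"panel {pid!r}: no calibration items")
        if len(set(panel.experts)) != len(panel.experts):
            violations.append(f"panel {pid!r}: duplicate expert ids")
        item_ids = [it.id for it in panel.items]
        if len(set(item_ids)) != len(item_ids):
            violations.append(f"panel {pid!r}: duplicate item ids")
        for it in panel.items:
            if it.kind not in ITEM_KINDS:
                violations.append(f"panel {pid!r}, item {it.id!r}: bad kind {it.kind!r}")
            if it.scale not in ITEM_SCALES:
                violations.append(f"panel {pid!r}, item {it.id!r}: bad scale {it.scale!r}")
            if it.kind == "calibration" and it.realization is None:
                violations.append(
                    f"panel {pid!r}, item {it.id!r}: calibration item without realization"
                )
            if it.bounds is not None:
                lo, hi = it.bounds
                if not lo < hi:
                    violations.append(
                        f"panel {pid!r}, item {it.id!r}: bounds {it.bounds} not increasing"
                    )
                elif it.realization is not None and not (lo <= it.realization <= hi):
                    violations.append(
                        f"panel {pid!r}, item {it.id!r}: realization "
                        f"{it.realization} outside bounds {it.bounds}"
                    )
        for expert in panel.experts:
            for it in panel.items:
                key = (expert, it.id)
                if key not in panel.assessments:
                    violations.append(
                        f"panel {pid!r}: missing assessment for expert "
                        f"{expert!r} on item {it.id!r}"
                    )
                else:
                    _check_triple(violations, pid, expert, it.id, panel.assessments[key])
        for (expert, item_id) in panel.assessments:
            if expert not in panel.experts:
                violations.append(
                    f"panel {pid!r}: assessment by unknown expert {expert!r}"
                )
            if item_id not in item_ids:
                violations.append(
                    f"panel {pid!r}: assessment for unknown item {item_id!r}"
                )
    return violations
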