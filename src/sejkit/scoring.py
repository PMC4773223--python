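"""Classical-Model performance scores for a single assessor.

Statistical accuracy is the p-value of a likelihood-ratio (G) test that the
assessor's realizations fall in the four inter-quantile bins with the
theoretical probabilities (0.05, 0.45, 0.45, 0.05).  Informativeness is the
Shannon relative information of the assessor's minimally-informative
reconstructed density with respect to a uniform background measure on an
item's intrinsic range.  The combined score is their product and is
proportional to the assessor's performance-based weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .study import (
    BIN_PROBS,
    CalibrationCounts,
    Item,
    Panel,
    QuantileTriple,
    RangeConfig,
    ScoreRecord,
)

__all__ = [
    "IntrinsicRange",
    "assign_bin",
    "intrinsic_range",
    "panel_ranges",
    "bin_counts",
    "relative_information_discrete",
    "statistical_accuracy",
    "information_per_item",
    "informativeness",
    "combined_score",
    "score_expert",
    "score_panel_experts",
]


@dataclass(frozen=True)
class IntrinsicRange:
    """Support [L, U] used for density reconstruction on one item."""

    item_id: str
    L: float
    U: float

    def __post_init__(self) -> None:
        if not self.L < self.U:
            raise ValueError(f"item {self.item_id!r}: degenerate range [{self.L}, {self.U}]")


def assign_bin(realization: float, triple: QuantileTriple) -> int:
    """Index (0..3) of the inter-quantile bin containing the realization.

    Ties at a quantile go to the upper bin: r == q50 counts in [q50, q95).
    """
    if realization < triple.q05:
        return 0
    if realization < triple.q50:
        return 1
    if realization < triple.q95:
        return 2
    return 3


def intrinsic_range(
    item: Item,
    triples: Sequence[QuantileTriple],
    cfg: RangeConfig | None = None,
) -> IntrinsicRange:
    """Envelope of all assessors' outer quantiles (and the realization),
    extended by the overshoot fraction and clipped to the item's bounds.
    """
    cfg = cfg or RangeConfig()
    if item.scale != "uniform":
        raise ValueError(
            f"item {item.id!r}: only the uniform background measure is supported "
            f"(got scale={item.scale!r})"
        )
    if not triples:
        raise ValueError(f"item {item.id!r}: no assessments")
    lo = min(t.q05 for t in triples)
    hi = max(t.q95 for t in triples)
    if item.realization is not None:
        lo = min(lo, item.realization)
        hi = max(hi, item.realization)
    span = hi - lo
    if span <= 0:
        raise ValueError(f"item {item.id!r}: degenerate range (zero raw span)")
    L = lo - cfg.overshoot_k * span
    U = hi + cfg.overshoot_k * span
    if cfg.clip_to_bounds and item.bounds is not None:
        L = max(L, item.bounds[0])
        U = min(U, item.bounds[1])
    return IntrinsicRange(item_id=item.id, L=L, U=U)


def panel_ranges(
    panel: Panel, cfg: RangeConfig | None = None
) -> dict[str, IntrinsicRange]:
    """Intrinsic range per item, from all the panel's experts jointly.

    Ranges are fixed once from the experts plus the realization and shared
    by every assessor, pooled DMs included, so informativeness scores are
    comparable across assessors.
    """
    return {
        it.id: intrinsic_range(it, panel.triples_for_item(it.id), cfg)
        for it in panel.items
    }


def bin_counts(
    panel: Panel, assessments: Mapping[str, QuantileTriple]
) -> CalibrationCounts:
    """Count realizations of the panel's calibration items per bin.

    ``assessments`` maps item id -> the assessor's triple (an expert's stated
    triples or a DM's derived ones).
    """
    cal = panel.calibration_items
    if not cal:
        raise ValueError(f"panel {panel.id!r}: no calibration items")
    counts = [0, 0, 0, 0]
    for it in cal:
        if it.realization is None:
            raise ValueError(f"panel {panel.id!r}, item {it.id!r}: no realization")
        counts[assign_bin(it.realization, assessments[it.id])] += 1
    return CalibrationCounts(counts=tuple(counts))


def relative_information_discrete(
    s: Sequence[float], p: Sequence[float]
) -> float:
    """Kullback–Leibler divergence I(s; p) = sum s_i ln(s_i / p_i).

    Zero terms follow 0·ln 0 = 0.  Nonnegative; zero iff s == p.
    """
    s_arr = np.asarray(s, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if s_arr.shape != p_arr.shape:
        raise ValueError("s and p must have the same length")
    if np.any(s_arr < 0):
        raise ValueError("s must be non-negative")
    if np.any((p_arr <= 0) & (s_arr > 0)):
        raise ValueError("p has zero mass where s is positive")
    if abs(s_arr.sum() - 1.0) > 1e-9 or abs(p_arr.sum() - 1.0) > 1e-9:
        raise ValueError("s and p must each sum to 1")
    mask = s_arr > 0
    return float(np.sum(s_arr[mask] * np.log(s_arr[mask] / p_arr[mask])))


def statistical_accuracy(c: CalibrationCounts) -> float:
    """Calibration p-value: P(chi2_3 >= 2·N·I(s; p)).

    The p-value at which the hypothesis that the assessor's probability
    statements are statistically accurate would be falsely rejected.  Equals
    1 when the empirical bin distribution matches (0.05, 0.45, 0.45, 0.05)
    and decreases strictly in the G statistic.
    """
    if c.N < 1:
        raise ValueError("need at least one calibration item")
    statistic = 2.0 * c.N * relative_information_discrete(c.s, c.p)
    return float(stats.chi2.sf(statistic, df=3))


def information_per_item(triple: QuantileTriple, rng: IntrinsicRange) -> float:
    """Shannon relative information of one assessment w.r.t. the uniform
    background on the intrinsic range.

    Evaluates sum p_i ln(p_i / r_i) over the four intervals cut by the
    triple, where r_i is the interval's share of the range width.  Zero iff
    the interval widths are proportional to (0.05, 0.45, 0.45, 0.05);
    invariant under joint affine rescaling of triple and range.
    """
    if not (rng.L <= triple.q05 and triple.q95 <= rng.U):
        raise ValueError(
            f"item {rng.item_id!r}: triple {triple.as_tuple()} outside range "
            f"[{rng.L}, {rng.U}]"
        )
    edges = np.array([rng.L, triple.q05, triple.q50, triple.q95, rng.U])
    widths = np.diff(edges)
    if np.any(widths <= 0):
        raise ValueError(f"item {rng.item_id!r}: zero-width interval with positive mass")
    r = widths / (rng.U - rng.L)
    p = np.asarray(BIN_PROBS)
    return float(np.sum(p * np.log(p / r)))


def informativeness(
    triples: Mapping[str, QuantileTriple],
    ranges: Mapping[str, IntrinsicRange],
    item_ids: Iterable[str],
) -> float:
    """Arithmetic mean of per-item information over the selected items."""
    ids = list(item_ids)
    if not ids:
        raise ValueError("empty item selection")
    return float(
        np.mean([information_per_item(triples[i], ranges[i]) for i in ids])
    )


def combined_score(accuracy: float, informativeness: float) -> float:
    """Product of statistical accuracy and informativeness."""
    return accuracy * informativeness


def _select_item_ids(panel: Panel, item_set: str) -> list[str]:
    if item_set == "calibration_only":
        return [it.id for it in panel.calibration_items]
    if item_set == "all_items":
        return [it.id for it in panel.items]
    raise ValueError(f"unknown item set {item_set!r}")


def score_expert(
    panel: Panel,
    expert_id: str,
    ranges: Mapping[str, IntrinsicRange],
    item_set: str = "all_items",
) -> ScoreRecord:
    """Statistical accuracy, informativeness and combined score of one expert
    on one panel (accuracy from calibration items; informativeness averaged
    over ``item_set``)."""
    triples = {it.id: panel.triple(expert_id, it.id) for it in panel.items}
    acc = statistical_accuracy(bin_counts(panel, triples))
    inf = informativeness(triples, ranges, _select_item_ids(panel, item_set))
    return ScoreRecord.from_scores(expert_id, acc, inf)


def score_panel_experts(
    panel: Panel,
    ranges: Mapping[str, IntrinsicRange],
    item_set: str = "all_items",
) -> dict[str, ScoreRecord]:
    """Score every expert of a panel; returns expert id -> ScoreRecord."""
    return {e: score_expert(panel, e, ranges, item_set) for e in panel.experts}
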