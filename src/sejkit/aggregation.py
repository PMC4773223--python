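"""Pooled decision makers (DMs) as weighted mixtures of expert densities.

Each expert's three stated quantiles, together with the item's intrinsic
range, determine the minimally-informative density consistent with them: a
piecewise-uniform density putting masses (0.05, 0.45, 0.45, 0.05) on the
four intervals.  A DM is a weighted mixture of these densities; its own
marker quantiles are read off the mixture CDF exactly (piecewise-linear
inversion, never Monte Carlo), and the DM is then scored on the panel's
calibration items exactly like an expert, on the same intrinsic ranges.

Three weighting schemes are provided: equal weights (``ew``), global
performance weights (``pwg``, one weight per expert proportional to
statistical accuracy x informativeness), and item weights (``pwi``, the
accuracy factor modulated per item by item-specific informativeness).
Performance schemes zero-weight experts whose statistical accuracy falls
below a threshold alpha; ``optimize_threshold`` picks alpha maximizing the
DM's in-sample combined score over the exhaustive candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .scoring import (
    IntrinsicRange,
    bin_counts,
    information_per_item,
    informativeness,
    score_panel_experts,
    statistical_accuracy,
    _select_item_ids,
)
from .study import Panel, QuantileTriple, ScoreRecord

__all__ = [
    "PiecewiseUniformDensity",
    "DMResult",
    "expert_density",
    "mixture_density",
    "dm_quantiles",
    "performance_weights",
    "build_dm",
    "equal_weight_dm",
    "performance_weight_dm",
    "optimize_threshold",
    "score_dm_triples",
]

_EXPERT_MASSES = np.array([0.05, 0.45, 0.45, 0.05])


@dataclass(frozen=True)
class PiecewiseUniformDensity:
    """A density that is constant between consecutive breakpoints.

    ``masses[i]`` is the probability of the interval
    (breakpoints[i], breakpoints[i+1]); masses sum to 1.
    """

    breakpoints: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "masses", m)
        if bp.ndim != 1 or m.ndim != 1 or len(bp) != len(m) + 1:
            raise ValueError("need n+1 breakpoints for n interval masses")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("masses must be non-negative")
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError(f"masses sum to {m.sum()!r}, not 1")

    @property
    def _cum(self) -> np.ndarray:
        cum = np.concatenate(([0.0], np.cumsum(self.masses)))
        cum[-1] = 1.0  # absorb cumulative rounding
        return cum

    def cdf(self, x):
        """Piecewise-linear CDF, evaluated vectorized; 0 left of support, 1 right."""
        return np.interp(x, self.breakpoints, self._cum)

    def ppf(self, q):
        """Exact inverse CDF (piecewise-linear interpolation)."""
        return np.interp(q, self._cum, self.breakpoints)


@dataclass
class DMResult:
    """A pooled decision maker: weights used, per-item quantiles/densities,
    and its in-sample ScoreRecord on the panel's calibration items."""

    label: str
    weights: Mapping[str, float] | Mapping[tuple[str, str], float]
    alpha_used: float
    quantiles: dict[str, QuantileTriple]
    densities: dict[str, PiecewiseUniformDensity]
    score: ScoreRecord


def expert_density(
    triple: QuantileTriple, rng: IntrinsicRange
) -> PiecewiseUniformDensity:
    """Minimally-informative density consistent with the stated quantiles:
    masses (0.05, 0.45, 0.45, 0.05) spread uniformly over the four
    intervals cut by the triple within [L, U]."""
    bp = np.array([rng.L, triple.q05, triple.q50, triple.q95, rng.U])
    if np.any(np.diff(bp) <= 0):
        raise ValueError(
            f"item {rng.item_id!r}: zero-width interval with positive mass"
        )
    return PiecewiseUniformDensity(breakpoints=bp, masses=_EXPERT_MASSES.copy())


def mixture_density(
    components: Sequence[PiecewiseUniformDensity],
    weights: Sequence[float],
) -> PiecewiseUniformDensity:
    """Weighted mixture on the union grid of component breakpoints.

    The mixture CDF equals the weighted average of component CDFs at every
    point.  Components must share the same support endpoints.
    """
    if not components:
        raise ValueError("no components")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(components):
        raise ValueError("weights and components differ in length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()!r}, not 1")
    lo = components[0].breakpoints[0]
    hi = components[0].breakpoints[-1]
    for c in components[1:]:
        if c.breakpoints[0] != lo or c.breakpoints[-1] != hi:
            raise ValueError("components must share the same intrinsic range")
    grid = np.unique(np.concatenate([c.breakpoints for c in components]))
    cdf_at_grid = np.zeros_like(grid)
    for wc, c in zip(w, components):
        if wc > 0:
            cdf_at_grid += wc * c.cdf(grid)
    masses = np.diff(cdf_at_grid)
    masses = np.clip(masses, 0.0, None)
    masses /= masses.sum()
    return PiecewiseUniformDensity(breakpoints=grid, masses=masses)


def dm_quantiles(
    density: PiecewiseUniformDensity,
    probs: Sequence[float] = (0.05, 0.50, 0.95),
) -> QuantileTriple:
    """Marker quantiles of a density by exact CDF inversion."""
    q = density.ppf(np.asarray(probs, dtype=float))
    return QuantileTriple(q05=float(q[0]), q50=float(q[1]), q95=float(q[2]))


def performance_weights(
    scores: Mapping[str, ScoreRecord],
    alpha: float,
    scheme: str = "global",
    per_item_information: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> Mapping[str, float] | Mapping[tuple[str, str], float]:
    """Normalized performance-based weights.

    Global: w_e proportional to 1{acc_e >= alpha} * acc_e * inf_e.  Item:
    w_{e,i} proportional to 1{acc_e >= alpha} * acc_e * inf_{e,i},
    normalized per item (``per_item_information`` maps expert -> item ->
    information).
    """
    experts = list(scores)
    acc = {e: scores[e].statistical_accuracy for e in experts}
    support = [e for e in experts if acc[e] >= alpha]
    if not support:
        raise ValueError(f"empty weight support: no expert with accuracy >= {alpha}")
    if scheme == "global":
        raw = {e: acc[e] * scores[e].informativeness if e in support else 0.0
               for e in experts}
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("empty weight support: all combined scores are zero")
        return {e: raw[e] / total for e in experts}
    if scheme == "item":
        if per_item_information is None:
            raise ValueError("item scheme requires per_item_information")
        item_ids = list(next(iter(per_item_information.values())))
        out: dict[tuple[str, str], float] = {}
        for i in item_ids:
            raw_i = {e: acc[e] * per_item_information[e][i] if e in support else 0.0
                     for e in experts}
            total = sum(raw_i.values())
            if total <= 0:
                raise ValueError(f"empty weight support on item {i!r}")
            for e in experts:
                out[(e, i)] = raw_i[e] / total
        return out
    raise ValueError(f"unknown scheme {scheme!r}")


def score_dm_triples(
    label: str,
    triples: Mapping[str, QuantileTriple],
    panel: Panel,
    ranges: Mapping[str, IntrinsicRange],
    item_set: str = "all_items",
) -> ScoreRecord:
    """Score a DM from its per-item quantile triples through the identical
    path used for experts (bin counts -> accuracy; per-item information ->
    informativeness), on the experts' intrinsic ranges."""
    acc = statistical_accuracy(bin_counts(panel, triples))
    inf = informativeness(triples, ranges, _select_item_ids(panel, item_set))
    return ScoreRecord.from_scores(label, acc, inf)


def build_dm(
    label: str,
    panel: Panel,
    ranges: Mapping[str, IntrinsicRange],
    weights: Mapping[str, float] | Mapping[tuple[str, str], float],
    alpha_used: float = 0.0,
    item_set: str = "all_items",
) -> DMResult:
    """Assemble and score a DM from given (already normalized) weights.

    ``weights`` keyed by expert id applies the same weights on every item;
    keyed by (expert id, item id) applies item-specific weights.
    """
    per_item = any(isinstance(k, tuple) for k in weights)
    densities: dict[str, PiecewiseUniformDensity] = {}
    quantiles: dict[str, QuantileTriple] = {}
    for it in panel.items:
        if per_item:
            w = {e: weights.get((e, it.id), 0.0) for e in panel.experts}
        else:
            w = {e: weights.get(e, 0.0) for e in panel.experts}
        support = [e for e in panel.experts if w[e] > 0]
        comps = [expert_density(panel.triple(e, it.id), ranges[it.id]) for e in support]
        mix = mixture_density(comps, [w[e] for e in support])
        densities[it.id] = mix
        quantiles[it.id] = dm_quantiles(mix)
    score = score_dm_triples(label, quantiles, panel, ranges, item_set)
    return DMResult(
        label=label,
        weights=dict(weights),
        alpha_used=alpha_used,
        quantiles=quantiles,
        densities=densities,
        score=score,
    )


def equal_weight_dm(
    panel: Panel,
    ranges: Mapping[str, IntrinsicRange],
    item_set: str = "all_items",
) -> DMResult:
    """The EW DM: simple average of all experts' distributions on each item."""
    n = len(panel.experts)
    weights = {e: 1.0 / n for e in panel.experts}
    return build_dm("ew", panel, ranges, weights, alpha_used=0.0, item_set=item_set)


def _per_item_information(
    panel: Panel, ranges: Mapping[str, IntrinsicRange]
) -> dict[str, dict[str, float]]:
    return {
        e: {
            it.id: information_per_item(panel.triple(e, it.id), ranges[it.id])
            for it in panel.items
        }
        for e in panel.experts
    }


def performance_weight_dm(
    panel: Panel,
    ranges: Mapping[str, IntrinsicRange],
    alpha: float,
    scheme: str = "global",
    item_set: str = "all_items",
    expert_scores: Optional[Mapping[str, ScoreRecord]] = None,
) -> DMResult:
    """The PW DM at a fixed accuracy threshold alpha (no optimization)."""
    scores = expert_scores or score_panel_experts(panel, ranges, item_set)
    per_item = _per_item_information(panel, ranges) if scheme == "item" else None
    weights = performance_weights(scores, alpha, scheme, per_item)
    label = "pwg" if scheme == "global" else "pwi"
    return build_dm(label, panel, ranges, weights, alpha_used=alpha, item_set=item_set)


def optimize_threshold(
    panel: Panel,
    ranges: Mapping[str, IntrinsicRange],
    scheme: str = "global",
    item_set: str = "all_items",
    expert_scores: Optional[Mapping[str, ScoreRecord]] = None,
    trace: Optional[list] = None,
) -> DMResult:
    """Exhaustive in-sample optimization of the accuracy threshold.

    Candidates are 0 plus every distinct expert accuracy in the panel (a
    finer grid cannot change any DM's support).  Returns the DM with the
    maximal in-sample combined score; ties resolve to the smallest alpha
    (widest support).  ``trace`` receives (alpha, combined) pairs if given.
    """
    scores = expert_scores or score_panel_experts(panel, ranges, item_set)
    per_item = _per_item_information(panel, ranges) if scheme == "item" else None
    label = "pwg" if scheme == "global" else "pwi"
    candidates = sorted({0.0} | {s.statistical_accuracy for s in scores.values()})
    best: Optional[DMResult] = None
    for alpha in candidates:
        weights = performance_weights(scores, alpha, scheme, per_item)
        dm = build_dm(label, panel, ranges, weights, alpha_used=alpha, item_set=item_set)
        if trace is not None:
            trace.append((alpha, dm.score.combined))
        if best is None or dm.score.combined > best.score.combined:
            best = dm
    assert best is not None
    return best
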