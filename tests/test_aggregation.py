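"""Density reconstruction, mixtures, DM quantiles, weights and threshold
optimization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sejkit.aggregation import (
    PiecewiseUniformDensity,
    build_dm,
    dm_quantiles,
    equal_weight_dm,
    expert_density,
    mixture_density,
    optimize_threshold,
    performance_weight_dm,
    performance_weights,
)
from sejkit.scoring import IntrinsicRange, panel_ranges, score_panel_experts
from sejkit.study import QuantileTriple, ScoreRecord

from .conftest import make_panel


def oracle_cdf(density: PiecewiseUniformDensity, x: float) -> float:
    """Independent CDF evaluation: accumulate interval masses with plain
    Python, splitting the straddling interval proportionally."""
    bp = [float(v) for v in density.breakpoints]
    masses = [float(v) for v in density.masses]
    if x <= bp[0]:
        return 0.0
    total = 0.0
    for i, m in enumerate(masses):
        lo, hi = bp[i], bp[i + 1]
        if x >= hi:
            total += m
        else:
            total += m * (x - lo) / (hi - lo)
            break
    return min(total, 1.0)


def _bisect_ppf(cdf, q: float, lo: float, hi: float, tol: float = 1e-13) -> float:
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


triples = st.tuples(
    st.floats(0.01, 0.3), st.floats(0.35, 0.6), st.floats(0.65, 0.99)
).map(lambda t: QuantileTriple(*t))


class TestExpertDensity:
    def test_background_triple_gives_uniform_density(self):
        rng = IntrinsicRange("x", 0.0, 1.0)
        d = expert_density(QuantileTriple(0.05, 0.50, 0.95), rng)
        xs = np.linspace(0, 1, 101)
        assert np.allclose(d.cdf(xs), xs, atol=1e-12)

    @given(triples)
    def test_cdf_hits_quantile_probs(self, t):
        rng = IntrinsicRange("x", 0.0, 1.0)
        d = expert_density(t, rng)
        assert d.cdf(t.q05) == pytest.approx(0.05, abs=1e-12)
        assert d.cdf(t.q50) == pytest.approx(0.50, abs=1e-12)
        assert d.cdf(t.q95) == pytest.approx(0.95, abs=1e-12)

    def test_zero_width_interval_raises(self):
        rng = IntrinsicRange("x", 0.1, 1.0)
        with pytest.raises(ValueError, match="zero-width"):
            expert_density(QuantileTriple(0.1, 0.5, 0.9), rng)


class TestMixture:
    def _components(self):
        rng = IntrinsicRange("x", 0.0, 1.0)
        return [
            expert_density(QuantileTriple(0.1, 0.3, 0.5), rng),
            expert_density(QuantileTriple(0.4, 0.6, 0.9), rng),
        ]

    def test_identical_components_reproduce_component(self):
        rng = IntrinsicRange("x", 0.0, 1.0)
        c = expert_density(QuantileTriple(0.2, 0.4, 0.8), rng)
        mix = mixture_density([c, c], [0.3, 0.7])
        xs = np.linspace(0, 1, 500)
        assert np.allclose(mix.cdf(xs), c.cdf(xs), atol=1e-14)

    def test_degenerate_weight_selects_component(self):
        c1, c2 = self._components()
        mix = mixture_density([c1, c2], [1.0, 0.0])
        xs = np.linspace(0, 1, 500)
        assert np.allclose(mix.cdf(xs), c1.cdf(xs), atol=1e-14)

    def test_cdf_equals_weighted_average_of_component_cdfs(self):
        c1, c2 = self._components()
        mix = mixture_density([c1, c2], [0.5, 0.5])
        for x in np.linspace(-0.1, 1.1, 1000):
            expected = 0.5 * oracle_cdf(c1, x) + 0.5 * oracle_cdf(c2, x)
            assert abs(mix.cdf(x) - expected) < 1e-10

    def test_unnormalized_weights_rejected(self):
        c1, c2 = self._components()
        with pytest.raises(ValueError, match="sum"):
            mixture_density([c1, c2], [0.5, 0.6])

    def test_mismatched_ranges_rejected(self):
        rng1 = IntrinsicRange("x", 0.0, 1.0)
        rng2 = IntrinsicRange("x", 0.0, 2.0)
        c1 = expert_density(QuantileTriple(0.1, 0.3, 0.5), rng1)
        c2 = expert_density(QuantileTriple(0.4, 0.6, 0.9), rng2)
        with pytest.raises(ValueError, match="range"):
            mixture_density([c1, c2], [0.5, 0.5])


class TestDMQuantiles:
    def test_uniform_density_quantiles(self):
        rng = IntrinsicRange("x", 0.0, 1.0)
        d = expert_density(QuantileTriple(0.05, 0.50, 0.95), rng)
        t = dm_quantiles(d)
        assert t.as_tuple() == pytest.approx((0.05, 0.50, 0.95), abs=1e-12)

    @given(triples)
    def test_inverts_expert_density_construction(self, t):
        rng = IntrinsicRange("x", 0.0, 1.0)
        got = dm_quantiles(expert_density(t, rng))
        assert got.as_tuple() == pytest.approx(t.as_tuple(), abs=1e-12)

    @given(triples, triples, st.floats(0.05, 0.95))
    def test_matches_bisection_on_oracle_cdf(self, t1, t2, w):
        rng = IntrinsicRange("x", 0.0, 1.0)
        c1, c2 = expert_density(t1, rng), expert_density(t2, rng)
        mix = mixture_density([c1, c2], [w, 1.0 - w])
        avg = lambda x: w * oracle_cdf(c1, x) + (1.0 - w) * oracle_cdf(c2, x)
        got = dm_quantiles(mix)
        for q, v in zip((0.05, 0.50, 0.95), got.as_tuple()):
            assert abs(v - _bisect_ppf(avg, q, 0.0, 1.0)) < 1e-10


class TestPerformanceWeights:
    def _scores(self):
        return {
            "A": ScoreRecord.from_scores("A", 0.8, 1.0),
            "B": ScoreRecord.from_scores("B", 0.4, 1.0),
            "C": ScoreRecord.from_scores("C", 0.01, 5.0),
        }

    def test_weight_ratio_follows_combined_score(self):
        scores = {
            "A": ScoreRecord.from_scores("A", 0.8, 1.0),
            "B": ScoreRecord.from_scores("B", 0.4, 1.0),
        }
        w = performance_weights(scores, alpha=0.0)
        assert w["A"] / w["B"] == pytest.approx(2.0)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_alpha_above_all_but_one_gives_degenerate_weight(self):
        w = performance_weights(self._scores(), alpha=0.5)
        assert w == {"A": 1.0, "B": 0.0, "C": 0.0}

    def test_alpha_between_accuracies_renormalizes_support(self):
        w = performance_weights(self._scores(), alpha=0.1)
        assert w["C"] == 0.0
        assert w["A"] + w["B"] == pytest.approx(1.0)
        assert w["A"] / w["B"] == pytest.approx(2.0)

    def test_all_below_alpha_is_an_error(self):
        with pytest.raises(ValueError, match="empty weight support"):
            performance_weights(self._scores(), alpha=0.99)


class TestDMs:
    def test_identical_experts_ew_dm_scores_equal_expert(self):
        t = QuantileTriple(1.0, 4.0, 11.0)
        panel = make_panel(
            experts=("A", "B"),
            triples={(e, i): t for e in "AB" for i in ("c0", "c1", "c2", "t0")},
        )
        ranges = panel_ranges(panel)
        expert_scores = score_panel_experts(panel, ranges)
        dm = equal_weight_dm(panel, ranges)
        assert dm.score.statistical_accuracy == pytest.approx(
            expert_scores["A"].statistical_accuracy
        )
        assert dm.score.informativeness == pytest.approx(
            expert_scores["A"].informativeness, rel=1e-9
        )

    def test_degenerate_pw_dm_equals_surviving_expert(self):
        # realizations chosen so the two experts' accuracies differ
        panel = make_panel(realizations=(2.0, 5.0, 11.5))
        ranges = panel_ranges(panel)
        scores = score_panel_experts(panel, ranges)
        best = max(scores, key=lambda e: scores[e].statistical_accuracy)
        alpha = scores[best].statistical_accuracy
        dm = performance_weight_dm(panel, ranges, alpha=alpha)
        for it in panel.items:
            assert dm.quantiles[it.id].as_tuple() == pytest.approx(
                panel.triple(best, it.id).as_tuple(), abs=1e-10
            )
        assert dm.score.statistical_accuracy == pytest.approx(
            scores[best].statistical_accuracy
        )

    def test_mixture_information_convexity_bound(self, mixed_study):
        study, _ = mixed_study
        from sejkit.scoring import information_per_item

        panel = study.panels[0]
        ranges = panel_ranges(panel)
        rng = np.random.default_rng(5)
        for _ in range(5):
            raw = rng.random(len(panel.experts))
            w = raw / raw.sum()
            weights = dict(zip(panel.experts, w))
            dm = build_dm("mix", panel, ranges, weights)
            for it in panel.items:
                bound = sum(
                    weights[e] * information_per_item(panel.triple(e, it.id), ranges[it.id])
                    for e in panel.experts
                )
                assert information_per_item(dm.quantiles[it.id], ranges[it.id]) <= bound + 1e-9


class TestOptimizeThreshold:
    def test_excludes_overconfident_experts(self):
        # one statistically accurate expert whose realizations land in the
        # bins with near-nominal frequencies (1, 4, 4, 1)/10, and three
        # overconfident experts with narrow intervals that always miss
        realizations = tuple(float(v) for v in (2, 5, 9, 3, 7, 4, 6, 8, 2.5, 5.5))
        triples = {}
        for i, r in enumerate(realizations):
            if i == 0:
                good = QuantileTriple(r + 1.0, r + 4.0, r + 8.0)  # bin 1
            elif i <= 4:
                good = QuantileTriple(r - 1.0, r + 1.0, r + 4.0)  # bin 2
            elif i <= 8:
                good = QuantileTriple(r - 4.0, r - 1.0, r + 2.0)  # bin 3
            else:
                good = QuantileTriple(r - 4.5, r - 2.5, r - 0.5)  # bin 4
            triples[("good", f"c{i}")] = good
            for e in ("oc1", "oc2", "oc3"):
                triples[(e, f"c{i}")] = QuantileTriple(r + 1.0, r + 1.1, r + 1.2)
        panel = make_panel(
            experts=("good", "oc1", "oc2", "oc3"),
            realizations=realizations,
            n_target=0,
            triples=triples,
        )
        ranges = panel_ranges(panel)
        dm = optimize_threshold(panel, ranges)
        support = [e for e, w in dm.weights.items() if w > 0]
        assert support == ["good"]
        assert dm.alpha_used > 0

    def test_returns_argmax_over_exhaustive_candidates(self, mixed_study):
        study, _ = mixed_study
        panel = study.panels[1]
        ranges = panel_ranges(panel)
        scores = score_panel_experts(panel, ranges)
        trace: list = []
        dm = optimize_threshold(panel, ranges, trace=trace)
        # the oracle is the exhaustive candidate sweep itself
        candidates = sorted({0.0} | {s.statistical_accuracy for s in scores.values()})
        assert [a for a, _ in trace] == candidates
        by_hand = [
            performance_weight_dm(panel, ranges, alpha=a).score.combined
            for a in candidates
        ]
        assert dm.score.combined == pytest.approx(max(by_hand), rel=1e-12)
        best_alpha = candidates[int(np.argmax(by_hand))]
        assert dm.alpha_used == pytest.approx(best_alpha)

    def test_never_below_all_experts_dm(self, mixed_study):
        study, _ = mixed_study
        for panel in study.panels:
            ranges = panel_ranges(panel)
            dm = optimize_threshold(panel, ranges)
            base = performance_weight_dm(panel, ranges, alpha=0.0)
            assert dm.score.combined >= base.score.combined - 1e-12

    def test_identical_experts_tie_resolves_to_zero_alpha(self):
        t = QuantileTriple(1.0, 4.0, 11.0)
        panel = make_panel(
            experts=("A", "B"),
            triples={(e, i): t for e in "AB" for i in ("c0", "c1", "c2", "t0")},
        )
        ranges = panel_ranges(panel)
        dm = optimize_threshold(panel, ranges)
        assert dm.alpha_used == 0.0

    def test_near_equal_weights_when_experts_equivalent(self):
        # same accuracy and informativeness -> PW weights near-equal, DM ~ EW DM
        t1 = QuantileTriple(1.0, 4.0, 11.0)
        t2 = QuantileTriple(1.2, 4.2, 11.2)
        triples = {}
        for i in ("c0", "c1", "c2", "t0"):
            triples[("A", i)] = t1
            triples[("B", i)] = t2
        panel = make_panel(experts=("A", "B"), triples=triples)
        ranges = panel_ranges(panel)
        scores = score_panel_experts(panel, ranges)
        w = performance_weights(scores, alpha=0.0)
        assert w["A"] == pytest.approx(w["B"], rel=0.15)
        pw = performance_weight_dm(panel, ranges, alpha=0.0)
        ew = equal_weight_dm(panel, ranges)
        for it in panel.items:
            assert pw.quantiles[it.id].as_tuple() == pytest.approx(
                ew.quantiles[it.id].as_tuple(), abs=0.05
            )
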