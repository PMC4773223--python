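# Methods

## Scoring model

Experts state 5/50/95% quantiles per item, so a realization falls below
q05, in [q05, q50), in [q50, q95), or at/above q95 with theoretical
probabilities p = (0.05, 0.45, 0.45, 0.05). Ties at a quantile are assigned
to the upper bin (r = q50 counts in the third bin); any fixed convention
works, this one is chosen for determinism and documented here.

**Statistical accuracy** uses the likelihood-ratio (G) statistic
2·N·I(s; p) with I the Kullback–Leibler divergence of the empirical bin
distribution s from p, referred to a chi-square distribution with 3 degrees
of freedom (four bins, one sum constraint). The asymptotic chi-square
p-value — not an exact multinomial test — is the Classical-Model
convention and keeps scores comparable with legacy implementations; with
the 10–15 calibration variables typical of the panels modelled here the
approximation is adequate, and at N = 100 the p-value distribution of a
perfectly calibrated expert is uniform to within Kolmogorov–Smirnov
distance 0.05 (verified in the test suite). The score is 1 exactly when
s = p and decreases strictly in the statistic.

**Informativeness** is Shannon relative information of the expert's
minimally-informative density (masses p on the four intervals, uniform
within each) with respect to a uniform background on the item's intrinsic
range, i.e. Σ pᵢ ln(pᵢ/rᵢ) with rᵢ the interval's share of the range
width. The intrinsic range is the envelope of all assessors' outer
quantiles and the realization, extended at each end by a fraction
k = 0.10 of the raw span (configurable via `RangeConfig`), then clipped to
the item's natural bounds so that, e.g., percentage items never get
negative support. Per-expert informativeness is the arithmetic mean over
an item set — all items by default (calibration + target), with a
calibration-only option for sensitivity analyses.

Only the uniform background measure is implemented. Items may be declared
`scale="log"` in the data model, but scoring rejects them; the quantities
the package targets are relative frequencies on [0, 100], for which a
log-uniform background is not meaningful. This is a known limitation.

## Decision makers

Each expert's density is reconstructed on the item's intrinsic range;
a DM is a weighted mixture of these, computed exactly on the union grid of
breakpoints (the mixture CDF is the weighted average of component CDFs).
DM marker quantiles come from exact piecewise-linear CDF inversion — never
Monte Carlo — so all DM scores are deterministic. The DM is then scored
through the identical path as an expert (bin counts on the calibration
items; per-item information averaged over the same item set), on the
*experts'* intrinsic ranges: ranges are fixed before DM construction so
expert and DM informativeness share one background and remain comparable.

Weights: `ew` gives every expert 1/E on every item; `pwg` weights expert e
proportionally to 1{accuracy ≥ α}·accuracy·informativeness; `pwi`
modulates the accuracy factor per item with the expert's item-specific
information. The threshold α is optimized in-sample: the candidate set is
{0} plus the distinct observed expert accuracies (a finer grid cannot
change any DM's support), each candidate DM is built and scored, and the
maximal combined score wins, ties resolving to the smallest α (widest
support). The optimized DM therefore never scores below the all-experts
(α = 0) DM. `pwg` and `pwi` are optimized separately. For reporting, the
`pwi` DM's informativeness uses the same all-item mean as `pwg` and `ew`,
so the three DM score rows are directly comparable.

Degenerate inputs fail loudly: a zero raw span yields a "degenerate range"
error, and an interval of zero width carrying positive mass (e.g. q95 at a
clipped upper bound) is an error rather than a silent renormalization.

## Cross-panel analytics

A *score table* (one row per panel × assessor, DM rows labelled
pwg/pwi/ew) is the exchange format between scoring and evaluation; tables
computed from a study and tables read from files flow through identical
code. Panels sharing exactly the same expert membership collapse to one
representative (first in panel-id order) before the PW-vs-EW comparison.
Expert-level deduplicated scores pool each expert's calibration bin counts
across their panels into a single accuracy test and average information
over all their items (a per-panel-then-average alternative is available;
it is also the only option when starting from a score table, which carries
no counts).

The informativeness–accuracy association is Spearman's rank correlation
with average ranks for ties. Its one-sided p-value (probability of a
correlation this negative or lower under independence) comes from a seeded
permutation test, 100,000 permutations by default with seed 20160301, with
a t-approximation fallback (`n_perm=0`). The running rank correlation
orders experts by increasing accuracy (ties broken by id) and reports the
correlation over experts k..n for k = 1..n−2 (windows below 3 experts are
omitted). The expected number of false rejections among n statistically
accurate panels at level λ is round(n·λ), half away from zero.

## Synthetic studies

The generator emulates a large multi-panel elicitation: 112 panels × 13
experts by default, 10–15 calibration items per panel (sampled uniformly),
10 target items, quantities being percentages. Item j has a latent scale
σⱼ ~ U(0.3, 1.0) on a logit scale and truth xⱼ; expert e observes the
noisy signal xⱼ + σⱼ·η (η standard normal, independent per expert) and
states the quantiles of N(signal + bₑσⱼ, (cₑσⱼ)²); everything is mapped to
[0, 100] by the logistic function, which preserves quantiles and hence bin
membership. Archetypes: calibrated (b=0, c=1 — the stated distribution is
exactly the sampling distribution of the realization given the expert's
information, so stated quantiles are true quantiles), overconfident (c=0.3),
underconfident (c=2), biased (b=1, c=1). The default mix is 10% calibrated,
50% overconfident, 25% biased, 15% underconfident: mostly miscalibrated
experts with a small accurate minority, the regime — common in remote,
lightly-trained elicitations — in which the informativeness–accuracy
trade-off and the benefit of performance weighting are visible. A Gaussian
location-scale family is used for analytic control of calibration; nothing
downstream depends on that choice.

Randomness is organized as counter-keyed substreams (numpy `SeedSequence`
spawn keys per panel and per expert within a panel), so enlarging
`n_panels` never reshuffles existing panels and a fixed seed reproduces a
study bit-for-bit.

What the generator does **not** emulate: overlapping panel membership
(every synthetic panel has fresh experts, so deduplication analytics are
exercised by construction rather than by realistic overlap), behavioral
coupling between experts (anchoring, shared information), heavy-tailed or
skewed subjective distributions, and item difficulty heterogeneity beyond
the σⱼ spread. Passing tests on synthetic data therefore demonstrate the
correctness of the scoring/pooling machinery and the qualitative pooling
phenomena, not quantitative agreement with any particular field study.

## Problem sizes and tolerances

The test suite uses 200-replicate panels for the simulation phenomena
(equal-weight dilution, performance-weight recovery, correlation
attenuation, archetype recovery), 2,000 replicate experts × 100 items for
p-value uniformity, and exhaustive search as its own oracle for the
threshold optimizer; `scripts/acceptance.py` runs the full 112-panel
configuration. Mixture CDFs are validated against an independently coded
interval-accumulation oracle to 1e-10, DM quantiles against bisection to
1e-10, and the chi-square tail against direct numerical integration of the
density. Serialization uses `repr` floats (shortest round-trip), so
write/read cycles are bit-identical.
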