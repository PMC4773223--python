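# sejkit

Scoring and pooling machinery for **structured expert judgment (SEJ)** under
Cooke's Classical Model, plus the cross-panel evaluation analytics used to
appraise large multi-panel elicitations such as expert attributions of
disease burden across hazards and world regions.

When data are sparse, panels of experts quantify uncertain quantities by
stating three marker quantiles (5%, 50%, 95%) per question. The Classical
Model scores each expert empirically on *calibration variables* — questions
from their field whose true values become known — and uses those scores to
weight the experts when pooling their distributions for the target
questions. `sejkit` implements the scores, the pooled decision makers, the
in-sample threshold optimization, and the study-level analytics that compare
performance weighting with equal weighting, and ships a synthetic-study
generator with controlled expert behavior so every stage can be exercised
end-to-end.

## The model

For expert *e* with *N* calibration variables, each realization falls into
one of the four inter-quantile bins with theoretical probabilities
*p* = (0.05, 0.45, 0.45, 0.05). With empirical bin frequencies *s*,

- **Statistical accuracy** (calibration score) is the p-value
  `C(e) = P(χ²₃ ≥ 2·N·I(s; p))`, where `I(s; p) = Σ sᵢ ln(sᵢ/pᵢ)` — the
  p-value at which one would falsely reject the hypothesis that the
  expert's probability statements are statistically accurate.
- **Informativeness** is the Shannon relative information of the expert's
  minimally-informative reconstructed density (masses 0.05/0.45/0.45/0.05,
  uniform within each inter-quantile interval) with respect to a uniform
  background measure on the item's *intrinsic range* — the envelope of all
  assessors' outer quantiles and the realization, extended by a 10%
  overshoot and clipped to natural bounds. Averaged over items; scale
  invariant; higher means narrower distributions.
- **Combined score** = accuracy × informativeness, proportional to the
  expert's performance-based weight.

A **decision maker (DM)** is a weighted mixture of the experts' densities:
equal weights (`ew`), global performance weights (`pwg`), or item-specific
performance weights (`pwi`). Experts whose accuracy falls below a threshold
α get zero weight; α is optimized in-sample by exhaustive search over the
observed accuracy values, maximizing the DM's own combined score. DMs are
scored exactly like experts, on the same intrinsic ranges.

## Worked example

```sh
sejkit simulate --seed 7 --n-panels 10 --out study.json --truth-out truth.csv
sejkit score study.json --out scores.csv
sejkit report scores.csv
```

prints

```
Panels: 10 total, 10 with distinct expert sets
Experts (deduplicated): 130; 48 with accuracy > 0.05
PWG beats EW (combined, in-sample) in 90.0% of distinct panels
Mean informativeness: experts 0.974, EW 0.202, PWG 0.489
EW DMs with informativeness < 0.5: 100.0%
Panels with pwg accuracy < 0.045: 0
Expert-level Spearman(informativeness, accuracy): rho=-0.693, one-sided p=1.00e-05
Expected false rejections at 5% among 10 panels: 1
```

The synthetic panels mix calibrated, overconfident, biased and
underconfident experts, so the numbers show the canonical SEJ pattern:
experts' informativeness correlates negatively with their statistical
accuracy (ρ = −0.69, driven by the overconfident majority); averaging all
experts (EW) achieves accuracy but dilutes informativeness five-fold
(0.97 → 0.20); performance weighting (PWG) recovers much of it (0.49)
while keeping every panel DM statistically acceptable, and beats EW on the
combined score in 90% of panels. `sejkit analyze` writes the same
statistics, the expert accuracy/informativeness scatter, and the running
rank correlation (experts ordered by increasing accuracy — the negative
correlation attenuates as the least accurate experts are dropped) as CSV
files for plotting.

The library API mirrors the pipeline: `sejkit.generate_study`,
`sejkit.score_panel_experts`, `sejkit.equal_weight_dm`,
`sejkit.optimize_threshold`, `sejkit.score_table_from_study`,
`sejkit.pw_vs_ew_summary`. Published per-panel score tables (expert rows
plus `pwg`/`pwi`/`ew` rows) can be loaded with `sejkit.read_score_table`
from CSV or spreadsheet and fed to the same analytics.

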