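"""Cross-panel evaluation analytics.

Works on a *score table*: a tidy frame with one row per (panel, assessor)
carrying statistical accuracy, informativeness and the combined score, where
the assessor is either an expert or one of the pooled DMs (``ew``, ``pwg``,
``pwi``).  The same summaries can be computed from raw elicitations (a
Study) by first exporting its score table with :func:`score_table_from_study`,
and the two routes agree exactly.

The headline analytics are the PW-vs-EW comparison (how often performance
weighting beats equal weighting in-sample, and what each costs in
informativeness) and the correlation structure between informativeness and
statistical accuracy across experts, including the running rank correlation
over progressively more accurate subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import equal_weight_dm, optimize_threshold
from .scoring import panel_ranges, score_panel_experts, statistical_accuracy
from .study import CalibrationCounts, RangeConfig, ScoreRecord, Study
from . import scoring

__all__ = [
    "SCORE_TABLE_COLUMNS",
    "DM_KINDS",
    "RunningCorrelation",
    "score_table_from_study",
    "validate_score_table",
    "distinct_panels",
    "expert_overall_scores",
    "spearman_rho",
    "running_rank_correlation",
    "pw_vs_ew_summary",
    "expected_false_rejections",
]

SCORE_TABLE_COLUMNS = (
    "panel",
    "assessor",
    "kind",
    "statistical_accuracy",
    "informativeness",
    "combined",
)

DM_KINDS = ("pwg", "pwi", "ew")

#: Default seed of the permutation test for the correlation p-value.
DEFAULT_PERMUTATION_SEED = 20160301


@dataclass(frozen=True)
class RunningCorrelation:
    """Rank correlation over experts k..n, ordered by increasing accuracy."""

    k: int
    rho: float


def score_table_from_study(
    study: Study,
    range_cfg: Optional[RangeConfig] = None,
    item_set: str = "all_items",
    optimize: bool = True,
    alpha: float = 0.0,
    schemes: Sequence[str] = ("pwg", "pwi"),
) -> pd.DataFrame:
    """Run the full scoring + pooling pipeline on every panel.

    Emits one expert row per (panel, expert) plus ``ew`` and performance-DM
    rows per panel.  With ``optimize`` the accuracy threshold of each
    performance scheme is optimized in-sample per panel (separately per
    scheme); otherwise the fixed ``alpha`` is used.
    """
    rows = []
    for panel in study.panels:
        ranges = panel_ranges(panel, range_cfg)
        expert_scores = score_panel_experts(panel, ranges, item_set)
        for e in panel.experts:
            rows.append((panel.id, e, "expert", expert_scores[e]))
        rows.append((panel.id, "ew", "ew", equal_weight_dm(panel, ranges, item_set).score))
        for label in schemes:
            scheme = "global" if label == "pwg" else "item"
            if optimize:
                dm = optimize_threshold(
                    panel, ranges, scheme, item_set, expert_scores=expert_scores
                )
            else:
                from .aggregation import performance_weight_dm

                dm = performance_weight_dm(
                    panel, ranges, alpha, scheme, item_set, expert_scores=expert_scores
                )
            rows.append((panel.id, label, label, dm.score))
    return pd.DataFrame(
        [
            {
                "panel": pid,
                "assessor": assessor,
                "kind": kind,
                "statistical_accuracy": rec.statistical_accuracy,
                "informativeness": rec.informativeness,
                "combined": rec.combined,
            }
            for pid, assessor, kind, rec in rows
        ],
        columns=list(SCORE_TABLE_COLUMNS),
    )


def validate_score_table(table: pd.DataFrame, rtol: float = 1e-6) -> list[str]:
    """Check score-table invariants; returns violation descriptions."""
    problems: list[str] = []
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        return [f"missing columns: {missing}"]
    dup = table.duplicated(subset=["panel", "assessor"])
    for idx in table.index[dup]:
        problems.append(
            f"row {idx}: duplicate (panel, assessor) "
            f"({table.at[idx, 'panel']!r}, {table.at[idx, 'assessor']!r})"
        )
    bad_kind = ~table["kind"].isin(("expert",) + DM_KINDS)
    for idx in table.index[bad_kind]:
        problems.append(f"row {idx}: unknown assessor kind {table.at[idx, 'kind']!r}")
    prod = table["statistical_accuracy"] * table["informativeness"]
    off = ~np.isclose(prod, table["combined"], rtol=rtol, atol=1e-9)
    for idx in table.index[off & ~bad_kind]:
        problems.append(
            f"row {idx}: combined {table.at[idx, 'combined']} inconsistent with "
            f"accuracy x informativeness = {prod[idx]}"
        )
    return problems


def distinct_panels(obj: Study | pd.DataFrame) -> list[str]:
    """One representative panel id per distinct expert-membership set.

    Panels sharing exactly the same set of experts collapse to the first of
    them in panel-id order.
    """
    if isinstance(obj, Study):
        memberships = {p.id: frozenset(p.experts) for p in obj.panels}
    else:
        experts = obj[obj["kind"] == "expert"]
        memberships = {
            pid: frozenset(grp["assessor"]) for pid, grp in experts.groupby("panel")
        }
    seen: dict[frozenset, str] = {}
    for pid in sorted(memberships):
        seen.setdefault(memberships[pid], pid)
    return sorted(seen.values())


def expert_overall_scores(
    study: Study,
    range_cfg: Optional[RangeConfig] = None,
    item_set: str = "all_items",
    method: str = "pooled",
) -> pd.DataFrame:
    """One overall ScoreRecord per expert across all their panels.

    ``pooled`` (default) sums each expert's calibration bin counts across
    panels into a single accuracy test and averages information over all
    their items; ``average`` instead averages the per-panel scores.
    """
    if method not in ("pooled", "average"):
        raise ValueError(f"unknown pooling method {method!r}")
    per_panel: dict[str, list[ScoreRecord]] = {}
    counts: dict[str, np.ndarray] = {}
    infos: dict[str, list[float]] = {}
    for panel in study.panels:
        ranges = panel_ranges(panel, range_cfg)
        for e in panel.experts:
            triples = {it.id: panel.triple(e, it.id) for it in panel.items}
            rec = scoring.score_expert(panel, e, ranges, item_set)
            per_panel.setdefault(e, []).append(rec)
            c = scoring.bin_counts(panel, triples)
            counts[e] = counts.get(e, np.zeros(4)) + np.asarray(c.counts)
            ids = [it.id for it in (panel.items if item_set == "all_items"
                                    else panel.calibration_items)]
            infos.setdefault(e, []).extend(
                scoring.information_per_item(triples[i], ranges[i]) for i in ids
            )
    rows = []
    for e in sorted(per_panel):
        if method == "pooled":
            acc = statistical_accuracy(
                CalibrationCounts(counts=tuple(int(x) for x in counts[e]))
            )
            inf = float(np.mean(infos[e]))
        else:
            acc = float(np.mean([r.statistical_accuracy for r in per_panel[e]]))
            inf = float(np.mean([r.informativeness for r in per_panel[e]]))
        rows.append(
            {
                "assessor": e,
                "n_panels": len(per_panel[e]),
                "statistical_accuracy": acc,
                "informativeness": inf,
                "combined": acc * inf,
            }
        )
    return pd.DataFrame(rows)


def expert_scores_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated expert-level scores from a score table: per-expert mean
    of accuracy and informativeness across the panels they sat on."""
    experts = table[table["kind"] == "expert"]
    agg = (
        experts.groupby("assessor")[["statistical_accuracy", "informativeness"]]
        .mean()
        .reset_index()
    )
    agg["n_panels"] = experts.groupby("assessor").size().values
    agg["combined"] = agg["statistical_accuracy"] * agg["informativeness"]
    return agg


def _permutation_p_less(
    rx: np.ndarray, ry: np.ndarray, rho_obs: float, n_perm: int, seed: int
) -> float:
    """One-sided p-value P(rho_perm <= rho_obs) by permuting one rank vector."""
    rng = np.random.default_rng(seed)
    n = len(rx)
    rxc = rx - rx.mean()
    denom = math.sqrt(float(np.sum(rxc**2)))
    ryc = ry - ry.mean()
    sy = math.sqrt(float(np.sum(ryc**2)))
    hits = 0
    chunk = max(100, int(2e7 // max(n, 1)))  # cap the permutation matrix at ~160 MB
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(ryc, (m, 1)), axis=1)
        rhos = (perms @ rxc) / (denom * sy)
        hits += int(np.sum(rhos <= rho_obs + 1e-12))
        done += m
    return (1 + hits) / (n_perm + 1)


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 100_000,
    seed: int = DEFAULT_PERMUTATION_SEED,
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and the one-sided
    p-value that a correlation this negative or lower arises by chance.

    The p-value is a seeded permutation test by default; with ``n_perm=0``
    it falls back to the t approximation.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if len(x_arr) != len(y_arr):
        raise ValueError("x and y must have equal length")
    if len(x_arr) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x_arr == x_arr[0]) or np.all(y_arr == y_arr[0]):
        raise ValueError("undefined correlation: constant vector")
    rx = stats.rankdata(x_arr)
    ry = stats.rankdata(y_arr)
    rho = float(stats.pearsonr(rx, ry).statistic)
    if n_perm and n_perm > 0:
        p = _permutation_p_less(rx, ry, rho, n_perm, seed)
    else:
        res = stats.spearmanr(x_arr, y_arr, alternative="less")
        p = float(res.pvalue)
    return rho, p


def running_rank_correlation(
    scores: pd.DataFrame,
) -> list[RunningCorrelation]:
    """Rank correlation between informativeness and accuracy over the
    experts k..n, with experts ordered by increasing statistical accuracy
    (ties broken by assessor id).  Windows smaller than 3 are omitted, so k
    runs 1..n-2.
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 experts")
    ordered = scores.sort_values(
        ["statistical_accuracy", "assessor"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(ordered)
    out = []
    acc = ordered["statistical_accuracy"].to_numpy()
    inf = ordered["informativeness"].to_numpy()
    for k in range(1, n - 1):  # 1-based window start; size n-k+1 >= 3
        window = slice(k - 1, n)
        rho = float(stats.spearmanr(inf[window], acc[window]).statistic)
        out.append(RunningCorrelation(k=k, rho=rho))
    return out


def expected_false_rejections(n_panels: int, level: float) -> int:
    """Expected count of statistically accurate panels rejected at ``level``,
    rounded to the nearest integer (half away from zero)."""
    if n_panels < 1:
        raise ValueError("n_panels must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    return int(math.floor(n_panels * level + 0.5))


def pw_vs_ew_summary(
    table: pd.DataFrame,
    panels: Optional[Iterable[str]] = None,
    pw_kind: str = "pwg",
    accuracy_threshold: float = 0.045,
    info_threshold: float = 0.5,
    expert_accuracy_level: float = 0.05,
) -> dict:
    """Headline PW-vs-EW comparison over a panel subset.

    Returns the percentage of panels where the performance-weighted DM's
    combined score strictly beats the equal-weight DM's, mean
    informativeness of the EW DMs / PW DMs / deduplicated experts, the count
    of panels whose PW DM accuracy falls below ``accuracy_threshold``, the
    percentage of EW DMs with informativeness below ``info_threshold``, and
    the count of deduplicated experts with accuracy above
    ``expert_accuracy_level``.
    """
    subset = sorted(panels) if panels is not None else sorted(table["panel"].unique())
    dm = table[table["kind"].isin(DM_KINDS)].set_index(["panel", "kind"])
    for pid in subset:
        for kind in (pw_kind, "ew"):
            if (pid, kind) not in dm.index:
                raise ValueError(f"panel {pid!r}: missing {kind!r} DM row")
    pw = dm.loc[[(p, pw_kind) for p in subset]].reset_index()
    ew = dm.loc[[(p, "ew") for p in subset]].reset_index()
    experts = expert_scores_from_table(table)
    wins = np.sum(pw["combined"].to_numpy() > ew["combined"].to_numpy())
    return {
        "n_panels": len(subset),
        "pw_kind": pw_kind,
        "pw_win_pct": 100.0 * float(wins) / len(subset),
        "mean_ew_informativeness": float(ew["informativeness"].mean()),
        "mean_pw_informativeness": float(pw["informativeness"].mean()),
        "mean_expert_informativeness": float(experts["informativeness"].mean()),
        "n_pw_accuracy_below_threshold": int(
            np.sum(pw["statistical_accuracy"] < accuracy_threshold)
        ),
        "pct_ew_informativeness_below": 100.0
        * float(np.mean(ew["informativeness"] < info_threshold)),
        "n_experts": int(len(experts)),
        "n_experts_accuracy_above_level": int(
            np.sum(experts["statistical_accuracy"] > expert_accuracy_level)
        ),
    }
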