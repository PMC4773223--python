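"""Synthetic elicitation studies with controlled expert behavior.

The generator emulates the structure of a large multi-panel attribution
elicitation: many panels of ~13 experts each, 10-15 calibration variables
per panel with known realizations, plus target variables, most quantities
being relative frequencies on [0, 100].

Expert behavior follows a signal-plus-archetype model.  For item j with
latent scale sigma_j, the truth is x_j; expert e privately observes the
noisy signal x_j + sigma_j * eta (eta standard normal) and states the 5/50/95%
quantiles of a normal centered at signal + b_e * sigma_j with standard
deviation c_e * sigma_j.  For the calibrated archetype (b=0, c=1) the stated
distribution is exactly the sampling distribution of the realization given
the expert's information, so their stated quantiles are true quantiles and
their calibration p-values are (asymptotically) uniform.  Overconfident
experts (c < 1) state intervals that are too narrow — more informative but
statistically inaccurate; underconfident experts (c > 1) the reverse;
biased experts (b != 0) are systematically shifted.  This mix is the
mechanism that produces the negative informativeness-accuracy association
that performance weighting must overcome.

Proportion items are generated on a logit scale and mapped to [0, 100], so
realizations and quantiles respect the natural bounds; the monotone map
preserves bin membership and hence calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .study import Item, Panel, QuantileTriple, Study

__all__ = [
    "ExpertArchetype",
    "SimConfig",
    "ARCHETYPES",
    "generate_study",
    "generate_score_table",
]

#: z-values of the 5/50/95% normal quantiles.
_Z = np.array([-1.6448536269514722, 0.0, 1.6448536269514722])


@dataclass(frozen=True)
class ExpertArchetype:
    """Bias and dispersion of an expert's stated distribution, in units of
    the item scale.  c < 1 is overconfident, c = 1 calibrated, c > 1
    underconfident."""

    name: str
    bias: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


ARCHETYPES = {
    "calibrated": ExpertArchetype("calibrated", bias=0.0, dispersion=1.0),
    "overconfident": ExpertArchetype("overconfident", bias=0.0, dispersion=0.3),
    "underconfident": ExpertArchetype("underconfident", bias=0.0, dispersion=2.0),
    "biased": ExpertArchetype("biased", bias=1.0, dispersion=1.0),
}

#: Default archetype mix: most experts overconfident or biased, a small
#: calibrated minority — the regime in which performance weighting matters.
DEFAULT_MIX = {
    "calibrated": 0.10,
    "overconfident": 0.50,
    "biased": 0.25,
    "underconfident": 0.15,
}


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    ``n_calibration`` is an inclusive (lo, hi) range sampled per panel;
    ``sigma_range`` bounds the per-item latent scale on the working
    (logit) scale; ``proportion_items`` maps items to percentages on
    [0, 100] through the logistic function.
    """

    n_panels: int = 112
    experts_per_panel: int = 13
    n_calibration: tuple[int, int] = (10, 15)
    n_target: int = 10
    archetype_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    sigma_range: tuple[float, float] = (0.3, 1.0)
    proportion_items: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_panels < 1 or self.experts_per_panel < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.n_calibration
        if not 1 <= lo <= hi:
            raise ValueError("invalid n_calibration range")
        if self.n_target < 0:
            raise ValueError("n_target must be >= 0")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype mix sums to {total}, not 1")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Substream generator keyed so added panels never reshuffle old ones."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _logistic_pct(x: np.ndarray) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(-x))


def generate_study(cfg: SimConfig) -> tuple[Study, pd.DataFrame]:
    """Generate a synthetic Study plus the truth record of expert archetypes.

    Deterministic in ``cfg.seed``: the same config yields a bit-identical
    study.  Returns ``(study, truth)`` where ``truth`` has one row per
    (panel, expert) with the archetype and its parameters.
    """
    arch_names = sorted(cfg.archetype_mix)
    probs = np.array([cfg.archetype_mix[a] for a in arch_names])
    panels: list[Panel] = []
    truth_rows = []
    for p in range(cfg.n_panels):
        pid = f"panel{p:03d}"
        item_rng = _rng(cfg.seed, p, 0)
        n_cal = int(item_rng.integers(cfg.n_calibration[0], cfg.n_calibration[1] + 1))
        n_items = n_cal + cfg.n_target
        sigma = item_rng.uniform(*cfg.sigma_range, size=n_items)
        center = item_rng.normal(0.0, 1.0, size=n_items)
        x = center + sigma * item_rng.standard_normal(n_items)
        arch_idx = item_rng.choice(len(arch_names), size=cfg.experts_per_panel, p=probs)

        items: list[Item] = []
        for j in range(n_items):
            kind = "calibration" if j < n_cal else "target"
            realization = None
            if kind == "calibration":
                realization = float(_logistic_pct(x[j])) if cfg.proportion_items else float(x[j])
            items.append(
                Item(
                    id=f"{pid}:item{j:02d}",
                    kind=kind,
                    scale="uniform",
                    units="%" if cfg.proportion_items else "",
                    realization=realization,
                    bounds=(0.0, 100.0) if cfg.proportion_items else None,
                )
            )

        experts = [f"{pid}:e{e:02d}" for e in range(cfg.experts_per_panel)]
        assessments: dict[tuple[str, str], QuantileTriple] = {}
        for e, eid in enumerate(experts):
            arch = ARCHETYPES[arch_names[arch_idx[e]]]
            erng = _rng(cfg.seed, p, 1 + e)
            eta = erng.standard_normal(n_items)
            mu = x + sigma * eta + arch.bias * sigma
            q = mu[:, None] + (arch.dispersion * sigma)[:, None] * _Z[None, :]
            if cfg.proportion_items:
                q = _logistic_pct(q)
            for j, it in enumerate(items):
                assessments[(eid, it.id)] = QuantileTriple(
                    q05=float(q[j, 0]), q50=float(q[j, 1]), q95=float(q[j, 2])
                )
            truth_rows.append(
                {
                    "panel": pid,
                    "expert": eid,
                    "archetype": arch.name,
                    "bias": arch.bias,
                    "dispersion": arch.dispersion,
                }
            )
        panels.append(
            Panel(
                id=pid,
                hazard=f"hazard{p % 16:02d}",
                region=f"region{p % 7}",
                experts=experts,
                items=items,
                assessments=assessments,
            )
        )
    labels = {e: e for panel in panels for e in panel.experts}
    return Study(panels=panels, expert_labels=labels), pd.DataFrame(truth_rows)


def generate_score_table(cfg: SimConfig, **score_kwargs) -> pd.DataFrame:
    """Generate a study and run it through scoring + aggregation, returning
    the score table produced by the full pipeline."""
    from .analysis import score_table_from_study

    study, _ = generate_study(cfg)
    return score_table_from_study(study, **score_kwargs)
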