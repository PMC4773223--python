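"""Shared fixtures: a hand-built two-expert panel and small synthetic studies."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from sejkit.simulate import SimConfig, generate_study
from sejkit.study import Item, Panel, QuantileTriple, Study

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(
    panel_id: str = "p1",
    experts: tuple[str, ...] = ("A", "B"),
    realizations: tuple[float, ...] = (2.0, 5.0, 9.0),
    n_target: int = 1,
    triples: dict | None = None,
) -> Panel:
    """A small complete panel; default triples straddle the realizations."""
    items = [
        Item(id=f"c{i}", kind="calibration", realization=r)
        for i, r in enumerate(realizations)
    ] + [Item(id=f"t{i}", kind="target") for i in range(n_target)]
    default = {
        "A": QuantileTriple(1.0, 4.0, 11.0),
        "B": QuantileTriple(0.5, 6.0, 12.0),
    }
    assessments = {}
    for e in experts:
        for it in items:
            if triples and (e, it.id) in triples:
                assessments[(e, it.id)] = triples[(e, it.id)]
            else:
                assessments[(e, it.id)] = default.get(e, QuantileTriple(1.0, 5.0, 10.0))
    return Panel(
        id=panel_id,
        hazard="hazardX",
        region="regionY",
        experts=list(experts),
        items=items,
        assessments=assessments,
    )


@pytest.fixture
def two_expert_panel() -> Panel:
    return make_panel()


@pytest.fixture
def tiny_study(two_expert_panel) -> Study:
    return Study(panels=[two_expert_panel], expert_labels={"A": "Alice", "B": "Bob"})


@pytest.fixture(scope="session")
def mixed_study():
    """A small mixed-archetype synthetic study plus its truth record."""
    cfg = SimConfig(n_panels=4, experts_per_panel=6, n_target=4, seed=1234)
    return generate_study(cfg)
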