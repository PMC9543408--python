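import warnings

import numpy as np
import pytest

import estimandtools as et
from estimandtools.synthetic_trial import ReasonHazard

# subject-exclusion warnings are expected noise in simulation-heavy tests
warnings.filterwarnings(
    "ignore", message="subject .* has no observed post-baseline outcomes"
)


def monotone_dropout_config(
    n_per_arm: int,
    loe_placebo: float = -4.9,
    loe_active: float | None = None,
    delta6: float = -4.0,
    mechanism: str = "MAR_CONTINUATION",
    effect_profile: str = "ramp",
    loe_score_coef: float = 0.08,
    **kw,
) -> et.SimConfig:
    """Study-condition config: monotone (LoE-dominated, score-dependent MAR)
    dropout, no intermittent missingness, visit-6 true contrast = delta6.

    ``effect_profile="ramp"`` lets the treatment effect build up over the
    first visits; ``"constant"`` applies the full offset from visit 1
    (effect established in week 1 and maintained).
    """
    placebo = (26.0, 24.0, 22.0, 21.0, 20.0, 19.0)
    frac = {"ramp": (0.5, 0.75, 0.8, 0.9, 1.0, 1.0),
            "constant": (1.0,) * 6}[effect_profile]
    active = tuple(p + delta6 * f for p, f in zip(placebo, frac))
    dropout = {
        "LoE": ReasonHazard(
            intercepts=(
                {"*": loe_placebo}
                if loe_active is None
                else {"placebo": loe_placebo, "*": loe_active}
            ),
            score_coef=loe_score_coef,
        ),
        "AE": ReasonHazard(intercepts={"placebo": -4.6, "*": -3.8}, visit_range=(1, 2)),
        "drug_unrelated": ReasonHazard(intercepts={"*": -4.8}),
        "unknown": ReasonHazard(intercepts={"*": -5.3}),
    }
    return et.SimConfig(
        n_per_arm=n_per_arm,
        arm_visit_means={"placebo": placebo, "active": active},
        dropout_model=dropout,
        intermittent_prob=0.0,
        post_ie_mechanism=mechanism,
        **kw,
    )


def no_dropout_config(n_per_arm: int, delta6: float = -4.0, **kw) -> et.SimConfig:
    """Complete-data config: all hazards off, no intermittent missingness."""
    cfg = monotone_dropout_config(n_per_arm, delta6=delta6, **kw)
    cfg.dropout_model = {}
    return cfg


@pytest.fixture(scope="session")
def small_trial():
    """A small 2-arm, 6-visit trial with dropout and intermittent missing."""
    cfg = et.SimConfig(n_per_arm=30)
    ds, truth = et.simulate_trial(cfg, 42)
    return ds, truth


@pytest.fixture(scope="session")
def complete_trial():
    cfg = no_dropout_config(40)
    ds, truth = et.simulate_trial(cfg, 7)
    return ds, truth


@pytest.fixture()
def tiny_dataset():
    """Hand-built 2-arm, 6-visit trial with 4 subjects."""
    sched = et.VisitSchedule(6)
    subs = [
        et.SubjectRecord("a1", "placebo", 28.0, [25, 24, 22, 21, 20, 19]),
        et.SubjectRecord("a2", "placebo", 32.0,
                         [27, np.nan, 24, np.nan, np.nan, np.nan],
                         "LoE", 3),
        et.SubjectRecord("b1", "active", 30.5, [24, 21.5, 19, 17, 16, 15]),
        et.SubjectRecord("b2", "active", 26.0, [22, 20, np.nan, 18, 17, 16]),
    ]
    return et.TrialDataset(sched, subs, "placebo")
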