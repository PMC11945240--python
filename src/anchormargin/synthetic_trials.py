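"""Case-study fixture and binomial trial simulator.

``case_study_fixture`` returns the three published trials of the worked
example verbatim; ``simulate_trial`` draws two-arm binomial trials from stated
true rates for property tests and power exploration.  All randomness is
explicitly seeded; nothing reads global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .trial_model import ArmSummary, TwoArmTrial, make_arm


@dataclass(frozen=True)
class TrueTrialSpec:
    """Generative truth for a simulated two-arm trial."""

    trial_id: str
    true_rate_per_arm: dict[str, float]
    n_per_arm: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.true_rate_per_arm) != 2:
            raise ValidationError("a two-arm trial spec needs exactly two arm labels")
        if set(self.true_rate_per_arm) != set(self.n_per_arm):
            raise ValidationError("rate and n mappings must share the same arm labels")
        for label, rate in self.true_rate_per_arm.items():
            if not 0.0 < rate < 1.0:
                raise ValidationError(f"arm {label!r}: true rate must be in (0,1), got {rate}")
        for label, n in self.n_per_arm.items():
            if n < 1:
                raise ValidationError(f"arm {label!r}: n must be >= 1, got {n}")


def case_study_fixture() -> tuple[TwoArmTrial, TwoArmTrial, TwoArmTrial]:
    """The three published trials of the worked case study, hard-coded.

    Trial 1 compares Anchor to Reference, Trials 2 and 3 compare Anchor to
    Placebo (Trial 3 in a slightly different population).
    """
    # Trial 1: Anchor 94/200 (0.470), Reference 85/200 (0.425)
    trial1 = TwoArmTrial(
        trial_id="Trial 1",
        arm_a=make_arm("Anchor", 200, 94),
        arm_b=make_arm("Reference", 200, 85),
    )
    # Trial 2: Anchor 183/350 (0.523), Placebo 64/350 (0.183)
    trial2 = TwoArmTrial(
        trial_id="Trial 2",
        arm_a=make_arm("Anchor", 350, 183),
        arm_b=make_arm("Placebo", 350, 64),
    )
    # Trial 3: Anchor 53/100 (0.530), Placebo 5/50 (0.100)
    trial3 = TwoArmTrial(
        trial_id="Trial 3",
        arm_a=make_arm("Anchor", 100, 53),
        arm_b=make_arm("Placebo", 50, 5),
    )
    return trial1, trial2, trial3


def case_study_true_specs() -> tuple[TrueTrialSpec, TrueTrialSpec]:
    """Generative specs whose true rates equal the case-study point estimates
    of Trials 1 and 2 (used for parameter-recovery simulations)."""
    return (
        TrueTrialSpec(
            trial_id="Trial 1",
            true_rate_per_arm={"Anchor": 0.470, "Reference": 0.425},
            n_per_arm={"Anchor": 200, "Reference": 200},
        ),
        TrueTrialSpec(
            trial_id="Trial 2",
            true_rate_per_arm={"Anchor": 183 / 350, "Placebo": 64 / 350},
            n_per_arm={"Anchor": 350, "Placebo": 350},
        ),
    )


def simulate_trial(spec: TrueTrialSpec, seed: int) -> TwoArmTrial:
    """Draw a two-arm trial with independent binomial responder counts.

    Deterministic given (spec, seed); arms are drawn in the order the labels
    appear in the spec.
    """
    rng = np.random.default_rng(seed)
    arms: list[ArmSummary] = []
    for label, rate in spec.true_rate_per_arm.items():
        n = spec.n_per_arm[label]
        responders = int(rng.binomial(n, rate))
        arms.append(make_arm(label, n, responders))
    return TwoArmTrial(trial_id=spec.trial_id, arm_a=arms[0], arm_b=arms[1])
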