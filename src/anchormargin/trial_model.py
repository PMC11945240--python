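"""Binomial two-arm trial summaries.

The package works on aggregate data only: one row per arm with the number of
participants and the number of responders.  Response rates are carried at full
floating precision; rounding to the 3 decimals used in published tables happens
only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import NormalDist

from .errors import ValidationError

DEFAULT_LEVEL = 0.95
#: Exact two-sided 95% normal quantile.  Published tables quote "1.96" in
#: footnotes, but reproducing every printed cell (notably the 40%-preservation
#: margin bound, which sits on a rounding boundary) requires the exact
#: quantile; pass z=1.96 explicitly for the literal textbook multiplier.
DEFAULT_Z = NormalDist().inv_cdf(0.975)


def z_for_level(level: float, z: float | None = None) -> float:
    """Normal multiplier for a two-sided confidence level.

    Returns ``z`` unchanged if given, otherwise the exact quantile for the
    level.
    """
    if z is not None:
        return z
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    return NormalDist().inv_cdf(0.5 + level / 2.0)


@dataclass(frozen=True)
class ArmSummary:
    """One trial arm: ``responders`` of ``n`` participants responded."""

    label: str
    n: int
    responders: int
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or self.n <= 0:
            raise ValidationError(f"n must be a positive integer, got n={self.n!r}")
        if not isinstance(self.responders, int) or self.responders < 0:
            raise ValidationError(
                f"responders must be a non-negative integer, got responders={self.responders!r}"
            )
        if self.responders > self.n:
            raise ValidationError(
                f"responders={self.responders} exceeds n={self.n} for arm {self.label!r}"
            )
        object.__setattr__(self, "rate", self.responders / self.n)


def make_arm(label: str, n: int, responders: int) -> ArmSummary:
    """Validated constructor for :class:`ArmSummary`."""
    return ArmSummary(label=label, n=n, responders=responders)


@dataclass(frozen=True)
class TwoArmTrial:
    """A randomized two-arm trial, e.g. Anchor vs. Reference."""

    trial_id: str
    arm_a: ArmSummary
    arm_b: ArmSummary

    def __post_init__(self) -> None:
        if self.arm_a.label == self.arm_b.label:
            raise ValidationError(
                f"trial {self.trial_id!r}: arm labels must be distinct, "
                f"both are {self.arm_a.label!r}"
            )

    @property
    def arms(self) -> tuple[ArmSummary, ArmSummary]:
        return (self.arm_a, self.arm_b)

    def arm(self, label: str) -> ArmSummary:
        for a in self.arms:
            if a.label == label:
                return a
        raise ValidationError(
            f"trial {self.trial_id!r} has no arm {label!r} "
            f"(arms: {self.arm_a.label!r}, {self.arm_b.label!r})"
        )

    def has_arm(self, label: str) -> bool:
        return label in (self.arm_a.label, self.arm_b.label)


@dataclass(frozen=True)
class RateCI:
    """A response rate with a Wald confidence interval."""

    rate: float
    lower: float
    upper: float
    level: float = DEFAULT_LEVEL

    def __post_init__(self) -> None:
        if not self.lower <= self.rate <= self.upper:
            raise ValidationError(
                f"require lower <= rate <= upper, got ({self.lower}, {self.rate}, {self.upper})"
            )


def wald_rate_ci(
    arm: ArmSummary,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    clip: bool = False,
) -> RateCI:
    """Normal-approximation CI for a binomial response rate.

    rate ± z * sqrt(rate * (1 - rate) / n).  By default the bounds are *not*
    truncated to [0, 1], matching the convention of the published tables
    (e.g. a 5/50 arm prints a lower bound of 0.017); set ``clip=True`` to
    truncate.
    """
    zz = z_for_level(level, z)
    half = zz * (arm.rate * (1.0 - arm.rate) / arm.n) ** 0.5
    lo, hi = arm.rate - half, arm.rate + half
    if clip:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return RateCI(rate=arm.rate, lower=lo, upper=hi, level=level)
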