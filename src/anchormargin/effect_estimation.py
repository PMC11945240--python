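"""Rate-ratio effect estimation: direct within-trial and anchor-based indirect.

Direct comparison
    ratio = rate_num / rate_den on the response-rate scale, with the standard
    delta-method SE of the log ratio

        SE(ln ratio) = sqrt(1/r1 + 1/r2 - 1/n1 - 1/n2)

    where r is the responder count and n the arm size.

Anchor-based indirect comparison
    Two trials share a common comparator arm (the anchor A).  The effect of
    Reference (R) vs Placebo (P), never compared head-to-head, is estimated on
    the log scale as

        ln RR(R vs P) = ln RR(A vs P) - ln RR(A vs R)

    with variance the sum of the two component variances.  This is the classic
    adjusted indirect comparison (Bucher) with the anchor as the bridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError, ZeroResponderError
from .trial_model import DEFAULT_LEVEL, DEFAULT_Z, ArmSummary, z_for_level


@dataclass(frozen=True)
class RatioEstimate:
    """A response-rate ratio with its log-scale SE and Wald CI.

    ``numerator``/``denominator`` are the treatment labels of the comparison
    "numerator vs. denominator"; ``provenance`` records where the estimate
    came from ("direct:<trial_id>", "indirect", "pooled:<model>", ...).
    """

    numerator: str
    denominator: str
    log_ratio: float
    se_log: float
    level: float = DEFAULT_LEVEL
    z: float = DEFAULT_Z
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if self.se_log < 0:
            raise ValidationError(f"se_log must be non-negative, got {self.se_log}")

    @property
    def ratio(self) -> float:
        return math.exp(self.log_ratio)

    @property
    def ci_lower(self) -> float:
        return math.exp(self.log_ratio - self.z * self.se_log)

    @property
    def ci_upper(self) -> float:
        return math.exp(self.log_ratio + self.z * self.se_log)

    @property
    def comparison(self) -> str:
        return f"{self.numerator} vs. {self.denominator}"

    def inverted(self) -> "RatioEstimate":
        """The same comparison in the opposite direction (ratio -> 1/ratio)."""
        return RatioEstimate(
            numerator=self.denominator,
            denominator=self.numerator,
            log_ratio=-self.log_ratio,
            se_log=self.se_log,
            level=self.level,
            z=self.z,
            provenance=self.provenance,
        )


def se_log_ratio(r1: float, r2: float, n1: float, n2: float) -> float:
    """SE of the log rate ratio from (possibly non-integer) counts."""
    if r1 <= 0 or r2 <= 0:
        raise ZeroResponderError(
            "SE(ln ratio) is undefined with zero responders in an arm; "
            "pass continuity=True to apply a 0.5 correction"
        )
    return math.sqrt(1.0 / r1 + 1.0 / r2 - 1.0 / n1 - 1.0 / n2)


def direct_ratio(
    numerator_arm: ArmSummary,
    denominator_arm: ArmSummary,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    trial_id: str | None = None,
    continuity: bool = False,
) -> RatioEstimate:
    """Within-trial response-rate ratio of two arms.

    Zero-responder arms are refused by default (the SE formula is undefined
    there); ``continuity=True`` adds 0.5 to all four cells of the comparison.
    """
    r1, n1 = numerator_arm.responders, numerator_arm.n
    r2, n2 = denominator_arm.responders, denominator_arm.n
    if (r1 == 0 or r2 == 0) and continuity:
        r1, r2, n1, n2 = r1 + 0.5, r2 + 0.5, n1 + 0.5, n2 + 0.5
    se = se_log_ratio(r1, r2, n1, n2)
    log_ratio = math.log((r1 / n1) / (r2 / n2))
    prov = f"direct:{trial_id}" if trial_id else "direct"
    return RatioEstimate(
        numerator=numerator_arm.label,
        denominator=denominator_arm.label,
        log_ratio=log_ratio,
        se_log=se,
        level=level,
        z=z_for_level(level, z),
        provenance=prov,
    )


def ratio_from_rates(
    p_num: float,
    p_den: float,
    n_num: int,
    n_den: int,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    numerator: str = "num",
    denominator: str = "den",
    rounding: str = "continuous",
    provenance: str = "assumed",
) -> RatioEstimate:
    """Rate ratio for *assumed* true rates at given arm sizes.

    Used by the deterministic sensitivity sweeps, where candidate rates are
    plugged into the SE formula via expected responder counts n*p.  With
    ``rounding='continuous'`` the counts stay fractional; with
    ``rounding='integer'`` they are rounded to whole responders (both
    conventions give sweep minima within ~0.1 percentage point of each other).
    """
    if not (0.0 < p_num < 1.0 and 0.0 < p_den < 1.0):
        raise ValidationError(
            f"rates must be in (0,1) for the SE to be defined, got {p_num}, {p_den}"
        )
    r1, r2 = n_num * p_num, n_den * p_den
    if rounding == "integer":
        r1, r2 = round(r1), round(r2)
        if r1 == 0 or r2 == 0:
            raise ZeroResponderError("rounded responder count is zero")
        p_num, p_den = r1 / n_num, r2 / n_den
    elif rounding != "continuous":
        raise ValidationError(f"rounding must be 'continuous' or 'integer', got {rounding!r}")
    se = se_log_ratio(r1, r2, n_num, n_den)
    return RatioEstimate(
        numerator=numerator,
        denominator=denominator,
        log_ratio=math.log(p_num / p_den),
        se_log=se,
        level=level,
        z=z_for_level(level, z),
        provenance=provenance,
    )


def indirect_ratio(
    anchor_vs_target: RatioEstimate,
    anchor_vs_comparator: RatioEstimate,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
) -> RatioEstimate:
    """Anchor-based indirect comparison of target vs comparator.

    Both inputs must be "Anchor vs. X" estimates sharing the same anchor
    (numerator) label.  The result is target vs comparator:

        ln RR(T vs C) = ln RR(A vs C) - ln RR(A vs T),
        SE = sqrt(SE_1^2 + SE_2^2).
    """
    if anchor_vs_target.numerator != anchor_vs_comparator.numerator:
        raise ValidationError(
            "indirect comparison requires a common anchor: numerator labels are "
            f"{anchor_vs_target.numerator!r} and {anchor_vs_comparator.numerator!r}"
        )
    log_ratio = anchor_vs_comparator.log_ratio - anchor_vs_target.log_ratio
    se = math.sqrt(anchor_vs_target.se_log**2 + anchor_vs_comparator.se_log**2)
    return RatioEstimate(
        numerator=anchor_vs_target.denominator,
        denominator=anchor_vs_comparator.denominator,
        log_ratio=log_ratio,
        se_log=se,
        level=level,
        z=z_for_level(level, z),
        provenance=(
            f"indirect:({anchor_vs_target.provenance},{anchor_vs_comparator.provenance})"
        ),
    )
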