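"""Equivalence-margin derivation by the 95-95 fixed-margin method.

The margin is a fraction of the demonstrated historical effect: from the lower
95% CI bound L (> 1) of the Reference-vs-Placebo rate ratio and a preservation
factor f, the upper margin is

    upper = exp(ln(L) * (1 - f)),      lower = 1 / upper,

so the margin pair is symmetric on the log scale and guarantees that a trial
concluding equivalence within it preserves at least the fraction f of the
historical log effect.  ``preservation_of`` is the exact inverse: given a
margin upper bound and a CI bound it returns the fraction retained.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .effect_estimation import RatioEstimate
from .errors import MarginUndefinedError, ValidationError
from .trial_model import DEFAULT_LEVEL


@dataclass(frozen=True)
class EquivalenceMargin:
    """A (lower, upper) equivalence margin symmetric on the log scale."""

    lower: float
    upper: float
    preservation: float
    source_bound: float
    level: float = DEFAULT_LEVEL

    def __post_init__(self) -> None:
        if not math.isclose(self.lower * self.upper, 1.0, rel_tol=1e-12):
            raise ValidationError(
                f"margin must be symmetric on the log scale: {self.lower} * {self.upper} != 1"
            )


class Verdict(enum.Enum):
    MET = "met"
    NOT_MET = "not_met"
    MET_WITHOUT_EQUALITY_POINT = "met_without_equality_point"


def derive_margin_from_bound(
    source_bound: float, preservation: float, level: float = DEFAULT_LEVEL
) -> EquivalenceMargin:
    """Margin from a raw CI bound (> 1) and a preservation fraction."""
    if not 0.0 <= preservation <= 1.0:
        raise ValidationError(f"preservation must be in [0,1], got {preservation}")
    if source_bound <= 1.0:
        raise MarginUndefinedError(
            "no demonstrated effect; margin undefined "
            f"(CI bound {source_bound:.4g} does not exceed 1)"
        )
    upper = math.exp(math.log(source_bound) * (1.0 - preservation))
    return EquivalenceMargin(
        lower=1.0 / upper,
        upper=upper,
        preservation=preservation,
        source_bound=source_bound,
        level=level,
    )


def derive_margin(effect: RatioEstimate, preservation: float) -> EquivalenceMargin:
    """95-95 margin from the CI bound of a superiority effect estimate.

    The bound used is the CI bound nearer 1.  Effects in the protective
    direction (ratio < 1) are inverted internally, so the relevant bound is
    1/ci_upper; the published worked example only treats ratios > 1.
    """
    eff = effect.inverted() if effect.ratio < 1.0 else effect
    return derive_margin_from_bound(eff.ci_lower, preservation, level=eff.level)


def preservation_of(margin_upper: float, ci_lower: float) -> float:
    """Fraction of the historical effect a margin preserves: 1 - ln(U)/ln(L).

    Exact inverse of :func:`derive_margin_from_bound`.  The value is returned
    signed: a margin wider than the demonstrated effect (U >= L) yields a
    preservation <= 0, which sensitivity sweeps plot rather than clamp.
    """
    if ci_lower <= 1.0:
        raise MarginUndefinedError(
            f"preservation undefined: CI bound {ci_lower:.4g} does not exceed 1"
        )
    if margin_upper <= 1.0:
        raise ValidationError(f"margin upper bound must exceed 1, got {margin_upper}")
    return 1.0 - math.log(margin_upper) / math.log(ci_lower)


def equivalence_verdict(
    ci_lower: float,
    ci_upper: float,
    margin: EquivalenceMargin,
    strict: bool = True,
) -> Verdict:
    """Equivalence conclusion for a future trial's CI against a margin.

    Equivalence is met when the CI lies entirely within the margin (strict
    containment by default, matching the usual graphical convention).  When
    the CI is contained but excludes the equality point 1, the verdict flags
    that an additional explanation is needed.
    """
    if not (0.0 < ci_lower <= ci_upper):
        raise ValidationError(f"require 0 < ci_lower <= ci_upper, got ({ci_lower}, {ci_upper})")
    if strict:
        inside = margin.lower < ci_lower and ci_upper < margin.upper
    else:
        inside = margin.lower <= ci_lower and ci_upper <= margin.upper
    if not inside:
        return Verdict.NOT_MET
    if ci_lower > 1.0 or ci_upper < 1.0:
        return Verdict.MET_WITHOUT_EQUALITY_POINT
    return Verdict.MET
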