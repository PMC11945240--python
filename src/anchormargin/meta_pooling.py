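"""Meta-analytic pooling of rate ratios across trials.

Three models are provided for pooling several trials of the same comparison
before it enters the indirect analysis:

* ``common_iv`` — inverse-variance common effect on the log-ratio scale.
* ``common_mh`` — Mantel–Haenszel common effect on the 2x2 counts, with the
  Greenland–Robins variance for the log pooled risk ratio.
* ``random_dl`` — DerSimonian–Laird random effects: the moment estimator
  tau^2 = max(0, (Q - df) / C), C = sum(w) - sum(w^2)/sum(w), with Q from the
  inverse-variance common-effect residuals, and weights 1/(se_i^2 + tau^2).

Heterogeneity is summarized by Cochran's Q, tau^2 and I^2 = max(0, (Q-df)/Q).
CIs use the normal approximation (not Hartung–Knapp), matching the published
interval widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .effect_estimation import RatioEstimate, direct_ratio
from .errors import ValidationError
from .trial_model import DEFAULT_LEVEL, DEFAULT_Z, TwoArmTrial, z_for_level


@dataclass(frozen=True)
class MetaResult:
    """A pooled log rate ratio with heterogeneity statistics."""

    numerator: str
    denominator: str
    pooled_log_ratio: float
    se_log: float
    model: str  # common_iv | common_mh | random_dl
    q_stat: float
    tau2: float
    i2: float
    weights: tuple[float, ...]  # normalized, sum to 1
    level: float = DEFAULT_LEVEL
    z: float = DEFAULT_Z

    @property
    def ratio(self) -> float:
        return math.exp(self.pooled_log_ratio)

    @property
    def ci_lower(self) -> float:
        return math.exp(self.pooled_log_ratio - self.z * self.se_log)

    @property
    def ci_upper(self) -> float:
        return math.exp(self.pooled_log_ratio + self.z * self.se_log)

    def as_estimate(self) -> RatioEstimate:
        """The pooled result as a plain :class:`RatioEstimate` for chaining
        into the indirect comparison."""
        return RatioEstimate(
            numerator=self.numerator,
            denominator=self.denominator,
            log_ratio=self.pooled_log_ratio,
            se_log=self.se_log,
            level=self.level,
            z=self.z,
            provenance=f"pooled:{self.model}",
        )


def _check_estimates(estimates: Sequence[RatioEstimate]) -> None:
    if len(estimates) == 0:
        raise ValidationError("cannot pool an empty list of estimates")
    pairs = {(e.numerator, e.denominator) for e in estimates}
    if len(pairs) > 1:
        raise ValidationError(
            f"all estimates must be the same comparison; found {sorted(pairs)}"
        )


def _q_statistic(estimates: Sequence[RatioEstimate]) -> tuple[float, float, float]:
    """Cochran's Q from inverse-variance weights; returns (Q, sum_w, C)."""
    w = [1.0 / e.se_log**2 for e in estimates]
    th = [e.log_ratio for e in estimates]
    sw = sum(w)
    mu = sum(wi * ti for wi, ti in zip(w, th)) / sw
    q = sum(wi * (ti - mu) ** 2 for wi, ti in zip(w, th))
    c = sw - sum(wi**2 for wi in w) / sw
    return q, sw, c


def pool_common_iv(
    estimates: Sequence[RatioEstimate],
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
) -> MetaResult:
    """Inverse-variance common-effect pooled log rate ratio."""
    _check_estimates(estimates)
    w = [1.0 / e.se_log**2 for e in estimates]
    sw = sum(w)
    mu = sum(wi * e.log_ratio for wi, e in zip(w, estimates)) / sw
    q, _, _ = _q_statistic(estimates) if len(estimates) > 1 else (0.0, sw, 0.0)
    df = max(len(estimates) - 1, 0)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        numerator=estimates[0].numerator,
        denominator=estimates[0].denominator,
        pooled_log_ratio=mu,
        se_log=math.sqrt(1.0 / sw),
        model="common_iv",
        q_stat=q,
        tau2=0.0,
        i2=i2,
        weights=tuple(wi / sw for wi in w),
        level=level,
        z=z_for_level(level, z),
    )


def pool_random_dl(
    estimates: Sequence[RatioEstimate],
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
) -> MetaResult:
    """DerSimonian–Laird random-effects pooled log rate ratio.

    With a single study the result is that study with tau^2 = 0.
    """
    _check_estimates(estimates)
    if len(estimates) == 1:
        e = estimates[0]
        return MetaResult(
            numerator=e.numerator,
            denominator=e.denominator,
            pooled_log_ratio=e.log_ratio,
            se_log=e.se_log,
            model="random_dl",
            q_stat=0.0,
            tau2=0.0,
            i2=0.0,
            weights=(1.0,),
            level=level,
            z=z_for_level(level, z),
        )
    q, _, c = _q_statistic(estimates)
    df = len(estimates) - 1
    tau2 = max(0.0, (q - df) / c)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    wr = [1.0 / (e.se_log**2 + tau2) for e in estimates]
    swr = sum(wr)
    mu = sum(wi * e.log_ratio for wi, e in zip(wr, estimates)) / swr
    return MetaResult(
        numerator=estimates[0].numerator,
        denominator=estimates[0].denominator,
        pooled_log_ratio=mu,
        se_log=math.sqrt(1.0 / swr),
        model="random_dl",
        q_stat=q,
        tau2=tau2,
        i2=i2,
        weights=tuple(wi / swr for wi in wr),
        level=level,
        z=z_for_level(level, z),
    )


def pool_common_mh(
    trials: Sequence[TwoArmTrial],
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
) -> MetaResult:
    """Mantel–Haenszel common-effect pooled risk ratio from 2x2 counts.

    Each trial contributes its full counts (arm_a is the numerator arm):

        RR_MH = sum(a_i * n2_i / N_i) / sum(c_i * n1_i / N_i)

    with the Greenland–Robins variance for ln(RR_MH).  Q/tau^2/I^2 are
    reported from the inverse-variance residuals of the per-trial log ratios
    (the usual forest-plot heterogeneity line).
    """
    if len(trials) == 0:
        raise ValidationError("cannot pool an empty list of trials")
    pairs = {(t.arm_a.label, t.arm_b.label) for t in trials}
    if len(pairs) > 1:
        raise ValidationError(
            f"all trials must compare the same arms in the same order; found {sorted(pairs)}"
        )
    num, den = 0.0, 0.0
    gr_num = 0.0  # Greenland-Robins variance numerator
    mh_weights = []
    for t in trials:
        a, n1 = t.arm_a.responders, t.arm_a.n
        c, n2 = t.arm_b.responders, t.arm_b.n
        if a == 0 or c == 0:
            raise ValidationError(
                f"trial {t.trial_id!r} has a zero-responder arm; the MH log-RR "
                "variance is undefined"
            )
        big_n = n1 + n2
        num += a * n2 / big_n
        den += c * n1 / big_n
        gr_num += (n1 * n2 * (a + c) - a * c * big_n) / big_n**2
        mh_weights.append(c * n1 / big_n)
    log_rr = math.log(num / den)
    se = math.sqrt(gr_num / (num * den))
    per_trial = [direct_ratio(t.arm_a, t.arm_b, level=level, z=z, trial_id=t.trial_id) for t in trials]
    if len(per_trial) > 1:
        q, _, c_ = _q_statistic(per_trial)
        df = len(per_trial) - 1
        tau2 = max(0.0, (q - df) / c_)
        i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    else:
        q, tau2, i2 = 0.0, 0.0, 0.0
    sw = sum(mh_weights)
    return MetaResult(
        numerator=trials[0].arm_a.label,
        denominator=trials[0].arm_b.label,
        pooled_log_ratio=log_rr,
        se_log=se,
        model="common_mh",
        q_stat=q,
        tau2=tau2,
        i2=i2,
        weights=tuple(wi / sw for wi in mh_weights),
        level=level,
        z=z_for_level(level, z),
    )


def forest_data(
    estimates: Sequence[RatioEstimate],
    labels: Sequence[str] | None = None,
    level: float = DEFAULT_LEVEL,
) -> pd.DataFrame:
    """Plot-ready forest data: per-study rows plus common and random pooled rows.

    Columns: label, ratio, ci_lower, ci_upper, weight_common, weight_random.
    No rendering is done here; this is the data behind a forest plot.
    """
    _check_estimates(estimates)
    labels = list(labels) if labels is not None else [e.provenance for e in estimates]
    common = pool_common_iv(estimates, level=level)
    random = pool_random_dl(estimates, level=level)
    rows = [
        {
            "label": lab,
            "ratio": e.ratio,
            "ci_lower": e.ci_lower,
            "ci_upper": e.ci_upper,
            "weight_common": wc,
            "weight_random": wr,
        }
        for lab, e, wc, wr in zip(labels, estimates, common.weights, random.weights)
    ]
    for pooled, name in ((common, "Common effect"), (random, "Random effects")):
        rows.append(
            {
                "label": name,
                "ratio": pooled.ratio,
                "ci_lower": pooled.ci_lower,
                "ci_upper": pooled.ci_upper,
                "weight_common": 1.0 if name == "Common effect" else float("nan"),
                "weight_random": 1.0 if name == "Random effects" else float("nan"),
            }
        )
    return pd.DataFrame(rows)
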