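"""Sensitivity analyses for the anchor-based margin.

Three analyses probe the transitivity/consistency assumptions behind an
indirect margin:

SA1 — direct margin from the Anchor-vs-Placebo trial alone, meaningful when
      Anchor and Reference have similar effects.
SA2 — robustness of the preservation factor to the unknown true Reference
      rate (and, in a second variant, to the Reference-vs-Anchor difference):
      deterministic sweeps across the Reference rate's 95% CI, and a
      posterior-predictive Monte-Carlo giving the probability of retaining at
      least a target fraction of the effect.
SA3 — indirect analysis after random-effects pooling of heterogeneous
      Anchor-vs-Placebo trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .effect_estimation import (
    RatioEstimate,
    direct_ratio,
    indirect_ratio,
    ratio_from_rates,
)
from .errors import ValidationError
from .margin_derivation import (
    EquivalenceMargin,
    derive_margin,
    preservation_of,
)
from .meta_pooling import MetaResult, pool_random_dl
from .trial_model import DEFAULT_LEVEL, TwoArmTrial, wald_rate_ci, z_for_level

PRIORS = {"uniform": (1.0, 1.0), "jeffreys": (0.5, 0.5)}

#: Anchor-minus-Reference differences examined in the worked case study:
#: the observed 4.5 points, then 6.0, 7.5 and twice-observed 9.0.
DEFAULT_DIFFERENCES = (0.045, 0.060, 0.075, 0.090)


@dataclass(frozen=True)
class SweepPoint:
    """One grid point of a deterministic sensitivity sweep."""

    reference_rate: float
    anchor_rate: float
    assumed_difference: float  # anchor - reference
    indirect_ci_lower: float
    preservation: float


@dataclass(frozen=True)
class SimulationResult:
    """Posterior-predictive Monte-Carlo output.

    ``preservation_draws`` holds one preservation factor per valid replicate;
    replicates where the simulated comparison is undefined (zero responders,
    or an indirect CI bound not exceeding 1) are excluded and counted in
    ``n_excluded``.  Exceedance probabilities are always divided by the full
    ``n_reps``, so excluded replicates count as failures to retain the effect.
    """

    n_reps: int
    seed: int
    preservation_draws: tuple[float, ...]
    n_excluded: int = 0
    exceedance: dict[float, float] = field(default_factory=dict)

    def prob_at_least(self, f: float) -> float:
        """P(preservation >= f), exact count over n_reps."""
        draws = np.asarray(self.preservation_draws)
        return float((draws >= f).sum()) / self.n_reps


def _shared_anchor(trial1: TwoArmTrial, trial2: TwoArmTrial) -> str:
    labels1 = {trial1.arm_a.label, trial1.arm_b.label}
    labels2 = {trial2.arm_a.label, trial2.arm_b.label}
    common = labels1 & labels2
    if len(common) != 1:
        raise ValidationError(
            f"trials {trial1.trial_id!r} and {trial2.trial_id!r} must share exactly "
            f"one anchor arm label; shared: {sorted(common)} "
            f"(arms {sorted(labels1)} / {sorted(labels2)})"
        )
    return common.pop()


def _other_arm(trial: TwoArmTrial, label: str):
    return trial.arm_b if trial.arm_a.label == label else trial.arm_a


def default_reference_grid(
    trial1: TwoArmTrial,
    anchor_label: str,
    level: float = DEFAULT_LEVEL,
    step: float = 0.001,
) -> np.ndarray:
    """Grid spanning the Reference rate's Wald CI, endpoints included.

    Endpoints are the CI bounds rounded to 3 decimals (the precision at which
    they are reported), stepped by ``step``; for the case study this is the
    139-point grid 0.356, 0.357, ..., 0.494.
    """
    ref = _other_arm(trial1, anchor_label)
    ci = wald_rate_ci(ref, level=level)
    lo, hi = round(ci.lower, 3), round(ci.upper, 3)
    n_steps = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n_steps + 1)
    return np.round(grid, 9)


def sa1_direct_margin(
    anchor_placebo_trial: TwoArmTrial,
    preservation: float,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    anchor_label: str | None = None,
) -> EquivalenceMargin:
    """SA1: margin from the direct Anchor-vs-Placebo effect alone."""
    if anchor_label is None:
        anchor_arm, placebo_arm = anchor_placebo_trial.arm_a, anchor_placebo_trial.arm_b
    else:
        anchor_arm = anchor_placebo_trial.arm(anchor_label)
        placebo_arm = _other_arm(anchor_placebo_trial, anchor_label)
    eff = direct_ratio(
        anchor_arm, placebo_arm, level=level, z=z, trial_id=anchor_placebo_trial.trial_id
    )
    return derive_margin(eff, preservation)


def _sweep_points(
    trial1: TwoArmTrial,
    trial2: TwoArmTrial,
    margin: EquivalenceMargin,
    grid: Sequence[float],
    anchor_rate_for: callable,
    level: float,
    z: float | None,
    mode: str,
) -> list[SweepPoint]:
    anchor = _shared_anchor(trial1, trial2)
    a1 = trial1.arm(anchor)
    ref = _other_arm(trial1, anchor)
    t2_est = direct_ratio(
        trial2.arm(anchor), _other_arm(trial2, anchor), level=level, z=z,
        trial_id=trial2.trial_id,
    )
    points: list[SweepPoint] = []
    for p in grid:
        p = float(p)
        if not 0.0 < p < 1.0:
            raise ValidationError(f"candidate reference rate must be in (0,1), got {p}")
        pa = anchor_rate_for(p)
        if pa >= 1.0:
            warnings.warn(
                f"skipping grid point reference={p}: implied anchor rate {pa} >= 1",
                stacklevel=3,
            )
            continue
        t1_est = ratio_from_rates(
            pa, p, a1.n, ref.n, level=level, z=z,
            numerator=anchor, denominator=ref.label, rounding=mode,
        )
        ind = indirect_ratio(t1_est, t2_est, level=level, z=z)
        # A grid point where the indirect CI bound does not exceed 1 shows no
        # demonstrated effect: preservation is -inf there, not an error, so
        # extreme sweeps still plot.
        if ind.ci_lower > 1.0:
            pres = preservation_of(margin.upper, ind.ci_lower)
        else:
            pres = float("-inf")
        points.append(
            SweepPoint(
                reference_rate=p,
                anchor_rate=pa,
                assumed_difference=pa - p,
                indirect_ci_lower=ind.ci_lower,
                preservation=pres,
            )
        )
    return points


def sa2_sweep_reference(
    trial1: TwoArmTrial,
    trial2: TwoArmTrial,
    margin: EquivalenceMargin,
    grid: Sequence[float] | None = None,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    mode: str = "continuous",
) -> list[SweepPoint]:
    """SA2a: vary the assumed true Reference rate, Anchor fixed at its
    observed point estimate, and report the preservation the margin retains.

    Candidate rates feed the SE formula through expected responder counts
    (``mode='continuous'``; ``'integer'`` rounds to whole responders).
    """
    anchor = _shared_anchor(trial1, trial2)
    a_rate = trial1.arm(anchor).rate
    if grid is None:
        grid = default_reference_grid(trial1, anchor, level=level)
    return _sweep_points(
        trial1, trial2, margin, grid, lambda p: a_rate, level, z, mode
    )


def sa2_sweep_difference(
    trial1: TwoArmTrial,
    trial2: TwoArmTrial,
    margin: EquivalenceMargin,
    differences: Sequence[float] = DEFAULT_DIFFERENCES,
    grid: Sequence[float] | None = None,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    mode: str = "continuous",
) -> dict[float, list[SweepPoint]]:
    """SA2b: vary both the Reference rate (across its CI) and the fixed
    Anchor-minus-Reference difference; anchor rate = reference + difference."""
    anchor = _shared_anchor(trial1, trial2)
    if grid is None:
        grid = default_reference_grid(trial1, anchor, level=level)
    return {
        float(d): _sweep_points(
            trial1, trial2, margin, grid, lambda p, d=d: p + d, level, z, mode
        )
        for d in differences
    }


def min_preservation(points: Sequence[SweepPoint]) -> float:
    """Smallest preservation factor over a sweep."""
    if not points:
        raise ValidationError("empty sweep")
    return min(p.preservation for p in points)


def _simulate(
    trial1: TwoArmTrial,
    trial2: TwoArmTrial,
    margin: EquivalenceMargin,
    n_reps: int,
    seed: int,
    prior: str,
    level: float,
    z: float | None,
    draw_anchor: bool,
    f_grid: Sequence[float] | None,
) -> SimulationResult:
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    if seed is None:
        raise ValidationError("a seed is required; simulations never use global random state")
    if prior not in PRIORS:
        raise ValidationError(f"prior must be one of {sorted(PRIORS)}, got {prior!r}")
    a0, b0 = PRIORS[prior]
    zz = z_for_level(level, z)

    anchor = _shared_anchor(trial1, trial2)
    arm_a = trial1.arm(anchor)
    arm_r = _other_arm(trial1, anchor)
    t2 = direct_ratio(
        trial2.arm(anchor), _other_arm(trial2, anchor), level=level, z=z,
        trial_id=trial2.trial_id,
    )

    rng = np.random.default_rng(seed)
    # Reference arm: posterior draw of the true rate, then a binomial
    # resample of the observed rate at the trial's sample size.
    mu_r = rng.beta(a0 + arm_r.responders, b0 + arm_r.n - arm_r.responders, n_reps)
    x_r = rng.binomial(arm_r.n, mu_r)
    if draw_anchor:
        mu_a = rng.beta(a0 + arm_a.responders, b0 + arm_a.n - arm_a.responders, n_reps)
        x_a = rng.binomial(arm_a.n, mu_a)
    else:
        x_a = np.full(n_reps, arm_a.responders)

    valid = (x_r > 0) & (x_a > 0)
    xa, xr = x_a[valid].astype(float), x_r[valid].astype(float)
    se1 = np.sqrt(1.0 / xa + 1.0 / xr - 1.0 / arm_a.n - 1.0 / arm_r.n)
    log_t1 = np.log((xa / arm_a.n) / (xr / arm_r.n))
    log_ind = t2.log_ratio - log_t1
    ci_lower = np.exp(log_ind - zz * np.sqrt(se1**2 + t2.se_log**2))

    defined = ci_lower > 1.0
    pres = 1.0 - math.log(margin.upper) / np.log(ci_lower[defined])
    n_excluded = int(n_reps - pres.size)

    if f_grid is None:
        f_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    exceedance = {
        float(f): float((pres >= f).sum()) / n_reps for f in f_grid
    }
    return SimulationResult(
        n_reps=n_reps,
        seed=seed,
        preservation_draws=tuple(float(v) for v in pres),
        n_excluded=n_excluded,
        exceedance=exceedance,
    )


def sa2_simulate_reference(
    trial1: TwoArmTrial,
    trial2: TwoArmTrial,
    margin: EquivalenceMargin,
    n_reps: int,
    seed: int,
    prior: str = "uniform",
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    f_grid: Sequence[float] | None = None,
) -> SimulationResult:
    """SA2a Monte-Carlo: only the Reference arm is re-drawn per replicate.

    Per replicate: draw the true Reference rate from its Beta posterior under
    a non-informative prior, resample the observed rate binomially at the
    trial's n, recompute the indirect CI (anchor arm and the Anchor-vs-Placebo
    trial unchanged) and record the preservation the margin achieves.
    """
    return _simulate(
        trial1, trial2, margin, n_reps, seed, prior, level, z,
        draw_anchor=False, f_grid=f_grid,
    )


def sa2_simulate_both(
    trial1: TwoArmTrial,
    trial2: TwoArmTrial,
    margin: EquivalenceMargin,
    n_reps: int,
    seed: int,
    prior: str = "uniform",
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
    f_grid: Sequence[float] | None = None,
) -> SimulationResult:
    """SA2b Monte-Carlo: both Trial-1 arms are re-drawn from their
    (independent) posterior-predictive distributions per replicate."""
    return _simulate(
        trial1, trial2, margin, n_reps, seed, prior, level, z,
        draw_anchor=True, f_grid=f_grid,
    )


class SA3Result(NamedTuple):
    pooled: MetaResult
    indirect: RatioEstimate
    margin: EquivalenceMargin
    legacy_preservation: float | None


def sa3_pooled_indirect(
    trial1: TwoArmTrial,
    anchor_placebo_trials: Sequence[TwoArmTrial],
    preservation: float,
    legacy_margin: EquivalenceMargin | float | None = None,
    level: float = DEFAULT_LEVEL,
    z: float | None = None,
) -> SA3Result:
    """SA3: pool heterogeneous Anchor-vs-Placebo trials (DerSimonian–Laird
    random effects), then run the indirect comparison and margin derivation.

    If ``legacy_margin`` is given (a margin or its upper bound), the fraction
    of the pooled indirect effect that margin preserves is also returned.
    With a single Anchor-vs-Placebo trial this reduces exactly to the base
    analysis.
    """
    if len(anchor_placebo_trials) == 0:
        raise ValidationError("at least one Anchor-vs-Placebo trial is required")
    anchor = _shared_anchor(trial1, anchor_placebo_trials[0])
    for t in anchor_placebo_trials:
        if not t.has_arm(anchor):
            raise ValidationError(
                f"trial {t.trial_id!r} lacks the anchor arm {anchor!r}"
            )
    estimates = [
        direct_ratio(t.arm(anchor), _other_arm(t, anchor), level=level, z=z,
                     trial_id=t.trial_id)
        for t in anchor_placebo_trials
    ]
    pooled = pool_random_dl(estimates, level=level, z=z)
    t1_est = direct_ratio(
        trial1.arm(anchor), _other_arm(trial1, anchor), level=level, z=z,
        trial_id=trial1.trial_id,
    )
    ind = indirect_ratio(t1_est, pooled.as_estimate(), level=level, z=z)
    new_margin = derive_margin(ind, preservation)
    legacy_pres = None
    if legacy_margin is not None:
        upper = legacy_margin.upper if isinstance(legacy_margin, EquivalenceMargin) else float(legacy_margin)
        legacy_pres = preservation_of(upper, ind.ci_lower)
    return SA3Result(pooled=pooled, indirect=ind, margin=new_margin,
                     legacy_preservation=legacy_pres)
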