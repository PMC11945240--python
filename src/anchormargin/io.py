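"""File formats and report assembly.

Trial summaries travel as CSV (one row per arm: ``trial_id,arm,n,responders``)
or the JSON equivalent.  Report builders return pandas DataFrames shaped like
the published tables (per-trial ratios + indirect row; margin table per
preservation fraction) and can be serialized to CSV, JSON or markdown.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .effect_estimation import RatioEstimate
from .errors import ValidationError
from .margin_derivation import EquivalenceMargin, derive_margin_from_bound
from .trial_model import TwoArmTrial, make_arm

REQUIRED_COLUMNS = ("trial_id", "arm", "n", "responders")


def _trials_from_frame(df: pd.DataFrame, source: str) -> list[TwoArmTrial]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{source}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(map(str, df.columns))})"
        )
    trials = []
    for trial_id, group in df.groupby("trial_id", sort=False):
        if len(group) != 2:
            raise ValidationError(
                f"{source}: trial {trial_id!r} must have exactly 2 arms, found {len(group)}"
            )
        arms = [
            make_arm(str(row["arm"]), int(row["n"]), int(row["responders"]))
            for _, row in group.iterrows()
        ]
        trials.append(TwoArmTrial(trial_id=str(trial_id), arm_a=arms[0], arm_b=arms[1]))
    if not trials:
        raise ValidationError(f"{source}: no trials found")
    return trials


def read_trials_csv(path: str | Path) -> list[TwoArmTrial]:
    """Read two-arm trials from the CSV dialect (header required)."""
    df = pd.read_csv(path)
    return _trials_from_frame(df, str(path))


def read_trials_json(path: str | Path) -> list[TwoArmTrial]:
    """Read trials from JSON: a list of {trial_id, arm, n, responders} rows."""
    with open(path) as fh:
        rows = json.load(fh)
    return _trials_from_frame(pd.DataFrame(rows), str(path))


def read_trials(path: str | Path) -> list[TwoArmTrial]:
    """Dispatch on extension: .json -> JSON, anything else -> CSV."""
    if str(path).lower().endswith(".json"):
        return read_trials_json(path)
    return read_trials_csv(path)


def trials_to_frame(trials: Sequence[TwoArmTrial]) -> pd.DataFrame:
    rows = [
        {"trial_id": t.trial_id, "arm": a.label, "n": a.n, "responders": a.responders}
        for t in trials
        for a in t.arms
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_trials_csv(trials: Sequence[TwoArmTrial], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def classify_trials(
    trials: Sequence[TwoArmTrial],
) -> tuple[TwoArmTrial, list[TwoArmTrial], str]:
    """Identify the anchor label, the Reference trial and the Anchor-vs-Placebo
    trials in a set of two-arm trials.

    The anchor is the arm label present in every trial.  All trials whose
    other arm shares one label form the Anchor-vs-Placebo set; exactly one
    trial must have a distinct other arm (the Anchor-vs-Reference trial).
    """
    if len(trials) < 2:
        raise ValidationError("need at least two trials (Reference trial + anchor trial)")
    label_sets = [{t.arm_a.label, t.arm_b.label} for t in trials]
    common = set.intersection(*label_sets)
    if len(common) != 1:
        found = sorted({lab for s in label_sets for lab in s})
        raise ValidationError(
            "could not identify a unique anchor arm shared by all trials; "
            f"arm labels found: {', '.join(found)}"
        )
    anchor = common.pop()
    others: dict[str, list[TwoArmTrial]] = {}
    for t in trials:
        other = t.arm_b.label if t.arm_a.label == anchor else t.arm_a.label
        others.setdefault(other, []).append(t)
    singles = [lab for lab, ts in others.items() if len(ts) == 1]
    if len(others) != 2:
        raise ValidationError(
            f"expected exactly two non-anchor treatments (Reference and Placebo), "
            f"found: {', '.join(sorted(others))} (anchor: {anchor!r})"
        )
    if len(singles) == 2:
        # Two candidate Reference trials: take the conventional labels if present.
        for lab in singles:
            if lab.lower() == "reference":
                ref_label = lab
                break
        else:
            raise ValidationError(
                "ambiguous trial roles: each non-anchor treatment appears once; "
                f"label one arm 'Reference' (found: {', '.join(sorted(singles))})"
            )
    elif len(singles) == 1:
        ref_label = singles[0]
    else:
        raise ValidationError(
            "no unique Anchor-vs-Reference trial found; "
            f"non-anchor treatments: {', '.join(sorted(others))}"
        )
    reference_trial = others[ref_label][0]
    placebo_label = next(lab for lab in others if lab != ref_label)
    return reference_trial, others[placebo_label], anchor


def effects_table(
    direct_estimates: Sequence[RatioEstimate],
    indirect: RatioEstimate,
    labels: Sequence[str] | None = None,
    digits: int = 3,
) -> pd.DataFrame:
    """Per-trial ratios plus the indirect row (layout of the published
    treatment-ratio tables)."""
    labels = list(labels) if labels is not None else [
        e.provenance.removeprefix("direct:") for e in direct_estimates
    ]
    rows = []
    for lab, e in zip(labels, direct_estimates):
        rows.append(_effect_row(lab, e, digits))
    rows.append(_effect_row("Indirect comparison", indirect, digits))
    return pd.DataFrame(rows)


def _effect_row(label: str, e: RatioEstimate, digits: int) -> dict:
    return {
        "study": label,
        "comparison": e.comparison,
        "ratio": round(e.ratio, digits),
        "se_log": round(e.se_log, digits),
        "ci_lower": round(e.ci_lower, digits),
        "ci_upper": round(e.ci_upper, digits),
    }


def margin_table(
    effect: RatioEstimate,
    preservations: Sequence[float] = (0.40, 0.50, 0.60, 0.70),
    digits: int = 3,
) -> pd.DataFrame:
    """Margin per preservation fraction from one effect estimate's CI bound."""
    rows = []
    for f in preservations:
        m = derive_margin_from_bound(effect.ci_lower, f, level=effect.level)
        rows.append(
            {
                "preservation_pct": round(100 * f, 1),
                "ci_bound": round(effect.ci_lower, digits),
                "margin_lower": round(m.lower, digits),
                "margin_upper": round(m.upper, digits),
            }
        )
    return pd.DataFrame(rows)


def margin_to_dict(margin: EquivalenceMargin, digits: int = 3) -> dict:
    return {
        "lower": round(margin.lower, digits),
        "upper": round(margin.upper, digits),
        "preservation": margin.preservation,
        "source_bound": round(margin.source_bound, digits),
        "level": margin.level,
    }


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown table (no external dependencies)."""
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
    return "\n".join(lines) + "\n"
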