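import numpy as np
import pytest

from anchormargin import (
    ValidationError,
    default_reference_grid,
    derive_margin,
    min_preservation,
    preservation_of,
    sa1_direct_margin,
    sa2_simulate_both,
    sa2_simulate_reference,
    sa2_sweep_difference,
    sa2_sweep_reference,
    sa3_pooled_indirect,
)


# ---------------------------------------------------------------- SA1


def test_sa1_direct_margin_matches_published(trial2):
    m = sa1_direct_margin(trial2, 0.60)
    assert (round(m.lower, 3), round(m.upper, 3)) == (0.724, 1.381)


def test_sa1_full_preservation(trial2):
    m = sa1_direct_margin(trial2, 1.0)
    assert m.lower == m.upper == 1.0


def test_sa1_zero_preservation_is_inverse_of_ci_bound(trial2):
    m = sa1_direct_margin(trial2, 0.0)
    assert round(m.upper, 3) == 2.242
    assert m.lower == pytest.approx(1 / m.upper)


# ---------------------------------------------------------------- SA2 sweeps


def test_default_grid_is_139_points(trial1):
    grid = default_reference_grid(trial1, "Anchor")
    assert len(grid) == 139
    assert grid[0] == pytest.approx(0.356)
    assert grid[-1] == pytest.approx(0.494)


def test_sweep_round_trip_at_observed_rate(trial1, trial2, proposed_margin):
    """At the observed reference rate the margin was derived from these very
    data, so the sweep must return exactly the 60% preservation."""
    pts = sa2_sweep_reference(trial1, trial2, proposed_margin, grid=[0.425])
    assert pts[0].preservation == pytest.approx(0.60, abs=1e-12)


def test_sweep_preservation_at_published_thresholds(trial1, trial2, proposed_margin):
    pts = sa2_sweep_reference(trial1, trial2, proposed_margin, grid=[0.380])
    assert pts[0].preservation >= 0.50
    # reference at the CI lower bound with the observed 4.5-point difference
    by_diff = sa2_sweep_difference(
        trial1, trial2, proposed_margin, differences=[0.045], grid=[0.356]
    )
    assert by_diff[0.045][0].preservation == pytest.approx(0.571, abs=0.0015)


@pytest.mark.parametrize(
    "difference,expected_min_pct",
    [(0.045, 57.1), (0.060, 54.4), (0.075, 51.4), (0.090, 48.2)],
)
def test_sweep_minima_by_difference(trial1, trial2, proposed_margin, difference, expected_min_pct):
    by_diff = sa2_sweep_difference(trial1, trial2, proposed_margin, differences=[difference])
    assert 100 * min_preservation(by_diff[difference]) == pytest.approx(
        expected_min_pct, abs=0.15
    )


def test_integer_rounding_mode_matches_printed_minima(trial1, trial2, proposed_margin):
    by_diff = sa2_sweep_difference(trial1, trial2, proposed_margin, mode="integer")
    got = {d: round(100 * min_preservation(pts), 1) for d, pts in by_diff.items()}
    assert got == {0.045: 57.1, 0.060: 54.4, 0.075: 51.4, 0.090: 48.2}


def test_sweep_monotone_in_reference_rate(trial1, trial2, proposed_margin):
    """Larger reference rate -> smaller Trial-1 ratio -> larger indirect
    effect -> more preservation."""
    pts = sa2_sweep_reference(trial1, trial2, proposed_margin)
    pres = [p.preservation for p in pts]
    assert all(a < b for a, b in zip(pres, pres[1:]))


def test_sweep_minimum_at_lower_grid_endpoint(trial1, trial2, proposed_margin):
    by_diff = sa2_sweep_difference(trial1, trial2, proposed_margin)
    for pts in by_diff.values():
        assert min(pts, key=lambda p: p.preservation).reference_rate == pts[0].reference_rate


def test_sweep_difference_zero_reduces_to_trial2_effect(trial1, trial2, proposed_margin):
    """With no Anchor-Reference difference the Trial-1 ratio is 1 and the
    indirect effect is Trial 2's own (wider by Trial 1's SE)."""
    pts = sa2_sweep_difference(
        trial1, trial2, proposed_margin, differences=[0.0], grid=[0.470]
    )[0.0]
    assert pts[0].preservation == pytest.approx(
        preservation_of(proposed_margin.upper, pts[0].indirect_ci_lower)
    )
    assert pts[0].anchor_rate == pts[0].reference_rate


def test_sweep_rejects_zero_rate(trial1, trial2, proposed_margin):
    with pytest.raises(ValidationError):
        sa2_sweep_reference(trial1, trial2, proposed_margin, grid=[0.0])


def test_sweep_skips_impossible_anchor_rate(trial1, trial2, proposed_margin):
    with pytest.warns(UserWarning, match="anchor rate"):
        by_diff = sa2_sweep_difference(
            trial1, trial2, proposed_margin, differences=[0.7], grid=[0.25, 0.4]
        )
    assert len(by_diff[0.7]) == 1  # 0.4 + 0.7 >= 1 skipped


# ---------------------------------------------------------------- SA2 simulation


def test_simulation_is_bit_reproducible(trial1, trial2, proposed_margin):
    a = sa2_simulate_reference(trial1, trial2, proposed_margin, 500, seed=11)
    b = sa2_simulate_reference(trial1, trial2, proposed_margin, 500, seed=11)
    assert a.preservation_draws == b.preservation_draws
    assert a.exceedance == b.exceedance
    c = sa2_simulate_reference(trial1, trial2, proposed_margin, 500, seed=12)
    assert a.preservation_draws != c.preservation_draws


def test_exceedance_monotone_nonincreasing(trial1, trial2, proposed_margin):
    sim = sa2_simulate_both(trial1, trial2, proposed_margin, 2000, seed=5)
    probs = [sim.exceedance[f] for f in sorted(sim.exceedance)]
    assert all(a >= b for a, b in zip(probs, probs[1:]))


def test_exceedance_counts_exact(trial1, trial2, proposed_margin):
    sim = sa2_simulate_reference(trial1, trial2, proposed_margin, 777, seed=3)
    draws = np.array(sim.preservation_draws)
    for f in (0.3, 0.5, 0.6):
        assert sim.prob_at_least(f) == (draws >= f).sum() / 777


def test_single_replicate_is_step_function(trial1, trial2, proposed_margin):
    sim = sa2_simulate_reference(trial1, trial2, proposed_margin, 1, seed=2)
    assert set(sim.exceedance.values()) <= {0.0, 1.0}


def test_simulation_calibration_band(trial1, trial2, proposed_margin):
    """Exceedance at the margin's own 60% preservation sits near one half;
    a seed-robust band brackets the published Monte-Carlo values."""
    sim = sa2_simulate_reference(trial1, trial2, proposed_margin, 20_000, seed=19)
    assert 0.46 <= sim.prob_at_least(0.60) <= 0.54
    assert 0.79 <= sim.prob_at_least(0.50) <= 0.87
    both = sa2_simulate_both(trial1, trial2, proposed_margin, 20_000, seed=19)
    assert 0.46 <= both.prob_at_least(0.60) <= 0.54


def test_both_arm_simulation_varies_anchor(trial1, trial2, proposed_margin):
    """Re-drawing the anchor arm adds dispersion to the preservation draws
    (robust spread: the preservation distribution has a heavy lower tail)."""

    def iqr(sim):
        q25, q75 = np.percentile(sim.preservation_draws, [25, 75])
        return q75 - q25

    ref = sa2_simulate_reference(trial1, trial2, proposed_margin, 20_000, seed=7)
    both = sa2_simulate_both(trial1, trial2, proposed_margin, 20_000, seed=7)
    assert iqr(both) > iqr(ref)


def test_large_n_concentrates_to_deterministic_value(proposed_margin, trial2):
    """With huge arms the posterior and binomial noise vanish and preservation
    concentrates at the value implied by the observed rates."""
    from anchormargin import make_arm
    from anchormargin.trial_model import TwoArmTrial

    n = 2_000_000
    big = TwoArmTrial(
        "big",
        make_arm("Anchor", n, int(n * 0.47)),
        make_arm("Reference", n, int(n * 0.425)),
    )
    sim = sa2_simulate_both(big, trial2, proposed_margin, 300, seed=1)
    draws = np.array(sim.preservation_draws)
    assert np.std(draws) < 0.01


def test_simulation_requires_seed_and_valid_prior(trial1, trial2, proposed_margin):
    with pytest.raises(ValidationError, match="seed"):
        sa2_simulate_reference(trial1, trial2, proposed_margin, 10, seed=None)
    with pytest.raises(ValidationError, match="prior"):
        sa2_simulate_reference(trial1, trial2, proposed_margin, 10, seed=1, prior="flat")


# ---------------------------------------------------------------- SA3


def test_sa3_reproduces_published_values(trial1, trial2, trial3, proposed_margin):
    res = sa3_pooled_indirect(trial1, [trial2, trial3], 0.60, legacy_margin=proposed_margin)
    assert round(res.pooled.ratio, 3) == 3.382
    assert round(res.indirect.ratio, 3) == 3.059
    assert (round(res.margin.lower, 3), round(res.margin.upper, 3)) == (0.807, 1.240)
    assert round(res.legacy_preservation, 3) == 0.536


def test_sa3_single_trial_reduces_to_base_case(trial1, trial2, indirect):
    res = sa3_pooled_indirect(trial1, [trial2], 0.60)
    assert res.indirect.log_ratio == pytest.approx(indirect.log_ratio, rel=1e-14)
    assert res.indirect.se_log == pytest.approx(indirect.se_log, rel=1e-14)
    assert res.margin.upper == pytest.approx(derive_margin(indirect, 0.60).upper, rel=1e-14)


def test_sa3_requires_trials(trial1):
    with pytest.raises(ValidationError):
        sa3_pooled_indirect(trial1, [], 0.6)
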