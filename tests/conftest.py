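import pytest

from anchormargin import (
    case_study_fixture,
    derive_margin,
    direct_ratio,
    indirect_ratio,
)


@pytest.fixture(scope="session")
def trials():
    """The three published case-study trials."""
    return case_study_fixture()


@pytest.fixture(scope="session")
def trial1(trials):
    return trials[0]


@pytest.fixture(scope="session")
def trial2(trials):
    return trials[1]


@pytest.fixture(scope="session")
def trial3(trials):
    return trials[2]


@pytest.fixture(scope="session")
def estimates(trials):
    """Direct Anchor-vs-X estimates for Trials 1, 2, 3."""
    return tuple(
        direct_ratio(t.arm_a, t.arm_b, trial_id=t.trial_id) for t in trials
    )


@pytest.fixture(scope="session")
def indirect(estimates):
    """The base-case indirect Reference-vs-Placebo estimate."""
    return indirect_ratio(estimates[0], estimates[1])


@pytest.fixture(scope="session")
def proposed_margin(indirect):
    """The 60%-preservation margin of the base case, (0.779, 1.283)."""
    return derive_margin(indirect, 0.60)


@pytest.fixture(scope="session")
def trials_csv(tmp_path_factory, trials):
    """Case-study trials written to the CSV dialect."""
    from anchormargin.io import write_trials_csv

    path = tmp_path_factory.mktemp("data") / "trials.csv"
    write_trials_csv(trials, path)
    return path


@pytest.fixture(scope="session")
def trials12_csv(tmp_path_factory, trials):
    from anchormargin.io import write_trials_csv

    path = tmp_path_factory.mktemp("data") / "trials12.csv"
    write_trials_csv(trials[:2], path)
    return path
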