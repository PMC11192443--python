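import numpy as np
import pytest

from natisc.isc import TimeCourseSet
from natisc.synthdata import ConditionSpec, SimDesign, make_design, simulate_timecourses


@pytest.fixture(scope="session")
def small_design():
    return make_design("small", seed=7)


@pytest.fixture(scope="session")
def paper_design():
    return make_design("paper", seed=7)


@pytest.fixture(scope="session")
def paper_isc(paper_design):
    """ISC table from one paper-template simulation (shared across tests)."""
    from natisc.isc import compute_isc_table, preprocess

    return compute_isc_table(preprocess(simulate_timecourses(paper_design)))


def single_condition_design(
    a: float,
    n: int,
    T: int,
    seed: int,
    n_frois: int = 1,
    condition_type: str = "+M/-L",
    smoothing: float = 3.0,
) -> SimDesign:
    """One condition, arbitrary tracking strength — the basic test harness.

    T is the post-fixation sample count at TR = 2 s (preprocess then
    trims 3 more).
    """
    cond = ConditionSpec("clip", condition_type, T * 2.0 + 32.0, "visual", n)
    tracking = {"+M/-L": 0.0, "+M/+L": 0.0, "-M/-L": 0.0}
    tracking[condition_type] = a
    return SimDesign(
        conditions=[cond],
        tracking_strength=tracking,
        frois=tuple(f"froi{i}" for i in range(n_frois)),
        participation={"clip": tuple(f"P{i:03d}" for i in range(n))},
        smoothing_fwhm_tr=smoothing,
        seed=seed,
    )


def noise_tcs(seed: int, n: int = 10, T: int = 150, n_frois: int = 2) -> TimeCourseSet:
    """Plain white-noise TimeCourseSet (no trim pending, no smoothing)."""
    rng = np.random.default_rng(seed)
    data = {
        (f"P{i:02d}", "clip", f"f{j}"): rng.standard_normal(T)
        for i in range(n)
        for j in range(n_frois)
    }
    return TimeCourseSet(data=data, onset_exclusion_s=0.0, condition_types={"clip": "+M/-L"})
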