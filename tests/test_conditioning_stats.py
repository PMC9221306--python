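"""Learning index and randomization-test behaviour against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccsp.conditioning_stats import (
    StatsError,
    TimecourseConfig,
    exact_randomization,
    learning_index,
    li_timecourse,
    randomization_li_contrast,
    randomization_two_sample,
    retention_contrast,
)
from ccsp.ethogram_io import aggregate_groups
from ccsp.synthetic_data import SynthConfig, builtin_profiles, generate_ethograms

# ---------------------------------------------------------------- oracles


def brute_force_two_sample_p(x, y):
    """Exact two-sided randomization p via python enumeration (independent
    of the package's vectorized path)."""
    x, y = list(x), list(y)
    pooled = x + y
    t_obs = abs(np.mean(x) - np.mean(y))
    idx = range(len(pooled))
    b = total = 0
    for combo in itertools.combinations(idx, len(x)):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in combo]
        total += 1
        if abs(np.mean(xs) - np.mean(ys)) >= t_obs - 1e-12:
            b += 1
    return b / total


def brute_force_li_contrast_p(na_a, tr_a, na_b, tr_b):
    """Exhaustive stratified enumeration for T = LI_A - LI_B."""
    def li(na, tr):
        return 100.0 * (1.0 - np.mean(tr) / np.mean(na))

    t_obs = abs(li(na_a, tr_a) - li(na_b, tr_b))
    pooled_na = list(na_a) + list(na_b)
    pooled_tr = list(tr_a) + list(tr_b)
    b = total = 0
    for combo_na in itertools.combinations(range(len(pooled_na)), len(na_a)):
        sa_na = [pooled_na[i] for i in combo_na]
        sb_na = [pooled_na[i] for i in range(len(pooled_na)) if i not in combo_na]
        if np.mean(sa_na) == 0 or np.mean(sb_na) == 0:
            continue
        for combo_tr in itertools.combinations(range(len(pooled_tr)), len(tr_a)):
            sa_tr = [pooled_tr[i] for i in combo_tr]
            sb_tr = [pooled_tr[i] for i in range(len(pooled_tr)) if i not in combo_tr]
            total += 1
            if abs(li(sa_na, sa_tr) - li(sb_na, sb_tr)) >= t_obs - 1e-12:
                b += 1
    return b / total


# ---------------------------------------------------------- learning index


@pytest.mark.parametrize(
    "na,tr,expected",
    [
        ([40, 60], [40, 60], 0.0),       # identical means -> no learning
        ([40, 60], [0, 0], 100.0),       # complete suppression
        ([50, 70], [10, 20], 75.0),      # (1 - 15/60) * 100
    ],
)
def test_learning_index_formula(na, tr, expected):
    assert learning_index(na, tr).li == pytest.approx(expected)


def test_learning_index_undefined_when_naive_mean_zero():
    with pytest.raises(StatsError, match="undefined"):
        learning_index([0.0, 0.0], [10.0, 20.0])


@given(
    st.floats(10, 90),
    st.lists(st.floats(0, 100), min_size=2, max_size=6),
    st.floats(0.5, 20),
)
def test_li_strictly_decreases_in_trained_mean(na_mean, tr, delta):
    na = [na_mean, na_mean]
    li_low = learning_index(na, tr).li
    li_high = learning_index(na, [v + delta for v in tr]).li
    assert li_high < li_low


# ----------------------------------------------------- two-sample testing


def test_identical_constant_samples_alpha_one():
    r = randomization_two_sample([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], seed=1)
    assert r.alpha_r == 1.0


def test_small_sample_exhaustive_exact_value():
    # C(4,2)=6 assignments; |T|=1 for exactly the 2 label-preserving splits
    r = randomization_two_sample([0.0, 0.0], [1.0, 1.0], seed=1)
    assert r.exhaustive
    assert r.alpha_r == pytest.approx(2 / 6)


def test_sampled_matches_exhaustive_three_vs_three(rng):
    x = rng.normal(10, 3, 3)
    y = rng.normal(13, 3, 3)
    exact = exact_randomization(x, y)
    sampled = randomization_two_sample(
        x, y, n_perm=10_000, seed=7, exhaustive_threshold=0
    )
    assert not sampled.exhaustive
    assert abs(sampled.alpha_r - exact) <= 0.02


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1.0], [2.0], 1.0),                # symmetry: both assignments |T|=1
        ([1.0, 2.0], [10.0, 11.0], 2 / 6),  # brute force over 6 assignments
    ],
)
def test_exact_randomization_small_cases(x, y, expected):
    assert exact_randomization(x, y) == pytest.approx(expected)


def test_exact_randomization_matches_brute_force_oracle(rng):
    for _ in range(20):
        n, m = rng.integers(2, 6, 2)
        x = np.round(rng.normal(10, 4, n), 1)
        y = np.round(rng.normal(12, 4, m), 1)
        assert exact_randomization(x, y) == pytest.approx(
            brute_force_two_sample_p(x, y), abs=1e-12
        )


def test_exact_randomization_refuses_large_instances():
    with pytest.raises(StatsError, match="sampled"):
        exact_randomization(np.arange(15.0), np.arange(15.0))


def test_sampled_converges_to_exact():
    x = [3.1, 4.5, 2.2, 5.0]
    y = [5.5, 6.1, 4.9, 7.2]
    exact = exact_randomization(x, y)
    r = randomization_two_sample(
        x, y, n_perm=100_000, seed=11, exhaustive_threshold=0
    )
    band = 3 * math.sqrt(exact * (1 - exact) / 100_000) + 2 / 100_000
    assert abs(r.alpha_r - exact) <= band


def test_two_sidedness_and_shift_invariance():
    x = [10.0, 14.0, 9.0, 11.0]
    y = [15.0, 17.0, 16.0, 13.0]
    assert exact_randomization(x, y) == exact_randomization(y, x)
    shifted = exact_randomization([v + 500 for v in x], [v + 500 for v in y])
    assert shifted == pytest.approx(exact_randomization(x, y), abs=1e-12)
    # sampled path with identical seed is also shift invariant
    a = randomization_two_sample(x, y, n_perm=2000, seed=3, exhaustive_threshold=0)
    b = randomization_two_sample(
        [v + 500 for v in x], [v + 500 for v in y],
        n_perm=2000, seed=3, exhaustive_threshold=0,
    )
    assert a.alpha_r == b.alpha_r


def test_same_seed_bit_reproducible():
    x = list(np.linspace(0, 50, 8))
    y = list(np.linspace(10, 60, 8))
    r1 = randomization_two_sample(x, y, n_perm=5000, seed=42, exhaustive_threshold=0)
    r2 = randomization_two_sample(x, y, n_perm=5000, seed=42, exhaustive_threshold=0)
    assert r1.alpha_r == r2.alpha_r


def test_invalid_inputs():
    with pytest.raises(StatsError):
        randomization_two_sample([1.0], [2.0, 3.0])
    with pytest.raises(StatsError):
        randomization_two_sample([1.0, 2.0], [2.0, 3.0], n_perm=0)


# ------------------------------------------------------------ LI contrasts


def test_li_contrast_identical_groups_alpha_one():
    na = [40.0, 55.0, 60.0]
    tr = [10.0, 20.0, 15.0]
    r = randomization_li_contrast((na, tr), (na, tr), n_perm=2000, seed=1)
    assert r.statistic_observed == 0.0
    assert r.alpha_r == 1.0


def test_li_contrast_matches_stratified_enumeration_oracle(rng):
    for seed in range(5):
        na_a = np.round(rng.uniform(30, 70, 2), 1)
        tr_a = np.round(rng.uniform(5, 30, 2), 1)
        na_b = np.round(rng.uniform(30, 70, 2), 1)
        tr_b = np.round(rng.uniform(30, 70, 2), 1)
        exact = brute_force_li_contrast_p(na_a, tr_a, na_b, tr_b)
        r = randomization_li_contrast(
            (na_a, tr_a), (na_b, tr_b), n_perm=20_000, seed=seed
        )
        assert abs(r.alpha_r - exact) <= 0.02


def test_retention_contrast_identical_alpha_one():
    na = [40.0, 55.0, 60.0, 45.0]
    tr = [10.0, 20.0, 15.0, 25.0]
    r = retention_contrast((na, tr), (na, tr), n_perm=2000, seed=4)
    assert r.alpha_r == 1.0


def test_retention_contrast_matches_enumeration_oracle(rng):
    # retention permutes the occasion label within condition strata: the
    # same enumeration as the strain contrast with groups = occasions
    na_imm = np.round(rng.uniform(40, 60, 2), 1)
    tr_imm = np.round(rng.uniform(5, 25, 2), 1)
    na_del = np.round(rng.uniform(40, 60, 2), 1)
    tr_del = np.round(rng.uniform(35, 60, 2), 1)
    exact = brute_force_li_contrast_p(na_del, tr_del, na_imm, tr_imm)
    r = retention_contrast((na_imm, tr_imm), (na_del, tr_del), n_perm=20_000, seed=2)
    assert abs(r.alpha_r - exact) <= 0.02


def test_li_contrast_redraws_zero_naive_permutations():
    # four zero CIs among eight naive males: ~3% of stratified permutations
    # put them all in one group (naive mean 0) and must be redrawn
    na_a = [0.0, 0.0, 0.0, 40.0]
    tr_a = [10.0, 12.0, 9.0, 11.0]
    na_b = [0.0, 60.0, 55.0, 45.0]
    tr_b = [20.0, 25.0, 22.0, 18.0]
    r = randomization_li_contrast((na_a, tr_a), (na_b, tr_b), n_perm=2000, seed=9)
    assert r.n_redrawn > 0
    assert 0 < r.alpha_r <= 1


# --------------------------------------------------------------- timecourse


@pytest.fixture(scope="module")
def timecourse_df():
    obs = generate_ethograms(SynthConfig(profiles=builtin_profiles(), seed=11))
    groups = aggregate_groups(obs)
    return li_timecourse(
        groups, ["control"], TimecourseConfig(n_perm=1000, seed=13)
    )


def test_timecourse_layout(timecourse_df):
    df = timecourse_df
    assert len(df) == 9  # 3 strains x 3 timepoints
    assert set(df["strain"]) == {"control", "cbs_like", "cse_like"}
    assert (df["n_na"] == 20).all() and (df["n_tr"] == 20).all()


def test_timecourse_control_strain_learns(timecourse_df):
    ctrl = timecourse_df[timecourse_df["strain"] == "control"]
    assert (ctrl["alpha_within"] < 0.05).all()
    assert (ctrl["li"] > 40).all()
    assert not ctrl["flags"].str.contains("#").any()


def test_timecourse_cbs_like_flat_and_flagged(timecourse_df):
    cbs = timecourse_df[timecourse_df["strain"] == "cbs_like"]
    assert (cbs["li"].abs() < 30).all()
    assert cbs["flags"].str.contains(r"\*").all()


def test_timecourse_cse_like_loses_retention(timecourse_df):
    cse = timecourse_df[timecourse_df["strain"] == "cse_like"].set_index("timepoint")
    assert cse.loc["0", "alpha_within"] < 0.05
    assert "#" in cse.loc["8", "flags"]
    assert "#" not in cse.loc["2", "flags"]


def test_timecourse_empty_input():
    assert li_timecourse([], ["control"]).empty


def test_timecourse_not_testable_row():
    obs = generate_ethograms(
        SynthConfig(profiles=builtin_profiles(("0",)), timepoints=("0",), seed=3)
    )
    groups = [g for g in aggregate_groups(obs) if not
              (g.strain == "cse_like" and g.condition == "trained")]
    df = li_timecourse(groups, ["control"], TimecourseConfig(n_perm=200, seed=1))
    row = df[df["strain"] == "cse_like"].iloc[0]
    assert row["status"] == "not_testable"
    assert np.isnan(row["li"])
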