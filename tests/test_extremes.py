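"""Peak/trough detection, removal, and the random-removal null."""

import numpy as np
import pytest

import natisc as n
from natisc.extremes import (
    detect_extremes,
    matched_trough_indices,
    peak_vs_trough_test,
    random_removal_null,
    removed_isc,
    removed_mean_isc,
    threshold_indices,
)
from natisc.isc import TimeCourseSet, compute_isc_table, preprocess

from conftest import noise_tcs


def brute_force_removed_isc(tcs, condition, indices):
    """Oracle: delete indices by list comprehension, correlate by formula."""
    out = {}
    frois = tcs.frois(condition)
    for f in frois:
        ps, X = tcs.matrix(condition, f)
        kept = [t for t in range(X.shape[1]) if t not in set(indices)]
        Xk = X[:, kept]
        for i, p in enumerate(ps):
            others = np.mean([Xk[j] for j in range(len(ps)) if j != i], axis=0)
            x, y = Xk[i], others
            r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            out[(p, f)] = r
    return out


class TestDetect:
    def test_threshold_rule_on_known_series(self):
        z = np.array([0.2, 1.5, -0.3, 1.01, -1.2])
        np.testing.assert_array_equal(threshold_indices(z, "peak"), [1, 3])
        np.testing.assert_array_equal(threshold_indices(z, "trough"), [4])

    def test_infinite_threshold_gives_empty_set(self):
        tcs = noise_tcs(0)
        assert len(detect_extremes(tcs, "clip", "peak", np.inf).indices) == 0

    def test_polarity_symmetry(self):
        tcs = noise_tcs(1)
        flipped = tcs.copy()
        for k in flipped.data:
            flipped.data[k] = -flipped.data[k]
        peaks = detect_extremes(tcs, "clip", "peak").indices
        troughs = detect_extremes(flipped, "clip", "trough").indices
        np.testing.assert_array_equal(peaks, troughs)

    def test_constant_group_series_rejected(self):
        tcs = TimeCourseSet(
            data={("a", "c", "f"): np.ones(30), ("b", "c", "f"): -np.ones(30)},
            onset_exclusion_s=0.0, condition_types={"c": "+M/-L"},
        )
        with pytest.raises(ValueError, match="constant"):
            detect_extremes(tcs, "c", "peak")

    def test_absent_condition_rejected(self):
        with pytest.raises(KeyError):
            detect_extremes(noise_tcs(2), "nope", "peak")


class TestRemovedIsc:
    def test_empty_removal_is_identity(self):
        tcs = noise_tcs(3)
        a = removed_isc(tcs, "clip", [])
        b = compute_isc_table(tcs)
        np.testing.assert_allclose(a["r"], b["r"], atol=1e-14)

    def test_runs_at_three_remaining_samples(self):
        tcs = noise_tcs(4, T=20)
        table = removed_isc(tcs, "clip", list(range(17)))
        assert np.isfinite(table["r"]).all()

    def test_removal_below_three_samples_rejected(self):
        tcs = noise_tcs(5, T=20)
        with pytest.raises(ValueError, match="3 samples"):
            removed_isc(tcs, "clip", list(range(18)))

    def test_hand_worked_case_matches_manual_recomputation(self):
        X = np.array(
            [[1.0, 4.0, 2.0, 6.0, 3.0, 5.0],
             [2.0, 5.0, 1.0, 7.0, 4.0, 6.0],
             [0.0, 3.0, 3.0, 5.0, 1.0, 4.0]]
        )
        tcs = TimeCourseSet(
            data={(f"P{i}", "c", "f"): X[i] for i in range(3)},
            onset_exclusion_s=0.0, condition_types={"c": "+M/-L"},
        )
        got = removed_isc(tcs, "c", [1, 3])
        oracle = brute_force_removed_isc(tcs, "c", [1, 3])
        for _, row in got.iterrows():
            assert row["r"] == pytest.approx(oracle[(row["participant"], row["froi"])], abs=1e-12)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            nn, T = rng.integers(2, 6), rng.integers(8, 20)
            X = rng.standard_normal((nn, T))
            m = rng.integers(0, T - 4)
            idx = rng.choice(T, size=m, replace=False)
            tcs = TimeCourseSet(
                data={(f"P{i}", "c", "f"): X[i] for i in range(nn)},
                onset_exclusion_s=0.0, condition_types={"c": "+M/-L"},
            )
            got = removed_isc(tcs, "c", idx)
            oracle = brute_force_removed_isc(tcs, "c", idx)
            for _, row in got.iterrows():
                assert row["r"] == pytest.approx(
                    oracle[(row["participant"], row["froi"])], abs=1e-12
                )


class TestNull:
    def test_zero_removal_null_is_degenerate_and_p_is_one(self):
        tcs = noise_tcs(6, n=5, T=40)
        null = random_removal_null(tcs, "clip", m=0, n_iter=50, seed=1)
        assert np.ptp(null.values) == 0
        assert null.p_value(null.values[0]) == 1.0

    def test_same_seed_reproduces_values(self):
        tcs = noise_tcs(7, n=5, T=60)
        a = random_removal_null(tcs, "clip", m=5, n_iter=100, seed=9)
        b = random_removal_null(tcs, "clip", m=5, n_iter=100, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_m_rejected(self):
        tcs = noise_tcs(8, T=30)
        with pytest.raises(ValueError):
            random_removal_null(tcs, "clip", m=28, n_iter=10, seed=0)

    def test_p_uniform_when_observed_is_an_independent_random_draw(self):
        # The calibration the null does satisfy: comparing one random
        # removal (from an independent stream) against the null is
        # uniform by exchangeability.
        rng = np.random.default_rng(123)
        ps = []
        for rep in range(60):
            tcs = noise_tcs(1000 + rep, n=6, T=60, n_frois=1)
            m = 6
            null = random_removal_null(tcs, "clip", m, n_iter=99, seed=rep)
            obs = removed_mean_isc(tcs, "clip", rng.choice(60, size=m, replace=False))
            ps.append(null.p_value(obs))
        ps = np.asarray(ps)
        assert 0.2 < ps.mean() < 0.8
        assert np.mean(ps <= 0.2) < 0.45

    def test_null_spread_grows_with_removal_count(self):
        # Removing more time points leaves shorter series, so the
        # resampled mean ISC varies more from draw to draw.
        from conftest import single_condition_design

        spreads = []
        for seed in range(5):
            d = single_condition_design(a=0.4, n=10, T=120, seed=seed)
            pre = preprocess(n.simulate_timecourses(d))
            small = random_removal_null(pre, "clip", m=5, n_iter=80, seed=seed)
            big = random_removal_null(pre, "clip", m=80, n_iter=80, seed=seed)
            spreads.append(big.values.std() - small.values.std())
        assert np.mean(spreads) > 0


class TestPeakVsTrough:
    def test_identical_tables_give_t_zero_p_one(self):
        tab = compute_isc_table(noise_tcs(9))
        t, df, p = peak_vs_trough_test(tab, tab)
        assert (t, p) == (0.0, 1.0)
        assert df == 2 * len(tab) - 2

    def test_pooled_df_matches_group_sizes(self):
        a = compute_isc_table(noise_tcs(10, n=17, n_frois=2))
        b = compute_isc_table(noise_tcs(11, n=17, n_frois=2))
        _, df, _ = peak_vs_trough_test(a, b)
        assert df == 2 * 17 * 2 - 2

    def test_matched_trough_count_equals_peak_count(self):
        tcs, _ = n.simulate_peaked_timecourses(seed=3)
        pre = preprocess(tcs)
        m = len(detect_extremes(pre, "BurstClip", "peak").indices)
        assert len(matched_trough_indices(pre, "BurstClip", m)) == m

    def test_burst_data_peak_removal_hurts_more_than_trough(self):
        tcs, _ = n.simulate_peaked_timecourses(seed=21)
        pre = preprocess(tcs)
        peaks = detect_extremes(pre, "BurstClip", "peak").indices
        troughs = matched_trough_indices(pre, "BurstClip", len(peaks))
        assert removed_mean_isc(pre, "BurstClip", peaks) < removed_mean_isc(
            pre, "BurstClip", troughs
        )

    def test_suite_applies_fdr_across_conditions(self):
        tcs = noise_tcs(12, n=6, T=100)
        extra = noise_tcs(13, n=6, T=80)
        merged = dict(tcs.data)
        merged.update({(p, "c2", f): x for (p, _, f), x in extra.data.items()})
        both = TimeCourseSet(
            data=merged, onset_exclusion_s=0.0,
            condition_types={"clip": "+M/-L", "c2": "+M/-L"},
        )
        out = n.peak_vs_trough_suite(both, ["clip", "c2"])
        assert len(out) == 2
        assert (out["p_fdr"] >= out["p"] - 1e-15).all()
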