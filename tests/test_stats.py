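"""Mann-Whitney, BH adjustment, group comparisons and consistency calls."""

import numpy as np
import pandas as pd
import pytest

from genecentric import stats
from genecentric import synthetic as syn


class TestMannWhitney:
    def test_separated_triples_exact(self):
        u, p = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)   # 2 of C(6,3)=20 labelings

    def test_identical_groups_p_one(self):
        _, p = stats.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_singletons_p_one(self):
        _, p = stats.mann_whitney([5], [7])
        assert p == pytest.approx(1.0)

    def test_u_is_minimum_of_both_orientations(self):
        u_ab, _ = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        u_ba, _ = stats.mann_whitney([4, 5, 6], [1, 2, 3])
        assert u_ab == u_ba == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney([], [1, 2])

    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (1, 3), (2, 2), (2, 4),
                                         (3, 3), (3, 5), (4, 4), (2, 6)])
    def test_exact_p_matches_brute_force_enumeration(self, n_a, n_b, rng):
        for _ in range(5):
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b) + rng.normal()
            _, p = stats.mann_whitney(a, b)
            oracle = stats.mann_whitney_exact_oracle(a, b)
            assert p == pytest.approx(oracle, abs=1e-12)

    def test_large_samples_use_tie_corrected_approximation(self, rng):
        a = np.round(rng.normal(size=40), 1)   # induces ties
        b = np.round(rng.normal(size=40), 1)
        u, p = stats.mann_whitney(a, b)
        assert 0 <= p <= 1 and 0 <= u <= 40 * 40 / 2


class TestBhAdjust:
    def test_hand_computed_examples(self):
        assert stats.bh_adjust([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert stats.bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])

    def test_single_p_unchanged(self):
        assert stats.bh_adjust([0.123]) == pytest.approx([0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            stats.bh_adjust([-0.1])

    def test_step_up_definition_on_random_vectors(self, rng):
        # independent oracle: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1
        for _ in range(200):
            m = int(rng.integers(1, 20))
            p = rng.random(m)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert stats.bh_adjust(p) == pytest.approx(expected)

    def test_monotone_and_bounded(self, rng):
        p = rng.random(50)
        q = stats.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        # order preserved
        assert (np.argsort(p) == np.argsort(q, kind="stable")).all() or \
            np.allclose(np.sort(q)[np.argsort(np.argsort(p))], q)


def _long_table(n_features, n_cohorts, n_per_group, rng, shift=None):
    cols, data = [], {}
    samples = []
    for c in range(n_cohorts):
        for role, tag in (("control", "ctrl"), ("disease", "dis")):
            for i in range(n_per_group):
                sid = f"c{c}_{tag}{i}"
                cols.append(sid)
                samples.append((sid, f"c{c}", role, role, 10_000))
                vals = rng.lognormal(0, 1, size=n_features)
                if shift is not None and role == "disease":
                    vals = vals * shift
                data[sid] = vals
    table = pd.DataFrame(data, index=[f"f{i}" for i in range(n_features)])
    meta = pd.DataFrame(samples, columns=["sample_id", "cohort", "role",
                                          "group", "library_size"])
    return table, meta


class TestCompareGroups:
    def test_one_result_per_feature_cohort(self, rng):
        table, meta = _long_table(10, 3, 5, rng)
        res = stats.compare_groups(table, meta)
        assert len(res) == 30
        assert res.groupby("cohort").size().eq(10).all()

    def test_bh_batches_are_per_cohort(self, rng):
        table, meta = _long_table(10, 2, 5, rng)
        res = stats.compare_groups(table, meta)
        for _, sub in res.groupby("cohort"):
            assert sub["q"].to_numpy() == pytest.approx(
                stats.bh_adjust(sub["p_raw"].to_numpy()))

    def test_fold_change_flags(self):
        table = pd.DataFrame(
            {"s1": [0, 0], "s2": [0, 0], "s3": [0, 1], "s4": [0, 3]},
            index=["zero", "gain"])
        meta = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3", "s4"],
            "cohort": "c", "role": ["control", "control",
                                    "disease", "disease"],
            "group": "g", "library_size": 1})
        res = stats.compare_groups(table, meta).set_index("feature")
        assert res.loc["zero", "direction"] == "flat"
        assert np.isnan(res.loc["zero", "fold_change"])
        assert res.loc["gain", "direction"] == "up"
        assert np.isinf(res.loc["gain", "fold_change"])

    def test_cohort_without_two_roles_rejected(self, rng):
        table, meta = _long_table(3, 1, 4, rng)
        broken = meta.assign(role="control")
        with pytest.raises(ValueError):
            stats.compare_groups(table, broken)

    def test_strong_shift_detected(self, rng):
        table, meta = _long_table(5, 1, 50, rng, shift=4.0)
        res = stats.compare_groups(table, meta)
        assert (res["q"] < 0.05).all()
        assert (res["direction"] == "up").all()


class TestConsistency:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["feature", "cohort", "direction", "q"]) \
            .assign(p_raw=lambda d: d["q"], median_control=1.0,
                    median_disease=1.0, fold_change=1.0, u_statistic=0.0)

    def test_consistent_significant(self):
        res = self._results([("f", "c1", "down", 0.01),
                             ("f", "c2", "down", 0.2),
                             ("f", "c3", "down", 0.03)])
        call = stats.cross_cohort_consistency(res).iloc[0]
        assert call["verdict"] == "consistent-significant"
        assert call["n_significant"] == 2

    def test_mixed_directions_inconsistent(self):
        res = self._results([("f", "c1", "down", 0.01),
                             ("f", "c2", "up", 0.01),
                             ("f", "c3", "down", 0.01)])
        assert stats.cross_cohort_consistency(res).iloc[0]["verdict"] == \
            "inconsistent"

    def test_single_significant_cohort_is_trend_only(self):
        res = self._results([("f", "c1", "down", 0.01),
                             ("f", "c2", "down", 0.2),
                             ("f", "c3", "down", 0.2)])
        assert stats.cross_cohort_consistency(res).iloc[0]["verdict"] == \
            "trend-only"

    def test_exempt_cohort_not_counted(self):
        res = self._results([("f", "c1", "down", 0.01),
                             ("f", "c2", "down", 0.01),
                             ("f", "c3", "down", 0.2)])
        call = stats.cross_cohort_consistency(
            res, exempt_cohorts=["c2"]).iloc[0]
        assert call["n_significant"] == 1
        assert call["verdict"] == "trend-only"

    def test_feature_in_single_cohort_skipped_with_warning(self):
        res = self._results([("f", "c1", "down", 0.01)])
        with pytest.warns(UserWarning):
            calls = stats.cross_cohort_consistency(res)
        assert calls.empty


class TestUscgControl:
    def test_null_uscgs_pass(self, rng):
        table, meta = _long_table(5, 2, 20, rng)
        results, passed = stats.uscg_control(table, meta,
                                             [f"f{i}" for i in range(5)])
        assert len(results) == 10
        # under the null a false BH rejection is possible but unlikely here
        assert passed == bool((results["q"] >= 0.05).all())

    def test_shifted_uscg_fails_control(self, rng):
        table, meta = _long_table(5, 1, 50, rng, shift=5.0)
        _, passed = stats.uscg_control(table, meta,
                                       [f"f{i}" for i in range(5)])
        assert not passed

    def test_empty_uscg_set_rejected(self, rng):
        table, meta = _long_table(3, 1, 5, rng)
        with pytest.raises(ValueError):
            stats.uscg_control(table, meta, ["absent1", "absent2"])
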