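"""Clustering engine: binarization, likelihood, EM, elbow, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ohcengage as oe
from ohcengage.mixture import (
    DataError,
    EngagementSeries,
    MEASURES,
    MarkovChainMixture,
    _estep_core,
    _emissions_lin,
    _forward_all,
)

from conftest import enumeration_loglik, match_labels


def _series(counts_by_day, horizon=5, user="u1"):
    """Build an EngagementSeries from {day: {measure: count}}."""
    df = pd.DataFrame(
        0, index=pd.RangeIndex(1, horizon + 1, name="day_index"), columns=list(MEASURES)
    )
    for day, meas in counts_by_day.items():
        for m, v in meas.items():
            df.loc[day, m] = v
    return EngagementSeries(user_id=user, counts=df, horizon_days=horizon)


def _random_component(rng):
    A = np.zeros((3, 3))
    A[:2] = rng.dirichlet(np.ones(3), size=2)
    A[2] = (0, 0, 1)
    b_high = rng.uniform(0.3, 1.0)
    b_low = rng.uniform(0.0, b_high)
    return A, np.array([b_high, b_low, 0.0])


class TestBinarize:
    def test_all_zero_day_not_engaged(self):
        seq = oe.binarize(_series({}))
        assert not seq.engaged.any()

    def test_single_click_flags_day(self):
        seq = oe.binarize(_series({3: {"clicks": 1}}))
        assert seq.engaged[2] and seq.engaged.sum() == 1

    def test_negative_count_names_user_and_day(self):
        with pytest.raises(DataError, match="u1.*day 2"):
            oe.binarize(_series({2: {"comments": -1}}))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_row_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.4, size=(8, len(MEASURES)))
        df = pd.DataFrame(
            counts, index=pd.RangeIndex(1, 9, name="day_index"), columns=list(MEASURES)
        )
        seq = oe.binarize(EngagementSeries("u", df, 8))
        assert np.array_equal(seq.engaged, counts.sum(axis=1) > 0)


class TestSequenceLoglik:
    def test_length_one_engaged_is_certain(self):
        A, b = np.eye(3), np.array([1.0, 0.3, 0.0])
        assert oe.sequence_loglik([True], A, b) == 0.0

    def test_length_one_not_engaged_is_impossible(self):
        A, b = np.eye(3), np.array([1.0, 0.3, 0.0])
        assert oe.sequence_loglik([False], A, b) == -np.inf

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(200):
            T = int(rng.integers(1, 11))
            engaged = rng.random(T) < 0.6
            engaged[0] = True
            A, b = _random_component(rng)
            got = oe.sequence_loglik(engaged, A, b)
            want = enumeration_loglik(engaged, A, b)
            if np.isinf(want):
                assert np.isinf(got)
            else:
                worst = max(worst, abs(got - want))
        assert worst < 1e-9

    def test_numba_and_numpy_paths_agree(self):
        rng = np.random.default_rng(5)
        X = (rng.random((40, 30)) < 0.5)
        X[:, 0] = True
        A, b = _random_component(rng)
        A = A[None]
        w = np.ones(1)
        _, _, ll_np = _forward_all(X, _emissions_lin(X, b), A)
        _, cll_nb, *_ = _estep_core(X.astype(np.uint8), A, w, b)
        assert np.allclose(ll_np, cll_nb, atol=1e-10)


class TestEmFit:
    def test_degenerate_fully_engaged(self):
        X = np.ones((30, 20), dtype=bool)
        est = MarkovChainMixture(n_components=1, n_init=2, max_iter=100, random_state=0).fit(X)
        assert est.emissions_[0] > 1 - 1e-6
        assert est.transitions_[0, 0, 0] > 1 - 1e-6

    def test_requires_enough_sequences(self):
        with pytest.raises(ValueError, match="n_components"):
            MarkovChainMixture(n_components=5).fit(np.ones((3, 4), dtype=bool))

    def test_structural_constraints_hold_every_iteration(self, small_X):
        est = MarkovChainMixture(
            n_components=3, n_init=2, max_iter=60, tol=1e-6,
            random_state=1, keep_history=True,
        ).fit(small_X)
        for snap in est.history_:
            A, b = snap["transitions"], snap["emissions"]
            assert np.allclose(A.sum(axis=2), 1.0, atol=1e-10)
            assert np.all(A[:, 2] == (0.0, 0.0, 1.0))
            assert b[2] == 0.0
            assert b[0] >= b[1] >= 0.0
        ll = np.array([s["loglik"] for s in est.history_])
        assert np.all(np.diff(ll) >= -1e-8 * np.maximum(1.0, np.abs(ll[:-1])))

    def test_loglik_trace_nondecreasing_random_data(self):
        rng = np.random.default_rng(9)
        X = rng.random((80, 40)) < rng.uniform(0.1, 0.9, size=(80, 1))
        X[:, 0] = True
        est = MarkovChainMixture(n_components=2, n_init=3, max_iter=80, random_state=2).fit(X)
        tr = est.loglik_trace_
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_bit_reproducible(self, small_X):
        kw = dict(n_components=3, n_init=2, max_iter=40, random_state=11)
        a = MarkovChainMixture(**kw).fit(small_X)
        b = MarkovChainMixture(**kw).fit(small_X)
        assert np.array_equal(a.transitions_, b.transitions_)
        assert np.array_equal(a.responsibilities_, b.responsibilities_)
        assert np.array_equal(a.loglik_trace_, b.loglik_trace_)

    def test_total_loglik_invariant_under_label_permutation(self, small_X):
        est = MarkovChainMixture(n_components=3, n_init=2, max_iter=40, random_state=3).fit(small_X)
        base = est.score(small_X)
        perm = [2, 0, 1]
        est.transitions_ = est.transitions_[perm]
        est.weights_ = est.weights_[perm]
        assert np.isclose(est.score(small_X), base, rtol=1e-12)

    def test_engaged_final_day_forbids_earlier_absorption(self, small_X):
        """A user active on the final day cannot have disengaged earlier."""
        from ohcengage.mixture import _backward_stats

        est = MarkovChainMixture(n_components=2, n_init=2, max_iter=40, random_state=4).fit(small_X)
        X = small_X[small_X[:, -1]]  # users engaged on the last day
        e = _emissions_lin(X, est.emissions_)
        alphas, cs, ll = _forward_all(X, e, est.transitions_)
        occ, _, _ = _backward_stats(e, est.transitions_, X, alphas, cs)
        # total expected days spent disengaged (smoothed posterior) must be 0
        assert occ[:, :, 2].max() < 1e-12

    def test_responsibilities_rows_sum_to_one(self, small_X):
        est = MarkovChainMixture(n_components=4, n_init=2, max_iter=40, random_state=5).fit(small_X)
        assert np.allclose(est.responsibilities_.sum(axis=1), 1.0, atol=1e-8)

    def test_components_ordered_by_expected_engagement(self, small_X):
        est = MarkovChainMixture(n_components=4, n_init=2, max_iter=60, random_state=6).fit(small_X)
        vals = [
            oe.expected_engaged_days(A, est.emissions_, small_X.shape[1])
            for A in est.transitions_
        ]
        assert vals == sorted(vals)


class TestAssignClusters:
    def test_argmax_assignment(self):
        df = oe.assign_clusters(np.array([[0.1, 0.9], [0.8, 0.2]]), ["a", "b"])
        assert list(df["cluster"]) == [1, 0]
        assert list(df["max_responsibility"]) == [0.9, 0.8]

    def test_tie_breaks_to_lowest_index(self):
        df = oe.assign_clusters(np.array([[0.5, 0.5]]))
        assert df["cluster"].iloc[0] == 0


class TestElbow:
    def test_linear_curve_picks_smallest_interior(self, monkeypatch):
        self._patch_logliks(monkeypatch, {k: -1000.0 + 50.0 * k for k in range(1, 7)})
        sel = oe.select_k_elbow(np.ones((10, 5), dtype=bool), [1, 2, 3, 4, 5, 6])
        assert sel.chosen_K == 2

    def test_sharp_bend_is_found(self, monkeypatch):
        lls = {1: -2000.0, 2: -1500.0, 3: -1000.0, 4: -600.0, 5: -590.0, 6: -580.0}
        self._patch_logliks(monkeypatch, lls)
        sel = oe.select_k_elbow(np.ones((10, 5), dtype=bool), [1, 2, 3, 4, 5, 6])
        assert sel.chosen_K == 4

    def test_nonmonotone_curve_warns(self, monkeypatch):
        lls = {1: -1000.0, 2: -900.0, 3: -950.0, 4: -940.0}
        self._patch_logliks(monkeypatch, lls)
        with pytest.warns(RuntimeWarning, match="not monotone"):
            oe.select_k_elbow(np.ones((10, 5), dtype=bool), [1, 2, 3, 4])

    def test_needs_three_sorted_candidates(self):
        X = np.ones((10, 5), dtype=bool)
        with pytest.raises(ValueError):
            oe.select_k_elbow(X, [2, 3])
        with pytest.raises(ValueError):
            oe.select_k_elbow(X, [3, 2, 4])

    @staticmethod
    def _patch_logliks(monkeypatch, lls):
        def fake_fit(self, X, y=None):
            self.lower_bound_ = lls[self.n_components]
            return self

        monkeypatch.setattr(MarkovChainMixture, "fit", fake_fit)


class TestSummarizeClusters:
    def test_singleton_cluster_sd_zero(self):
        X = np.zeros((1, 10), dtype=bool)
        X[0, :6] = True
        df = oe.summarize_clusters([0], X)
        assert df.loc[0, "mean"] == 6 and df.loc[0, "sd"] == 0.0

    def test_two_user_sample_sd(self):
        X = np.zeros((2, 10), dtype=bool)
        X[0, :4] = True
        X[1, :8] = True
        df = oe.summarize_clusters([0, 0], X)
        assert df.loc[0, "mean"] == 6.0
        assert df.loc[0, "sd"] == pytest.approx(2.828, abs=0.001)

    def test_identical_users_sd_zero_and_empty_cluster_reported(self):
        X = np.ones((3, 5), dtype=bool)
        df = oe.summarize_clusters([0, 0, 0], X, n_clusters=2)
        assert df.loc[0, "sd"] == 0.0
        assert df.loc[1, "n"] == 0 and np.isnan(df.loc[1, "mean"])
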