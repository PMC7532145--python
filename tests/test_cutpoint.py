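import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit
from scipy.stats import combine_pvalues as scipy_combine

from bmx.association import fit_logistic, lr_pvalue
from bmx.cutpoint import (
    _g_test_pvalues,
    candidate_cutpoints,
    combine_pvalues_logit,
    cv_cutpoint_search,
    dichotomize,
)


class TestCandidates:
    def test_enumeration_oracle_one_to_twenty(self):
        """Brute-force enumeration of admissible midpoints for values 1..20."""
        values = np.arange(1.0, 21.0)
        got = candidate_cutpoints(values, min_group=5)

        sv = np.sort(values)
        expected = []
        for a, b in zip(np.unique(sv)[:-1], np.unique(sv)[1:]):
            mid = (a + b) / 2
            if (sv < mid).sum() >= 5 and (sv > mid).sum() >= 5:
                expected.append(mid)
        assert list(got) == expected
        assert got[0] == 5.5 and got[-1] == 15.5

    def test_all_identical_fatal(self):
        with pytest.raises(ValueError, match="identical"):
            candidate_cutpoints(np.full(20, 3.0))

    def test_min_group_half_n_single_candidate(self):
        values = np.arange(1.0, 11.0)
        got = candidate_cutpoints(values, min_group=5)
        assert list(got) == [5.5]

    def test_too_few_values_fatal(self):
        with pytest.raises(ValueError, match="at least"):
            candidate_cutpoints(np.arange(5.0), min_group=5)

    @given(st.lists(st.floats(-100, 100), min_size=12, max_size=60),
           st.integers(2, 6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_each_side_holds_min_group(self, values, min_group):
        x = np.asarray(values)
        if len(np.unique(x)) < 2 * min_group:
            return
        try:
            cand = candidate_cutpoints(x, min_group=min_group)
        except ValueError:
            return
        for c in cand:
            assert (x < c).sum() >= min_group
            assert (x > c).sum() >= min_group


class TestCombinePvalues:
    def test_all_half_gives_half(self):
        for k in (1, 3, 10, 100):
            assert combine_pvalues_logit([0.5] * k) == pytest.approx(0.5, abs=1e-12)

    def test_single_p_against_independent_implementation(self):
        """scipy's Mudholkar-George implementation as the independent oracle."""
        for ps in ([0.05], [0.01, 0.2, 0.7], [0.5, 0.9, 0.004, 0.3]):
            ours = combine_pvalues_logit(ps)
            ref = scipy_combine(ps, method="mudholkar_george").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_antisymmetric_logits_give_half(self):
        ps = [0.2, 0.8, 0.35, 0.65, 0.5]
        assert combine_pvalues_logit(ps) == pytest.approx(0.5, abs=1e-12)

    def test_boundary_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = combine_pvalues_logit([0.0, 0.5])
        assert 0 < p < 1

    def test_log_mode_consistent_and_stable(self):
        ps = [0.01] * 5
        assert np.exp(combine_pvalues_logit(ps, log=True)) == pytest.approx(
            combine_pvalues_logit(ps), rel=1e-10)
        # thousands of tiny p-values: log mode stays finite
        lp = combine_pvalues_logit([1e-10] * 1000, log=True)
        assert np.isfinite(lp) and lp < -1000

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            combine_pvalues_logit([])


class TestDichotomize:
    def test_basic(self):
        assert list(dichotomize(np.array([1.0, 2.0, 3.0]), 2.0)) == [0, 0, 1]

    def test_cut_below_min_all_one(self):
        assert dichotomize(np.array([1.0, 2.0]), 0.0).sum() == 2

    def test_cut_above_max_all_zero(self):
        assert dichotomize(np.array([1.0, 2.0]), 5.0).sum() == 0

    def test_missing_stays_missing(self):
        out = dichotomize(pd.Series([1.0, np.nan, 3.0]), 2.0)
        assert np.isnan(out.iloc[1]) and out.iloc[2] == 1.0


class TestGTestIdentity:
    @pytest.mark.parametrize("seed", range(4))
    def test_g_test_equals_logistic_lr(self, seed):
        """Closed-form 2x2 G-test == logistic LR test for a binary predictor."""
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.standard_normal(n)
        y = rng.binomial(1, 0.4, n).astype(float)
        cut = np.median(x)
        high = (x > cut).astype(float)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        p_fast = _g_test_pvalues((x[:, None] > np.array([cut])), y)[0]

        idx = [f"P{i}" for i in range(n)]
        full = fit_logistic(y, pd.DataFrame({"intercept": 1.0, "high": high}, index=idx))
        red = fit_logistic(y, pd.DataFrame({"intercept": np.ones(n)}, index=idx))
        p_slow, _ = lr_pvalue(full, red)
        assert p_fast == pytest.approx(p_slow, abs=1e-7)


class TestCVSearch:
    def _step_data(self, seed, n=120, delta=2.0):
        rng = np.random.default_rng(seed)
        x = np.exp(8.0 + 0.4 * rng.standard_normal(n))
        theta = np.exp(8.0)
        y = rng.binomial(1, expit(logit(0.3) + delta * (x > theta)))
        return x, y, theta

    def test_same_seed_identical_result(self):
        x, y, _ = self._step_data(0)
        r1 = cv_cutpoint_search(x, y, n_repeats=50, seed=4)
        r2 = cv_cutpoint_search(x, y, n_repeats=50, seed=4)
        assert r1.selected == r2.selected
        assert (r1.train_select_count == r2.train_select_count).all()
        np.testing.assert_array_equal(r1.combined_p_test, r2.combined_p_test)

    def test_monotone_transform_equivariance(self):
        """A strictly increasing transform maps the selection to the same rank interval."""
        x, y, _ = self._step_data(1)
        r1 = cv_cutpoint_search(x, y, n_repeats=100, seed=7)
        r2 = cv_cutpoint_search(np.log(x), y, n_repeats=100, seed=7)
        i1 = int(np.argmin(np.abs(r1.candidates - r1.selected)))
        i2 = int(np.argmin(np.abs(r2.candidates - r2.selected)))
        assert i1 == i2
        assert (r1.train_select_count == r2.train_select_count).all()

    def test_step_recovered_within_few_ranks(self):
        """Selected cut sits within 8 rank positions of the true jump in most runs."""
        near = 0
        n_runs = 12
        for seed in range(n_runs):
            x, y, theta = self._step_data(100 + seed)
            res = cv_cutpoint_search(x, y, n_repeats=200, seed=seed)
            assert res.pass_stability
            xs = np.sort(x)
            shift = abs(np.searchsorted(xs, res.selected) - np.searchsorted(xs, theta))
            near += shift <= 8
        assert near >= 0.75 * n_runs

    def test_too_few_events_fatal(self):
        x = np.arange(20.0)
        y = np.r_[np.ones(2), np.zeros(18)]
        with pytest.raises(ValueError, match="events"):
            cv_cutpoint_search(x, y)

    def test_missing_values_excluded(self):
        x, y, _ = self._step_data(3)
        x2 = x.copy()
        x2[:5] = np.nan
        res = cv_cutpoint_search(x2, y, n_repeats=20, seed=1)
        ref = cv_cutpoint_search(x[5:], y[5:], n_repeats=20, seed=1)
        assert res.selected == ref.selected

    def test_restrict_mode_selects_among_qualifying(self):
        x, y, _ = self._step_data(5)
        res = cv_cutpoint_search(x, y, n_repeats=100, seed=2,
                                 stability_mode="restrict")
        if res.selected is not None:
            i = int(np.argmin(np.abs(res.candidates - res.selected)))
            assert res.train_select_count[i] >= res.stability_min

    def test_train_counts_sum_to_repeats(self):
        x, y, _ = self._step_data(6)
        res = cv_cutpoint_search(x, y, n_repeats=80, seed=3)
        assert res.train_select_count.sum() == 80

    def test_result_serializes(self):
        import json

        x, y, _ = self._step_data(7)
        res = cv_cutpoint_search(x, y, n_repeats=20, seed=0)
        assert json.loads(json.dumps(res.to_dict()))["n_repeats"] == 20
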