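import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import chi2, kstest

from bmx.association import (
    AssociationResult,
    fit_logistic,
    lr_pvalue,
    screen,
    screen_all,
    signature_score,
)
from bmx.data_model import OmicsMatrix

from conftest import make_clinical


def design(**cols):
    n = len(next(iter(cols.values())))
    idx = [f"P{i}" for i in range(n)]
    return pd.DataFrame({"intercept": np.ones(n), **cols}, index=idx)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(6), np.zeros(4)]
        fit = fit_logistic(y, pd.DataFrame({"intercept": np.ones(10)}))
        assert fit.params["intercept"] == pytest.approx(np.log(6 / 4), abs=1e-6)
        assert fit.log_likelihood == pytest.approx(
            6 * np.log(0.6) + 4 * np.log(0.4), abs=1e-8)
        assert fit.n == 10 and fit.n_events == 6

    def test_two_by_two_closed_form_slope(self):
        # high group: 8/10 events; low group: 2/10
        y = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
        x = np.r_[np.ones(10), np.zeros(10)]
        fit = fit_logistic(y, design(biomarker=x))
        assert fit.params["biomarker"] == pytest.approx(np.log(16.0), abs=1e-5)
        assert not fit.separation_flag

    def test_separation_flagged_finite(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        x = np.r_[np.ones(5), np.zeros(5)].astype(float)
        fit = fit_logistic(y, design(biomarker=x))
        assert fit.separation_flag
        assert np.isfinite(fit.params).all()

    def test_degenerate_outcome_error(self):
        with pytest.raises(ValueError, match="degenerate outcome"):
            fit_logistic(np.ones(5), design(biomarker=np.arange(5.0)))

    def test_constant_column_dropped(self):
        y = np.r_[np.ones(4), np.zeros(4)]
        fit = fit_logistic(y, design(biomarker=np.r_[np.arange(8.0)],
                                     flat=np.zeros(8)))
        assert "flat" in fit.dropped_terms
        assert "flat" not in fit.params.index

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_statsmodels_mle(self, seed):
        """Independent MLE oracle on random 2-column designs, n <= 30."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 31))
        x = rng.standard_normal(n)
        y = rng.binomial(1, 0.4, n).astype(float)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        ours = fit_logistic(y, design(biomarker=x))
        X = sm.add_constant(pd.DataFrame({"biomarker": x}))
        ref = sm.Logit(y, X).fit(disp=0)
        if not ours.separation_flag:
            assert ours.params["biomarker"] == pytest.approx(
                ref.params["biomarker"], abs=1e-4)
            assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_grid_search_oracle_two_by_two(self):
        """Coarse-to-fine grid search over (b0, b1) reproduces the MLE."""
        y = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
        x = np.r_[np.ones(10), np.zeros(10)]

        def ll(b0, b1):
            eta = b0 + b1 * x
            return y @ eta - np.logaddexp(0, eta).sum()

        b0, b1, width = 0.0, 0.0, 8.0
        for _ in range(12):
            g0 = np.linspace(b0 - width, b0 + width, 41)
            g1 = np.linspace(b1 - width, b1 + width, 41)
            vals = np.array([[ll(a, b) for b in g1] for a in g0])
            i, j = np.unravel_index(vals.argmax(), vals.shape)
            b0, b1, width = g0[i], g1[j], width / 8
        fit = fit_logistic(y, design(biomarker=x))
        assert fit.params["biomarker"] == pytest.approx(b1, abs=1e-4)
        assert fit.params["intercept"] == pytest.approx(b0, abs=1e-4)


class TestLRPvalue:
    def _fits(self):
        y = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
        x = np.r_[np.ones(10), np.zeros(10)]
        full = fit_logistic(y, design(biomarker=x))
        reduced = fit_logistic(y, design(biomarker=x)[["intercept"]])
        return y, x, full, reduced

    def test_identical_models_give_p_one(self):
        _, _, full, _ = self._fits()
        p, df = lr_pvalue(full, full)
        assert p == 1.0 and df == 0

    def test_matches_g_test_oracle(self):
        """Binomial deviance G-test 2*sum O log(O/E) computed directly."""
        y, x, full, reduced = self._fits()
        obs = np.array([8, 2, 2, 8], dtype=float)
        n1 = n0 = 10.0
        e = y.sum()
        n = len(y)
        exp = np.array([n1 * e / n, n1 * (n - e) / n, n0 * e / n, n0 * (n - e) / n])
        g = 2 * (obs * np.log(obs / exp)).sum()
        p, df = lr_pvalue(full, reduced)
        assert df == 1
        assert p == pytest.approx(chi2.sf(g, 1), abs=1e-8)

    def test_chi_square_quantile(self):
        # df=1, statistic 3.841 -> p = 0.05
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)
        y, x, full, reduced = self._fits()
        # construct fits with controlled log-likelihoods
        f = AssociationResult  # noqa: F841  (keep import used)
        full.log_likelihood = reduced.log_likelihood + 3.841 / 2
        p, _ = lr_pvalue(full, reduced)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_mismatched_patients_fatal(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        x = np.arange(10.0)
        full = fit_logistic(y, design(biomarker=x))
        other = fit_logistic(y[:8], design(biomarker=x[:8])[["intercept"]])
        with pytest.raises(ValueError, match="patient"):
            lr_pvalue(full, other)

    def test_non_nested_fatal(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        a = fit_logistic(y, design(a=np.arange(10.0)))
        b = fit_logistic(y, design(b=np.arange(10.0)))
        with pytest.raises(ValueError, match="subset"):
            lr_pvalue(a, b)


class TestScreen:
    def test_affine_rescaling_invariance(self, rng):
        clin = make_clinical(80, rng)
        bm = pd.Series(rng.standard_normal(80), index=clin.patient_ids)
        p1 = screen(bm, clin, "interaction").lr_p
        p2 = screen(1000.0 * bm + 5.0, clin, "interaction").lr_p
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_constant_biomarker_flagged_null(self, rng):
        clin = make_clinical(40, rng)
        bm = pd.Series(1.0, index=clin.patient_ids)
        res = screen(bm, clin, "treated_arm")
        assert res.lr_p == 1.0 and res.direction == 0
        assert any(f.startswith("degenerate") for f in res.flags)

    def test_underpowered_subset_flagged_but_reported(self, rng):
        clin = make_clinical(30, rng, pcr_rate=0.3)
        bm = pd.Series(rng.standard_normal(30), index=clin.patient_ids)
        res = screen(bm, clin, "treated_arm", subset="HR-HER2+")
        assert "underpowered" in res.flags
        assert 0 < res.lr_p <= 1

    def test_direction_tracks_effect_sign(self, rng):
        clin = make_clinical(400, rng)
        eta = -1.0 + 2.0 * rng.standard_normal(400)
        bm = pd.Series(eta, index=clin.patient_ids)
        clin.df["pcr"] = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        res = screen(bm, clin, "treated_arm")
        assert res.direction == 1 and res.lr_p < 0.01

    def test_arm_exchangeability_under_null(self):
        """p-values from the two arm-wise screens are exchangeable under the null."""
        ps_t, ps_c = [], []
        rng = np.random.default_rng(0)
        for _ in range(200):
            clin = make_clinical(100, rng)
            bm = pd.Series(rng.standard_normal(100), index=clin.patient_ids)
            ps_t.append(screen(bm, clin, "treated_arm").lr_p)
            ps_c.append(screen(bm, clin, "control_arm").lr_p)
        stat = kstest(ps_t, ps_c)
        assert stat.pvalue > 0.01


class TestScreenAll:
    def test_empty_matrix(self, rng):
        clin = make_clinical(20, rng)
        m = OmicsMatrix(pd.DataFrame(columns=clin.patient_ids, dtype=float))
        table, n_pass = screen_all(m, clin, "treated_arm")
        assert len(table) == 0 and n_pass == 0

    def test_null_pass_count_binomial(self, rng):
        clin = make_clinical(100, rng)
        m = OmicsMatrix(pd.DataFrame(rng.standard_normal((300, 100)),
                                     index=[f"g{i}" for i in range(300)],
                                     columns=clin.patient_ids))
        _, n_pass = screen_all(m, clin, "interaction")
        # binomial(300, 0.05): 99% interval about [5, 26]
        assert 2 <= n_pass <= 30

    def test_strong_feature_detected(self, rng):
        clin = make_clinical(400, rng)
        z = rng.standard_normal(400)
        clin.df["pcr"] = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 2.0 * z))))
        vals = rng.standard_normal((10, 400))
        vals[0] = z
        m = OmicsMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                                     columns=clin.patient_ids))
        table, _ = screen_all(m, clin, "treated_arm")
        assert table.loc[table.biomarker == "g0", "lr_p"].iloc[0] < 0.05


class TestSignatureScore:
    def _matrix(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0], [5.0, 5.0, 8.0]],
            index=["up", "down", "extra"], columns=["P1", "P2", "P3"],
        )
        return OmicsMatrix(values)

    def test_singleton_set_is_centered_gene(self):
        m = self._matrix()
        score = signature_score(m, ["up"])
        assert list(score) == [-1.0, 0.0, 1.0]

    def test_antisymmetric_pair_scores_zero(self):
        m = self._matrix()
        assert (signature_score(m, ["up", "down"]) == 0).all()

    def test_hand_computed_mean(self):
        m = self._matrix()
        # centered rows: up -> (-1,0,1); extra -> (0,0,3)
        score = signature_score(m, ["up", "extra"])
        assert list(score) == [-0.5, 0.0, 2.0]

    def test_no_overlap_fatal(self):
        with pytest.raises(ValueError, match="absent"):
            signature_score(self._matrix(), ["absent"])
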