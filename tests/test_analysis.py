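import numpy as np
import pandas as pd
import pytest
from scipy.linalg import sqrtm

from kinemorph.analysis import (
    RankError,
    SeparationError,
    bonferroni_family,
    build_report,
    ci_overlap,
    descriptives,
    fit_logistic,
    johnson_relative_weights,
    predictor_correlations,
    relative_weights,
)

# ---------------------------------------------------------------------------
# Frozen external-oracle fixture for the logistic fit: 30 observations, two
# integer predictors.  Expected coefficients and 95% profile-likelihood CIs
# were computed independently with R (glm + MASS::confint.glm).
# ---------------------------------------------------------------------------
ORACLE_Y = [1,1,1,1,0,1,0,1,0,1,0,1,0,1,1,0,1,1,0,1,1,1,1,0,1,0,0,0,1,1]
ORACLE_X1 = [1,8,3,4,5,3,2,7,6,0,10,7,3,7,4,5,7,2,6,8,8,4,7,1,5,6,2,5,9,10]
ORACLE_X2 = [7,7,3,2,1,6,7,3,2,6,6,5,8,5,5,2,5,8,5,5,6,6,6,6,7,3,6,1,6,2]
ORACLE_COEF = {"s_h": 0.1943438549, "s_v": 0.3153084007}
ORACLE_PROFILE_CI = {
    "s_h": (-0.11215942, 0.54418793),
    "s_v": (-0.07455251, 0.75777184),
}


def _oracle_records():
    return pd.DataFrame(
        {
            "participant_id": range(len(ORACLE_Y)),
            "category": "dominant",
            "polarity": ORACLE_Y,
            "s_h": ORACLE_X1,
            "s_v": ORACLE_X2,
            "s_vel": 0,
            "experiment": "stick",
        }
    )


def _records(s_h, s_v, s_vel, y, category="dominant"):
    return pd.DataFrame(
        {
            "participant_id": range(len(y)),
            "category": category,
            "polarity": y,
            "s_h": s_h,
            "s_v": s_v,
            "s_vel": s_vel,
            "experiment": "stick",
        }
    )


class TestDescriptives:
    def test_median_and_quartiles(self):
        rec = _records([1, 2, 3, 0], [0, 10, 5, 5], [4, 4, 4, 4], [1, 1, 1, 0])
        out = descriptives(rec)
        high = out[(out["polarity"] == 1) & (out["component"] == "s_h")].iloc[0]
        assert high["median"] == 2.0  # odd count median
        mid = out[(out["polarity"] == 1) & (out["component"] == "s_v")].iloc[0]
        assert mid["q1"] <= mid["median"] <= mid["q3"]

    def test_two_value_median_is_midpoint(self):
        rec = _records([0, 10], [0, 0], [0, 0], [1, 1])
        out = descriptives(rec)
        row = out[out["component"] == "s_h"].iloc[0]
        assert row["median"] == 5.0

    def test_constant_group_collapses_quartiles(self):
        rec = _records([7] * 4, [1] * 4, [2] * 4, [1] * 4)
        row = descriptives(rec).query("component == 's_h'").iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == 7.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            descriptives(pd.DataFrame(columns=["category", "polarity", "s_h"]))


class TestFitLogistic:
    def test_matches_r_glm_oracle(self):
        fit = fit_logistic(_oracle_records(), "dominant", predictors=("s_h", "s_v"))
        for name, coef in ORACLE_COEF.items():
            assert fit.estimates[name] == pytest.approx(coef, abs=1e-6)

    def test_profile_ci_matches_r_confint(self):
        """Profile-likelihood CIs agree with MASS::confint.glm to ~1e-3
        (R interpolates the profile on a spline grid; we solve the
        likelihood-ratio equation directly)."""
        fit = fit_logistic(_oracle_records(), "dominant", predictors=("s_h", "s_v"))
        assert fit.ci_method == "profile"
        for name, (lo, hi) in ORACLE_PROFILE_CI.items():
            assert fit.conf_int[name][0] == pytest.approx(lo, abs=1e-3)
            assert fit.conf_int[name][1] == pytest.approx(hi, abs=1e-3)

    def test_symmetric_predictor_gives_zero_estimate(self):
        x = [0, 2, 4, 6, 8, 10] * 2
        y = [1] * 6 + [0] * 6
        fit = fit_logistic(_records(x, [0] * 12, [0] * 12, y), "dominant",
                           predictors=("s_h",), ci_method="wald")
        assert fit.estimates["s_h"] == pytest.approx(0.0, abs=1e-8)

    def test_complete_separation_raises(self):
        rec = _records([10] * 6 + [0] * 6, [5] * 12, [5] * 12, [1] * 6 + [0] * 6)
        with pytest.raises(SeparationError):
            fit_logistic(rec, "dominant", predictors=("s_h",))

    def test_constant_predictor_raises_rank_error(self):
        rec = _records([5] * 8, [1, 2, 3, 4, 5, 6, 7, 8], [0] * 8,
                       [1, 0, 1, 0, 1, 0, 1, 0])
        with pytest.raises(RankError):
            fit_logistic(rec, "dominant", predictors=("s_h",))

    def test_large_sample_consistency(self):
        """n = 10,000 draws from a logistic model with slope 0.5 recover
        the slope within 0.05."""
        rng = np.random.default_rng(7)
        x = rng.integers(0, 11, 10_000)
        p = 1 / (1 + np.exp(-(-2.5 + 0.5 * x)))
        y = (rng.random(10_000) < p).astype(int)
        fit = fit_logistic(_records(x, [0] * len(x), [0] * len(x), y), "dominant",
                           predictors=("s_h",), ci_method="wald")
        assert fit.estimates["s_h"] == pytest.approx(0.5, abs=0.05)

    def test_missing_polarity_rejected(self):
        rec = _records([1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="polarity"):
            fit_logistic(rec, "dominant")


class TestJohnsonWeights:
    @staticmethod
    def _orthogonal_design(n=64, p=3, seed=0):
        # QR of [1, G] gives columns that are mutually orthogonal AND
        # centered, so the standardized predictors are exactly uncorrelated
        rng = np.random.default_rng(seed)
        g = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        q, _ = np.linalg.qr(g)
        X = q[:, 1:]
        return (X - X.mean(0)) / X.std(0, ddof=1)

    def test_orthogonal_closed_form(self):
        """With exactly orthogonal standardized predictors each weight is
        the squared zero-order correlation with the outcome."""
        X = self._orthogonal_design(seed=1)
        rng = np.random.default_rng(2)
        y = X @ [0.5, -0.3, 0.8] + rng.standard_normal(len(X))
        eps, total = johnson_relative_weights(X, y, binary=False)
        r = [np.corrcoef(X[:, j], y)[0, 1] for j in range(3)]
        np.testing.assert_allclose(eps, np.square(r), atol=1e-10)
        assert total == pytest.approx(np.sum(np.square(r)), abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_linear_weights_sum_to_ols_r2(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        X = rng.standard_normal((n, 3)) @ rng.standard_normal((3, 3))
        y = X @ rng.standard_normal(3) + rng.standard_normal(n)
        eps, total = johnson_relative_weights(X, y, binary=False)
        Xc = np.column_stack([np.ones(n), X])
        resid = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        r2 = 1 - resid.var() / y.var()
        assert total == pytest.approx(r2, abs=1e-10)
        assert np.all(eps >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matrix_square_root_formulation(self, seed):
        """Independent oracle: the classical correlation-matrix route
        (loadings = Rxx^(1/2), surrogate betas = Rxx^(-1/2) rxy) gives the
        same linear weights as the SVD route."""
        rng = np.random.default_rng(100 + seed)
        n = 200
        X = rng.standard_normal((n, 3)) @ rng.standard_normal((3, 3))
        y = X @ [1.0, 0.2, -0.5] + 2 * rng.standard_normal(n)
        eps, _ = johnson_relative_weights(X, y, binary=False)
        R = np.corrcoef(X.T)
        rxy = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(3)])
        lam = np.real(sqrtm(R))
        beta_star = np.linalg.solve(lam, rxy)
        oracle = (lam**2) @ beta_star**2
        np.testing.assert_allclose(eps, oracle, atol=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 3)) @ rng.standard_normal((3, 3))
        y = (rng.random(80) < 0.5).astype(float)
        eps, _ = johnson_relative_weights(X, y, binary=True)
        perm = [2, 0, 1]
        eps_p, _ = johnson_relative_weights(X[:, perm], y, binary=True)
        np.testing.assert_allclose(eps_p, eps[perm], atol=1e-8)

    def test_logistic_weights_sum_to_pseudo_r2(self, toy_records):
        rw = relative_weights(toy_records, "dominant")
        assert sum(rw.weights.values()) == pytest.approx(rw.total_r2, abs=1e-8)
        assert all(w >= 0 for w in rw.weights.values())

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(40)
        X = np.column_stack([x, 2 * x, rng.standard_normal(40)])
        with pytest.raises(RankError):
            johnson_relative_weights(X, rng.random(40))


class TestDiagnostics:
    def test_correlation_matrix_properties(self, toy_records):
        R = predictor_correlations(toy_records, "dominant")
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R.values, R.values.T, atol=1e-12)

    def test_independent_sliders_uncorrelated(self):
        rng = np.random.default_rng(5)
        rec = _records(
            rng.integers(0, 11, 10_000),
            rng.integers(0, 11, 10_000),
            rng.integers(0, 11, 10_000),
            rng.integers(0, 2, 10_000),
        )
        R = predictor_correlations(rec, "dominant")
        off = R.values[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_zero_variance_flagged(self):
        rec = _records([5] * 6, [1, 2, 3, 4, 5, 6], [1, 1, 2, 2, 3, 3], [1, 0] * 3)
        with pytest.warns(UserWarning, match="zero-variance"):
            R = predictor_correlations(rec, "dominant")
        assert np.isnan(R.loc["s_h", "s_v"])


class TestBonferroni:
    def test_adjusted_alpha_for_family_of_30(self):
        flags, alpha = bonferroni_family([0.001, 0.01], m=30)
        assert alpha == pytest.approx(0.05 / 30)
        assert flags == [True, False]

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni_family([0.01], m=0)
        with pytest.raises(ValueError):
            bonferroni_family([0.01, 0.02, 0.03], m=2)


class TestCIOverlap:
    @pytest.mark.parametrize(
        "a,b,relation",
        [
            ((1, 2), (3, 4), "disjoint_or_touching"),
            ((1, 3), (2, 4), "overlapping"),
            ((1, 2), (2, 4), "disjoint_or_touching"),  # touching counts
        ],
    )
    def test_relations(self, a, b, relation):
        assert ci_overlap(a, b).relation == relation
        assert ci_overlap(b, a).relation == relation  # symmetric

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            ci_overlap((2, 1), (0, 3))


class TestBuildReport:
    def test_structure_and_r2_consistency(self, toy_records):
        report = build_report(toy_records, "stick")
        cats = {r["category"] for r in report["multi_predictor"]}
        assert cats <= {"dominant", "friendly"} and cats
        for row in report["multi_predictor"]:
            summed = sum(row[p]["weight"] for p in ("s_h", "s_v", "s_vel"))
            assert summed == pytest.approx(row["r2"], abs=1e-8)
            for p in ("s_h", "s_v", "s_vel"):
                lo, hi = row[p]["ci"]
                assert lo < hi
        assert report["adjusted_alpha"] <= 0.05 / 30

    def test_report_serializes_and_formats(self, toy_records):
        import json

        from kinemorph.analysis import format_report

        report = build_report(toy_records, "stick")
        text = format_report(report)
        assert "Multi-predictor" in text and "R2" in text
        json.dumps(report)  # must be JSON-serializable

    def test_unknown_experiment_rejected(self, toy_records):
        with pytest.raises(ValueError):
            build_report(toy_records, "video")
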