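"""Weighted logistic regression against closed forms and a reference MLE."""

import numpy as np
import pytest

from rdschain.exceptions import ConvergenceError, DesignError, EstimationError
from rdschain.models import (
    bivariate_association,
    dichotomize,
    fit_weighted_logistic,
    irls_logistic,
    odds_ratio_report,
)
from rdschain.records import build_dataset

from conftest import make_row


def two_by_two_dataset():
    """Exposed (pregnant): 20 users / 80 non-users; unexposed: 10 / 90.
    Closed-form OR = (20*90)/(80*10) = 2.25."""
    rows = [make_row("seed", None)]
    i = 0
    for pregnant, used, count in [(True, True, 20), (True, False, 80),
                                  (False, True, 10), (False, False, 90)]:
        for _ in range(count):
            rows.append(make_row(
                f"r{i}", "seed" if i < 3 else f"r{i-3}",
                degree_reported=10, pregnant=pregnant,
                used_health_service_15d=used,
                reason_for_use="prenatal" if used else None,
            ))
            i += 1
    return build_dataset(rows)


class TestIRLSAgainstClosedForms:
    def test_two_by_two_odds_ratio(self):
        ds = two_by_two_dataset()
        fit = fit_weighted_logistic(ds, None, covariates=["pregnant"])
        assert fit.odds_ratios["pregnant"] == pytest.approx(2.25, abs=1e-6)
        assert fit.coefficients["pregnant"] == pytest.approx(np.log(2.25), abs=1e-6)

    def test_null_model_intercept_is_logit_of_prevalence(self, tiny_dataset):
        from rdschain.estimation import compute_rds2_weights

        w = compute_rds2_weights(tiny_dataset)
        fit = fit_weighted_logistic(tiny_dataset, w, covariates=[])
        recruits = tiny_dataset.recruits().set_index("participant_id")
        ww = w.weights.reindex(recruits.index)
        p = float((ww * recruits["used_health_service_15d"]).sum() / ww.sum())
        assert fit.coefficients["const"] == pytest.approx(np.log(p / (1 - p)),
                                                          abs=1e-8)

    def test_integer_weights_equal_row_replication(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        w = rng.integers(1, 4, n).astype(float)
        beta_w, *_ = irls_logistic(X, y, w)
        X_rep = np.repeat(X, w.astype(int), axis=0)
        y_rep = np.repeat(y, w.astype(int))
        beta_r, *_ = irls_logistic(X_rep, y_rep)
        assert np.allclose(beta_w, beta_r, atol=1e-10)

    def test_outcome_recoding_negates_coefficients(self, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = (rng.random(n) < 0.5).astype(float)
        b1, *_ = irls_logistic(X, y)
        b2, *_ = irls_logistic(X, 1.0 - y)
        assert np.allclose(b1, -b2, atol=1e-9)

    def test_matches_reference_mle_on_random_fixtures(self, rng):
        import statsmodels.api as sm

        for trial in range(5):
            n = 150
            X = np.column_stack([
                np.ones(n),
                rng.integers(0, 2, n).astype(float),
                rng.normal(size=n),
                rng.random(n),
            ])
            eta = X @ np.array([-0.5, 0.8, -0.4, 0.6])
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            w = rng.uniform(0.5, 2.0, n)
            beta, *_ = irls_logistic(X, y, w)
            ref = sm.GLM(y, X, family=sm.families.Binomial(),
                         freq_weights=w).fit()
            assert np.allclose(beta, ref.params, atol=1e-6)

    def test_separation_raises_naming_term(self):
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        y = np.r_[np.zeros(4), np.ones(4)]
        with pytest.raises(ConvergenceError, match="x1"):
            irls_logistic(X, y, term_names=["const", "x1"])

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(DesignError):
            irls_logistic(X, y)


class TestParameterRecovery:
    def test_known_coefficients_recovered_at_5000(self, rng):
        # every covariate pattern of three binary covariates, n = 5000
        beta_true = np.array([-1.0, 0.7, -0.5, 1.2])
        n = 5000
        X = np.column_stack([
            np.ones(n),
            rng.integers(0, 2, n),
            rng.integers(0, 2, n),
            rng.integers(0, 2, n),
        ]).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        beta, cov, *_ = irls_logistic(X, y)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(beta - beta_true) < 3 * se)


class TestDatasetLevelFit:
    def test_constant_outcome_degenerate(self):
        rows = [make_row("seed", None)]
        rows += [make_row(f"r{i}", "seed") for i in range(3)]
        ds = build_dataset(rows)
        with pytest.raises(EstimationError, match="constant"):
            fit_weighted_logistic(ds, None, covariates=["pregnant"])

    def test_dichotomize_codings(self, tiny_dataset):
        d = dichotomize(tiny_dataset.participants)
        p = tiny_dataset.participants
        assert ((d["age_15_24"] == 1) == (p["age_group"] == "15-24")).all()
        assert ((d["college"] == 1) == (p["education"] == "college")).all()
        assert ((d["fair_poor_health"] == 1) ==
                p["self_rated_health"].isin(["fair", "poor"])).all()
        assert ((d["irregular"] == 1) == (p["migratory_status"] == "irregular")).all()


class TestBivariate:
    def test_two_by_two_prevalences(self):
        ds = two_by_two_dataset()
        table = bivariate_association(ds, None, "used_health_service_15d",
                                      "pregnant")
        assert table.prevalence[True] == pytest.approx(0.20)
        assert table.prevalence[False] == pytest.approx(0.10)
        assert table.df == 1
        assert table.p_value < 0.10  # Wald on a borderline 2x2

    def test_balanced_outcome_not_significant(self):
        rows = [make_row("seed", None)]
        i = 0
        for status in ("resident", "irregular"):
            for used in (True, False) * 10:
                rows.append(make_row(
                    f"r{i}", "seed" if i < 3 else f"r{i-3}",
                    migratory_status=status, used_health_service_15d=used,
                    reason_for_use="prenatal" if used else None))
                i += 1
        ds = build_dataset(rows)
        table = bivariate_association(ds, None, "used_health_service_15d",
                                      "migratory_status")
        assert table.prevalence["resident"] == pytest.approx(0.5)
        assert table.p_value > 0.99

    def test_constant_outcome_errors(self):
        rows = [make_row("seed", None)]
        rows += [make_row(f"r{i}", "seed") for i in range(3)]
        ds = build_dataset(rows)
        with pytest.raises(EstimationError):
            bivariate_association(ds, None, "used_health_service_15d",
                                  "migratory_status")


class TestReport:
    def test_or_row_and_reference_row(self):
        ds = two_by_two_dataset()
        fit = fit_weighted_logistic(ds, None, covariates=["pregnant"])
        report = odds_ratio_report(fit)
        shown = report[report["level"] == "yes"].iloc[0]
        assert shown["OR"] == pytest.approx(2.25, abs=1e-6)
        ref = report[report["level"] == "no"].iloc[0]
        assert ref["OR"] == 1.0
        assert np.isnan(ref["LL"]) and np.isnan(ref["UL"])
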