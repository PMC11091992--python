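"""Contingency building, closed-form cross-ratios, and the Newton fit.

The single-predictor design is saturated, so the maximum-likelihood
odds ratios must equal the analytic cross-ratios; statsmodels' MNLogit
serves as a second, independent implementation on the packaged table.
"""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from imckit import (
    CLASS_ORDER,
    PATTERN_ORDER,
    ValidationError,
    ZeroCellError,
    build_contingency,
    closed_form_or,
    fit_multinomial,
    study_labels,
)
from imckit.labels import IRREGULAR_PATTERNS


def random_table(rng, low=1, high=30):
    counts = rng.integers(low, high, size=(4, 5))
    return pd.DataFrame(counts, index=list(PATTERN_ORDER), columns=list(CLASS_ORDER))


class TestBuildContingency:
    def test_fixture_labels_roundtrip(self, counts):
        assert build_contingency(study_labels()).equals(counts)

    def test_single_item(self):
        table = build_contingency([("Normal", "Healthy")])
        assert table.to_numpy().sum() == 1
        assert table.at["Normal", "Healthy"] == 1

    def test_order_invariance(self, rng):
        labels = [
            (rng.choice(list(PATTERN_ORDER)), rng.choice(list(CLASS_ORDER)))
            for _ in range(200)
        ]
        shuffled = list(labels)
        rng.shuffle(shuffled)
        assert build_contingency(labels).equals(build_contingency(shuffled))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            build_contingency([])


class TestClosedForm:
    def test_valley_acl_cross_ratio(self, counts):
        or_, se = closed_form_or(counts, "Valley", "ACL")
        assert or_ == pytest.approx(17.500, abs=1e-9)   # 2*35 / (2*2)
        assert se == pytest.approx(1.236, abs=5e-4)

    def test_balanced_subtable_gives_unity(self):
        table = pd.DataFrame(3, index=list(PATTERN_ORDER), columns=list(CLASS_ORDER))
        or_, _ = closed_form_or(table, "Drop", "MS")
        assert or_ == pytest.approx(1.0)

    def test_zero_cell_raises(self, counts):
        table = counts.copy()
        table.at["Drop", "MS"] = 0
        with pytest.raises(ZeroCellError):
            closed_form_or(table, "Drop", "MS")

    def test_reference_levels_rejected(self, counts):
        with pytest.raises(ValidationError):
            closed_form_or(counts, "Normal", "ACL")
        with pytest.raises(ValidationError):
            closed_form_or(counts, "Valley", "Healthy")


class TestFitMultinomial:
    def test_matches_closed_form_on_random_tables(self):
        """Oracle equivalence: >= 100 random all-positive tables."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            table = random_table(rng)
            fit = fit_multinomial(table)
            for cls in CLASS_ORDER[:-1]:
                for pattern in IRREGULAR_PATTERNS:
                    oracle_or, oracle_se = closed_form_or(table, pattern, cls)
                    entry = fit.entry(cls, pattern)
                    assert entry.odds_ratio == pytest.approx(oracle_or, rel=1e-6)
                    assert entry.se == pytest.approx(oracle_se, rel=1e-6)

    def test_intercepts_are_log_reference_ratios(self, counts):
        fit = fit_multinomial(counts)
        for cls in CLASS_ORDER[:-1]:
            expected = math.log(
                counts.at["Normal", cls] / counts.at["Normal", "Healthy"]
            )
            assert fit.entry(cls, "Intercept").estimate == pytest.approx(expected, abs=1e-8)

    def test_fitted_probabilities_reproduce_row_frequencies(self, counts):
        """Saturated model: fitted conditional class probabilities equal
        the observed pattern-row frequencies."""
        fit = fit_multinomial(counts)
        observed = counts.div(counts.sum(axis=1), axis=0)
        assert np.allclose(fit.fitted_probs.to_numpy(), observed.to_numpy(), atol=1e-8)

    def test_matches_statsmodels_mnlogit(self, counts):
        """Independent implementation check on the packaged table."""
        rows = []
        for pattern in PATTERN_ORDER:
            for cls in CLASS_ORDER:
                for _ in range(int(counts.at[pattern, cls])):
                    rows.append((pattern, cls))
        frame = pd.DataFrame(rows, columns=["pattern", "cls"])
        endog = frame["cls"].map({c: i for i, c in enumerate(["Healthy"] + list(CLASS_ORDER[:-1]))})
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "Valley": (frame["pattern"] == "Valley").astype(float),
                "Drop": (frame["pattern"] == "Drop").astype(float),
                "Shaking": (frame["pattern"] == "Shaking").astype(float),
            }
        )
        res = sm.MNLogit(endog, exog).fit(method="newton", disp=False)
        fit = fit_multinomial(counts)
        for j, cls in enumerate(CLASS_ORDER[:-1]):
            for term, name in [(0, "Intercept"), (1, "Valley"), (2, "Drop"), (3, "Shaking")]:
                entry = fit.entry(cls, name)
                assert entry.estimate == pytest.approx(res.params.iloc[term, j], abs=1e-5)
                assert entry.se == pytest.approx(res.bse.iloc[term, j], abs=1e-4)

    def test_ci_and_p_consistency(self):
        """p < 0.05 iff the 95% CI excludes an odds ratio of 1."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            fit = fit_multinomial(random_table(rng))
            for e in fit.entries:
                if e.pattern_level == "Intercept":
                    continue
                if abs(abs(e.wald_z) - 1.96) < 1e-3:
                    continue  # knife-edge
                excluded = e.ci_lower > 1.0 or e.ci_upper < 1.0
                assert (e.p_value < 0.05) == excluded

    def test_independence_null_gives_small_log_ors(self):
        """Tables built from independent margins at large counts have
        cross-ratios near 1."""
        row = np.array([0.4, 0.2, 0.15, 0.25])
        col = np.array([0.1, 0.15, 0.2, 0.2, 0.35])
        table = pd.DataFrame(
            np.round(20000 * np.outer(row, col)).astype(int),
            index=list(PATTERN_ORDER),
            columns=list(CLASS_ORDER),
        )
        fit = fit_multinomial(table)
        for e in fit.entries:
            if e.pattern_level != "Intercept":
                assert abs(e.estimate) < 0.05

    def test_zero_cell_raises_unless_corrected(self, counts):
        table = counts.copy()
        table.at["Valley", "MS"] = 0
        with pytest.raises(ZeroCellError):
            fit_multinomial(table)
        fit = fit_multinomial(table, continuity_correction=True)
        a = table.at["Valley", "MS"] + 0.5
        b = table.at["Normal", "Healthy"] + 0.5
        c = table.at["Normal", "MS"] + 0.5
        d = table.at["Valley", "Healthy"] + 0.5
        assert fit.entry("MS", "Valley").odds_ratio == pytest.approx(a * b / (c * d), rel=1e-6)

    def test_invariants_on_entries(self, counts):
        for e in fit_multinomial(counts).entries:
            assert e.odds_ratio == pytest.approx(math.exp(e.estimate), rel=1e-9)
            assert e.ci_lower < e.odds_ratio < e.ci_upper
            assert 0.0 < e.p_value <= 1.0
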