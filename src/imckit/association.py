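"""Multinomial logistic regression of injury class on moment-curve pattern.

The design has a single categorical predictor (the four-level pattern,
Normal as reference) and a five-level outcome (injury class, Healthy as
reference), fitted to grouped counts of a 4 x 5 contingency table.  The
model is therefore *saturated*: the maximum-likelihood coefficients are
the log cross-ratios of the table,

    beta(pattern, class) = log( n[pattern, class] * n[Normal, Healthy]
                              / (n[Normal, class] * n[pattern, Healthy]) ),

with Wald standard errors equal to the square root of the sum of the
four reciprocal counts.  :func:`fit_multinomial` obtains the same
numbers by Newton-Raphson iteration on the grouped-count likelihood (and
is property-tested against the closed form); :func:`closed_form_or` is
the analytic oracle.

Inference is Wald throughout: 95% confidence intervals are
exp(estimate +/- z * SE) with the two-sided normal 97.5% quantile, and
p-values come from the normal tail of estimate / SE.  Zero cells make
the saturated solution diverge and raise :class:`ZeroCellError` unless
an explicit 0.5 continuity correction is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import FittingError, ValidationError, ZeroCellError
from .labels import (
    CLASS_ORDER,
    IRREGULAR_PATTERNS,
    PATTERN_ORDER,
    REFERENCE_CLASS,
    REFERENCE_PATTERN,
    validate_class,
    validate_pattern,
)

#: Two-sided normal 97.5% quantile used for the Wald 95% intervals.
Z_95 = float(norm.ppf(0.975))

_NONREF_CLASSES = tuple(c for c in CLASS_ORDER if c != REFERENCE_CLASS)


@dataclass(frozen=True)
class CoefficientEntry:
    """One term of the fitted model, in odds-ratio table layout."""

    outcome_class: str
    pattern_level: str  # "Valley", "Drop", "Shaking" or "Intercept"
    estimate: float
    se: float
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    wald_z: float
    p_value: float


@dataclass
class MultinomialFit:
    """Fit result: coefficient entries plus diagnostics."""

    entries: list[CoefficientEntry]
    fitted_probs: pd.DataFrame  # pattern x class conditional probabilities
    log_likelihood: float
    n_iter: int
    n_obs: int

    def entry(self, outcome_class: str, pattern_level: str) -> CoefficientEntry:
        for e in self.entries:
            if e.outcome_class == outcome_class and e.pattern_level == pattern_level:
                return e
        raise KeyError((outcome_class, pattern_level))

    def coefficients(self) -> pd.DataFrame:
        """Coefficient table with one row per (class, term)."""
        return pd.DataFrame(
            [
                {
                    "outcome_class": e.outcome_class,
                    "pattern_level": e.pattern_level,
                    "estimate": e.estimate,
                    "se": e.se,
                    "odds_ratio": e.odds_ratio,
                    "ci_lower": e.ci_lower,
                    "ci_upper": e.ci_upper,
                    "wald_z": e.wald_z,
                    "p_value": e.p_value,
                }
                for e in self.entries
            ]
        )


def build_contingency(labels: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Cross-tabulate ``(pattern, injury_class)`` pairs into the 4 x 5 table."""
    if len(labels) == 0:
        raise ValidationError("cannot build a contingency table from no labels")
    table = pd.DataFrame(0, index=list(PATTERN_ORDER), columns=list(CLASS_ORDER))
    for pattern, cls in labels:
        validate_pattern(pattern)
        validate_class(cls)
        table.at[pattern, cls] += 1
    return table


def _as_table(table: pd.DataFrame) -> pd.DataFrame:
    out = table.reindex(index=list(PATTERN_ORDER), columns=list(CLASS_ORDER))
    if out.isna().any().any():
        raise ValidationError(
            "contingency table must have pattern rows "
            f"{PATTERN_ORDER} and class columns {CLASS_ORDER}"
        )
    arr = out.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    if arr.sum() <= 0:
        raise ValidationError("contingency table is empty")
    return out


def closed_form_or(
    table: pd.DataFrame, pattern: str, outcome: str
) -> tuple[float, float]:
    """Analytic odds ratio and SE(log OR) for the saturated design.

    Returns the cross-ratio of the 2 x 2 sub-table formed by
    {pattern, Normal} x {outcome, Healthy} and the usual
    sqrt(sum of reciprocal counts) standard error.

    Raises
    ------
    ZeroCellError
        If any of the four cells is zero (the caller may apply a
        continuity correction explicitly and retry).
    """
    validate_pattern(pattern)
    validate_class(outcome)
    if pattern == REFERENCE_PATTERN or outcome == REFERENCE_CLASS:
        raise ValidationError("pattern and outcome must be non-reference levels")
    t = _as_table(table)
    a = float(t.at[pattern, outcome])
    b = float(t.at[REFERENCE_PATTERN, REFERENCE_CLASS])
    c = float(t.at[REFERENCE_PATTERN, outcome])
    d = float(t.at[pattern, REFERENCE_CLASS])
    if min(a, b, c, d) <= 0:
        raise ZeroCellError(
            f"zero cell in the {pattern}/{outcome} cross-ratio; "
            "use a continuity correction explicitly if appropriate"
        )
    return (a * b) / (c * d), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def _newton_fit(counts: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Newton-Raphson on the grouped multinomial-logit log-likelihood.

    ``counts`` is patterns x classes with the reference class last.
    Returns (beta[(K-1) x p], covariance[(K-1)p x (K-1)p], loglik, iters).
    """
    n_pat, n_cls = counts.shape
    x = np.zeros((n_pat, n_pat))
    x[:, 0] = 1.0
    for i in range(1, n_pat):
        x[i, i] = 1.0  # dummy for each irregular pattern
    row_tot = counts.sum(axis=1)
    k = n_cls - 1  # non-reference classes
    p = x.shape[1]
    beta = np.zeros((k, p))
    gtol = tol * max(1.0, float(counts.sum()))  # gradient is in count units

    def probs(b: np.ndarray) -> np.ndarray:
        eta = np.hstack([x @ b.T, np.zeros((n_pat, 1))])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    def loglik(b: np.ndarray) -> float:
        pr = probs(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(counts > 0, counts * np.log(pr), 0.0)
        return float(terms.sum())

    ll = loglik(beta)
    it = 0
    for it in range(1, max_iter + 1):
        pr = probs(beta)
        grad = np.concatenate(
            [x.T @ (counts[:, j] - row_tot * pr[:, j]) for j in range(k)]
        )
        if np.max(np.abs(grad)) < gtol:
            break
        hess = np.zeros((k * p, k * p))
        for a_ in range(k):
            for b_ in range(k):
                w = row_tot * pr[:, a_] * ((1.0 if a_ == b_ else 0.0) - pr[:, b_])
                hess[a_ * p : (a_ + 1) * p, b_ * p : (b_ + 1) * p] = -(x.T * w) @ x
        try:
            step = np.linalg.solve(hess, -grad).reshape(k, p)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by zero-cell check
            raise FittingError(f"singular Hessian at iteration {it}: {exc}") from exc
        # Step-halving safeguards the ascent far from the optimum.
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = loglik(candidate)
            if ll_new >= ll - 1e-12:
                beta, ll = candidate, ll_new
                break
            scale /= 2.0
        else:  # pragma: no cover
            raise FittingError(f"step-halving failed at iteration {it}")
    else:
        raise FittingError(
            f"Newton iteration did not converge in {max_iter} iterations "
            f"(last gradient norm {np.max(np.abs(grad)):.3e})"
        )

    pr = probs(beta)
    hess = np.zeros((k * p, k * p))
    for a_ in range(k):
        for b_ in range(k):
            w = row_tot * pr[:, a_] * ((1.0 if a_ == b_ else 0.0) - pr[:, b_])
            hess[a_ * p : (a_ + 1) * p, b_ * p : (b_ + 1) * p] = -(x.T * w) @ x
    cov = np.linalg.inv(-hess)
    return beta, cov, ll, it


def fit_multinomial(
    table: pd.DataFrame,
    continuity_correction: bool = False,
    z: float = Z_95,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MultinomialFit:
    """Fit the saturated multinomial logit to a pattern x class count table.

    Parameters
    ----------
    table : DataFrame
        4 x 5 counts (patterns x classes).
    continuity_correction : bool
        If True, add 0.5 to *every* cell before fitting (opt-in remedy
        for zero cells; never applied silently).
    z : float
        Normal quantile for the 95% Wald intervals.

    Raises
    ------
    ZeroCellError
        If any cell is zero and no continuity correction was requested
        (the saturated MLE diverges).
    FittingError
        If the Newton iteration fails to converge.
    """
    t = _as_table(table)
    counts = t.to_numpy(dtype=float)
    if continuity_correction:
        counts = counts + 0.5
    if (counts <= 0).any():
        raise ZeroCellError(
            "saturated multinomial fit requires every cell to be positive; "
            "pass continuity_correction=True to add 0.5 to all cells"
        )

    beta, cov, ll, it = _newton_fit(counts, tol=tol, max_iter=max_iter)
    se = np.sqrt(np.diag(cov)).reshape(beta.shape)

    term_names = ("Intercept",) + tuple(IRREGULAR_PATTERNS)
    entries: list[CoefficientEntry] = []
    for ci, cls in enumerate(_NONREF_CLASSES):
        for ti, term in enumerate(term_names):
            est = float(beta[ci, ti])
            s = float(se[ci, ti])
            zval = est / s if s > 0 else math.inf
            entries.append(
                CoefficientEntry(
                    outcome_class=cls,
                    pattern_level=term,
                    estimate=est,
                    se=s,
                    odds_ratio=math.exp(est),
                    ci_lower=math.exp(est - z * s),
                    ci_upper=math.exp(est + z * s),
                    wald_z=zval,
                    p_value=float(2.0 * norm.sf(abs(zval))),
                )
            )

    eta = np.zeros((len(PATTERN_ORDER), len(CLASS_ORDER)))
    x = np.zeros((len(PATTERN_ORDER), len(PATTERN_ORDER)))
    x[:, 0] = 1.0
    for i in range(1, len(PATTERN_ORDER)):
        x[i, i] = 1.0
    eta[:, : len(_NONREF_CLASSES)] = x @ beta.T
    e = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    # Column order of eta: non-reference classes then the reference.
    fitted = pd.DataFrame(
        probs,
        index=list(PATTERN_ORDER),
        columns=list(_NONREF_CLASSES) + [REFERENCE_CLASS],
    )[list(CLASS_ORDER)]

    return MultinomialFit(
        entries=entries,
        fitted_probs=fitted,
        log_likelihood=ll,
        n_iter=it,
        n_obs=int(round(t.to_numpy().sum())),
    )
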