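"""Covariate-adjusted general linear models for disease effects.

All inference is ordinary least squares with two-sided t tests. Disease
effects on a network measure are estimated with the binary ADCI and
LBCI flags plus six covariates (age, sex, education, DWMH, PWMH, ICV);
an ADCI x LBCI interaction term (1 only for the mixed group) is screened
at alpha = 0.05, and when it is not significant the model with the lower
AIC is kept. Multiple testing across the 92 nodes, or across the 14
neuropsychological tests, is controlled with Benjamini-Hochberg FDR.

AIC is computed as n*ln(RSS/n) + 2k (Gaussian OLS up to an additive
constant, k counting all coefficients including the intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .cohort import COGNITION_TESTS, COVARIATES, validate_cohort_frame

__all__ = [
    "GlmFit",
    "EffectTable",
    "fit_glm",
    "disease_effect_model",
    "select_model_by_aic",
    "groupwise_contrast",
    "fdr_correct",
    "cognition_models",
    "batch_ols",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


class RankDeficientDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class GlmFit:
    """Results of one ordinary-least-squares fit."""

    outcome: str
    predictors: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    n: int
    df_resid: int
    rss: float
    aic: float

    def coef(self, name: str) -> tuple[float, float, float]:
        """(beta, SE, p) for one predictor."""
        i = self.predictors.index(name)
        return float(self.params[i]), float(self.bse[i]), float(self.pvalues[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "beta": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            f"OLS fit: {self.outcome}  (n={self.n}, df_resid={self.df_resid}, "
            f"AIC={self.aic:.2f})",
            f"{'predictor':<22}{'beta':>12}{'SE':>12}{'t':>9}{'p':>10}",
        ]
        for i, name in enumerate(self.predictors):
            lines.append(
                f"{name:<22}{self.params[i]:>12.4g}{self.bse[i]:>12.4g}"
                f"{self.tvalues[i]:>9.3f}{self.pvalues[i]:>10.4f}"
            )
        return "\n".join(lines)


@dataclass
class EffectTable:
    """Rows of (outcome, predictor, beta, se, p, p_fdr) with an FDR scope."""

    table: pd.DataFrame
    scope: str = "none"  # e.g. "92 nodes", "14 tests", "none"

    def significant(self, q: float = ALPHA) -> pd.DataFrame:
        col = "p_fdr" if "p_fdr" in self.table.columns else "p"
        return self.table[self.table[col] < q]


def _ols_aic(n: int, rss: float, k: int) -> float:
    if rss <= 0:
        return float("-inf")
    return n * float(np.log(rss / n)) + 2 * k


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # QR with column pivoting: columns pivoted past the rank are the
        # ones expressible from the others.
        _, _, piv = linalg.qr(x, mode="economic", pivoting=True)
        collinear = [design.columns[i] for i in piv[rank:]]
        raise RankDeficientDesignError(
            f"design matrix is rank deficient; collinear columns: {collinear}"
        )


def fit_glm(y: np.ndarray | pd.Series, design: pd.DataFrame, outcome: str = "y") -> GlmFit:
    """OLS of ``y`` on ``design`` (an intercept is added if absent).

    Rows with missing values in either side are dropped (logged).
    """
    y = pd.Series(np.asarray(y, float), index=design.index, name=outcome)
    if "const" not in design.columns:
        design = sm.add_constant(design, has_constant="add")
    mask = design.notna().all(axis=1) & y.notna()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("fit_glm(%s): dropped %d row(s) with missing values", outcome, dropped)
    design = design.loc[mask]
    y = y.loc[mask]
    n, k = design.shape
    if n <= k + 1:
        raise ValueError(f"too few rows (n={n}) for {k} predictors")
    _check_rank(design)
    res = sm.OLS(y.to_numpy(), design.to_numpy(float)).fit()
    rss = float(res.ssr)
    return GlmFit(
        outcome=outcome,
        predictors=list(design.columns),
        params=np.asarray(res.params, float),
        bse=np.asarray(res.bse, float),
        tvalues=np.asarray(res.tvalues, float),
        pvalues=np.asarray(res.pvalues, float),
        n=n,
        df_resid=int(res.df_resid),
        rss=rss,
        aic=_ols_aic(n, rss, k),
    )


def batch_ols(
    x: np.ndarray, y: np.ndarray, predictors: list[str] | None = None
) -> dict[str, np.ndarray]:
    """OLS of many outcomes on one design, vectorized.

    ``x`` is (n, k) including the intercept column; ``y`` is (n, q).
    Returns arrays of shape (k, q) for betas/SEs/t/p plus per-outcome
    ``rss`` and ``aic``. Used for the 92-node sweeps; agrees with
    :func:`fit_glm` outcome by outcome.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    n, k = x.shape
    if np.linalg.matrix_rank(x) < k:
        raise RankDeficientDesignError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    rss = (resid**2).sum(axis=0)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    # constant outcomes (zero residual and zero beta) carry no evidence
    t = np.where(se > 0, t, np.where(beta == 0, 0.0, np.where(beta > 0, np.inf, -np.inf)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    aic = np.where(rss > 0, n * np.log(np.where(rss > 0, rss, 1.0) / n) + 2 * k, -np.inf)
    return {
        "predictors": predictors or [f"x{i}" for i in range(k)],
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "rss": rss,
        "df_resid": df,
        "aic": aic,
    }


def _covariate_design(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[list(COVARIATES)].astype(float)


def disease_effect_model(
    values: np.ndarray | pd.Series,
    cohort: pd.DataFrame,
    with_interaction: bool = False,
    outcome: str = "measure",
) -> GlmFit:
    """Independent (and optionally interaction) effects of ADCI and LBCI.

    Predictors are the two binary disease flags and the six covariates;
    ``with_interaction`` adds ADCI x LBCI, which is 1 for the mixed
    group only.
    """
    validate_cohort_frame(cohort, require_cognition=False)
    if cohort["group"].nunique() < 2:
        raise ValueError("cohort must contain at least two groups")
    design = pd.DataFrame(
        {"adci": cohort["adci"].astype(float), "lbci": cohort["lbci"].astype(float)},
        index=cohort.index,
    )
    if with_interaction:
        design["adci_x_lbci"] = design["adci"] * design["lbci"]
    design = pd.concat([design, _covariate_design(cohort)], axis=1)
    return fit_glm(values, design, outcome=outcome)


def select_model_by_aic(
    fit_with: GlmFit,
    fit_without: GlmFit,
    interaction_p: float,
    alpha: float = ALPHA,
) -> tuple[GlmFit, dict]:
    """Interaction-screening rule.

    Keep the interaction model when its term is significant at
    ``alpha``; otherwise keep whichever model has the lower AIC, with
    the simpler model winning AIC ties.
    """
    if fit_with.n != fit_without.n:
        raise ValueError("models were fit on different rows")
    if interaction_p < alpha:
        chosen, why = fit_with, f"interaction p={interaction_p:.4g} < {alpha}"
    elif fit_without.aic <= fit_with.aic:
        chosen, why = (
            fit_without,
            f"interaction ns (p={interaction_p:.4g}); AIC {fit_without.aic:.2f} <= "
            f"{fit_with.aic:.2f}",
        )
    else:
        chosen, why = (
            fit_with,
            f"interaction ns (p={interaction_p:.4g}); AIC with interaction "
            f"{fit_with.aic:.2f} < {fit_without.aic:.2f}",
        )
    rationale = {
        "outcome": fit_with.outcome,
        "interaction_p": float(interaction_p),
        "aic_with": fit_with.aic,
        "aic_without": fit_without.aic,
        "chosen": "with_interaction" if chosen is fit_with else "without_interaction",
        "reason": why,
    }
    return chosen, rationale


def groupwise_contrast(
    values: np.ndarray | pd.Series,
    cohort: pd.DataFrame,
    group_a: str,
    group_b: str,
    outcome: str = "measure",
) -> GlmFit:
    """Two-group comparison (indicator for ``group_b``) with covariates."""
    if group_a == group_b:
        raise ValueError("cannot contrast a group with itself")
    sub = cohort[cohort["group"].isin([group_a, group_b])]
    for g in (group_a, group_b):
        if not (sub["group"] == g).any():
            raise ValueError(f"group {g!r} is empty")
    values = pd.Series(np.asarray(values, float), index=cohort.index).loc[sub.index]
    design = pd.DataFrame(
        {"group": (sub["group"] == group_b).astype(float)}, index=sub.index
    )
    design = pd.concat([design, _covariate_design(sub)], axis=1)
    return fit_glm(values, design, outcome=outcome)


def fdr_correct(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cognition_models(
    cohort: pd.DataFrame,
    predictor: np.ndarray | pd.Series,
    predictor_name: str = "network_measure",
    model2_disease: str | None = None,
) -> dict[str, EffectTable]:
    """Per-test GLMs of the 14 cognition scores on a network measure.

    Model 1 adjusts for the six covariates; Model 2 additionally
    controls for the named disease flag (``"adci"`` or ``"lbci"``).
    Each model's 14 predictor p-values are FDR-corrected across the
    battery. Returns ``{"model1": ..., "model2": ...}`` (``model2``
    present only when requested).
    """
    validate_cohort_frame(cohort, require_cognition=False)
    missing = [t for t in COGNITION_TESTS if t not in cohort.columns]
    if missing:
        raise ValueError(f"missing cognition score columns: {missing}")
    predictor = pd.Series(np.asarray(predictor, float), index=cohort.index)

    def _one_model(extra_flag: str | None) -> EffectTable:
        rows = []
        for test in COGNITION_TESTS:
            design = pd.DataFrame({predictor_name: predictor}, index=cohort.index)
            if extra_flag is not None:
                design[extra_flag] = cohort[extra_flag].astype(float)
            design = pd.concat([design, _covariate_design(cohort)], axis=1)
            fit = fit_glm(cohort[test], design, outcome=test)
            beta, se, p = fit.coef(predictor_name)
            rows.append(
                {"outcome": test, "predictor": predictor_name, "beta": beta, "se": se, "p": p}
            )
        df = pd.DataFrame(rows)
        df["p_fdr"] = fdr_correct(df["p"].to_numpy())
        return EffectTable(df, scope="14 tests")

    out = {"model1": _one_model(None)}
    if model2_disease is not None:
        if model2_disease not in ("adci", "lbci"):
            raise ValueError("model2_disease must be 'adci' or 'lbci'")
        out["model2"] = _one_model(model2_disease)
    return out
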