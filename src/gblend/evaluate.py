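"""Empirical accuracy and bias of predictions on the masked test set.

Accuracy: EBV and phenotype are each residualized on the test set's own
sex and hatch-week fixed effects, their Pearson correlation is taken, and
the correlation is divided by sqrt(h2) to approximate the accuracy of
predicting the true breeding value.  Bias: the regression coefficient of
phenotype on EBV in a fixed linear model with sex and hatch week; 1 means
no bias, < 1 means EBV differences over-predict phenotypic differences.

``predict_lambda_theory`` gives the deterministic blending weight
lambda = m / (m + k) for m markers, with k = 50 (VanRaden's prediction
error variance of full-sib genome sharing) or k = M_e, the effective
number of independent chromosome segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EvaluationResult",
    "TheoryParams",
    "empirical_accuracy",
    "prediction_bias",
    "evaluate_predictions",
    "predict_lambda_theory",
]


@dataclass
class EvaluationResult:
    empirical_accuracy: float = np.nan
    residual_correlation: float = np.nan
    bias_coefficient: float = np.nan
    bias_se: float = np.nan
    n_tst: int = 0
    h2_used: float = np.nan


def _tst_frame(ebv: pd.Series, phenotypes: pd.DataFrame) -> pd.DataFrame:
    phen = phenotypes
    if "subset" in phen.columns and (phen["subset"] == "TST").any():
        phen = phen.loc[phen["subset"] == "TST"]
    df = phen.set_index("id").copy()
    df["ebv"] = ebv.reindex(df.index)
    if df["ebv"].isna().any():
        raise KeyError("EBV missing for some test individuals")
    return df.reset_index()


def _fixed_design(df: pd.DataFrame) -> np.ndarray:
    """TST-only design: intercept + sex + hatch-week dummies.

    Levels are those present in the test set itself; singleton hatch
    weeks are retained as their own levels (zero residual contribution).
    """
    from .mixedmodel import design_matrix

    X, _ = design_matrix(df, ("sex", "hatch_week"))
    return X


def empirical_accuracy(
    ebv: pd.Series, phenotypes: pd.DataFrame, h2: float
) -> EvaluationResult:
    """Residual correlation of EBV with phenotype, scaled by 1/sqrt(h2).

    The value is reported uncapped: an estimate above 1 signals
    miscalibration rather than being truncated away.
    """
    if not h2 > 0:
        raise ValueError("h2 must be > 0")
    df = _tst_frame(ebv, phenotypes)
    if len(df) < 3:
        raise ValueError("need >= 3 test records")
    X = _fixed_design(df)
    Q, _ = np.linalg.qr(X)

    def resid(v):
        v = np.asarray(v, dtype=float)
        return v - Q @ (Q.T @ v)

    re_ = resid(df["ebv"])
    ry = resid(df["bwt"])
    if np.std(re_) < 1e-12:
        raise ValueError("EBV residuals are constant; correlation undefined")
    r = float(np.corrcoef(re_, ry)[0, 1])
    return EvaluationResult(
        empirical_accuracy=r / np.sqrt(h2),
        residual_correlation=r,
        n_tst=len(df),
        h2_used=h2,
    )


def prediction_bias(ebv: pd.Series, phenotypes: pd.DataFrame) -> EvaluationResult:
    """Regression of test phenotype on EBV with sex and hatch-week effects."""
    df = _tst_frame(ebv, phenotypes)
    if len(df) < 3:
        raise ValueError("need >= 3 test records")
    X = _fixed_design(df)
    e = df["ebv"].to_numpy(dtype=float)
    # collinearity of EBV with the fixed-effect design is unrecoverable
    Q, _ = np.linalg.qr(X)
    if np.std(e - Q @ (Q.T @ e)) < 1e-12:
        raise ValueError("EBV collinear with fixed-effect design")
    design = np.column_stack([e, X])
    fit = sm.OLS(df["bwt"].to_numpy(dtype=float), design).fit()
    return EvaluationResult(
        bias_coefficient=float(fit.params[0]),
        bias_se=float(fit.bse[0]),
        n_tst=len(df),
    )


def evaluate_predictions(
    ebv: pd.Series, phenotypes: pd.DataFrame, h2: float
) -> EvaluationResult:
    """Accuracy and bias in one result object."""
    acc = empirical_accuracy(ebv, phenotypes, h2)
    bias = prediction_bias(ebv, phenotypes)
    return EvaluationResult(
        empirical_accuracy=acc.empirical_accuracy,
        residual_correlation=acc.residual_correlation,
        bias_coefficient=bias.bias_coefficient,
        bias_se=bias.bias_se,
        n_tst=acc.n_tst,
        h2_used=h2,
    )


@dataclass
class TheoryParams:
    """Inputs of the deterministic lambda predictor lambda = m/(m+k)."""

    m: int
    k: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")


def predict_lambda_theory(params: TheoryParams) -> float:
    """Deterministic composite weighting factor m / (m + k)."""
    return params.m / (params.m + params.k)
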