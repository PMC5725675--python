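"""REML estimation and BLUP prediction for the animal model.

Model: y = X tau + Z u + e with u ~ MVN(0, V_A * M) and e ~ MVN(0, V_E * I),
one record per individual (Z selects phenotyped rows of M).  Estimation
profiles the variance ratio gamma = V_A / V_E: after one symmetric
eigendecomposition of the (clamped) training submatrix of M, each gamma
evaluation is O(n p^2) and V_E has a closed form, so the restricted
likelihood is maximized by a bracketed one-dimensional search on
log(gamma).

The reported log-likelihood is the full restricted log-likelihood of the
error contrasts, logL = -1/2 [ (n-p) log 2*pi + log|V| + log|X' V^-1 X|
- log|X'X| + y'Py ], i.e. the density of B'y for any orthonormal basis B
of the null space of X'.  All terms depending on the relationship matrix
are included and the convention is identical across fits, so profiles
over the blending weight lambda are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .datatypes import RelationshipMatrix
from .relmat import blend

__all__ = ["RemlFit", "LambdaProfile", "reml_fit", "predict_ebv", "profile_lambda",
           "design_matrix"]

log = logging.getLogger(__name__)

#: eigenvalues of M below this are clamped (rank-deficient G_LD, blends)
EIG_FLOOR = 1e-8
#: support-interval rule: 2 * (logL_peak - logL) below the chi2(1) 0.95
#: critical value keeps lambda in the interval
CHI2_1_95 = 3.84


def design_matrix(
    phenotypes: pd.DataFrame, fixed: tuple[str, ...] = ("sex", "hatch_week")
) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded dummies, levels ordered by appearance.

    Single-level factors contribute no columns; the first-seen level of
    each factor is the reference.
    """
    cols = [np.ones(len(phenotypes))]
    names = ["intercept"]
    for f in fixed:
        codes, levels = pd.factorize(phenotypes[f])
        for k in range(1, len(levels)):
            cols.append((codes == k).astype(float))
            names.append(f"{f}[{levels[k]}]")
    X = np.column_stack(cols)
    # drop exactly collinear columns (e.g. a hatch week confounded with sex)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10
    if not keep.all():
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
    return X, names


@dataclass
class RemlFit:
    """Variance components, likelihood and fixed effects of one REML fit."""

    V_A: float
    V_E: float
    h2: float
    logL: float
    se_VA: float
    se_VE: float
    se_h2: float
    gamma: float
    tau: pd.Series
    converged: bool
    boundary: bool
    flat_likelihood: bool
    n: int
    p: int
    n_clamped_eigenvalues: int
    meta: dict = field(default_factory=dict)
    ebv: pd.Series | None = None
    # private solver state reused by predict_ebv
    _state: dict = field(default_factory=dict, repr=False)


def _restricted_m2ll(VA, VE, d, yt, Xt, logdet_XtX):
    """-2 * restricted logL at (V_A, V_E) in the eigenbasis of M."""
    v = VA * d + VE
    if (v <= 0).any() or VE <= 0:
        return np.inf
    vinv = 1.0 / v
    XtVX = Xt.T @ (Xt * vinv[:, None])
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, Xt.T @ (yt * vinv))
    r = yt - Xt @ beta
    yPy = float(r @ (r * vinv))
    n, p = len(yt), Xt.shape[1]
    return (
        (n - p) * np.log(2.0 * np.pi)
        + np.log(v).sum()
        + logdet_XtVX
        - logdet_XtX
        + yPy
    )


def reml_fit(
    phenotypes: pd.DataFrame,
    M: RelationshipMatrix,
    fixed: tuple[str, ...] = ("sex", "hatch_week"),
    response: str = "bwt",
    gamma_bounds: tuple[float, float] = (1e-6, 1e6),
    xtol: float = 1e-8,
) -> RemlFit:
    """REML variance components by profiling gamma = V_A / V_E.

    ``phenotypes`` must already be restricted to the training set; ids
    must all be present in ``M`` (which may cover more individuals).
    """
    phen = phenotypes.reset_index(drop=True)
    if len(phen) < 2:
        raise ValueError("need >= 2 phenotyped individuals")
    idx = pd.Index(M.ids).get_indexer(pd.Index(phen["id"]))
    if (idx < 0).any():
        raise KeyError("phenotyped ids missing from the relationship matrix")
    Mtrn = M.values[np.ix_(idx, idx)]
    y = phen[response].to_numpy(dtype=float)
    X, names = design_matrix(phen, fixed)
    n, p = len(y), X.shape[1]
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")

    d, U = np.linalg.eigh(Mtrn)
    n_clamped = int((d < EIG_FLOOR).sum())
    d = np.maximum(d, EIG_FLOOR)
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_XtX = np.linalg.slogdet(X.T @ X)

    def m2ll_gamma(loggamma):
        g = np.exp(loggamma)
        # closed-form V_E at fixed gamma: sigma2 = y'P1 y / (n - p) with
        # H = gamma*M + I
        h = g * d + 1.0
        hinv = 1.0 / h
        XtHX = Xt.T @ (Xt * hinv[:, None])
        sign, logdet_XtHX = np.linalg.slogdet(XtHX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtHX, Xt.T @ (yt * hinv))
        r = yt - Xt @ beta
        q = float(r @ (r * hinv))
        s2 = q / (n - p)
        return (
            (n - p) * (np.log(2.0 * np.pi) + 1.0 + np.log(s2))
            + np.log(h).sum()
            + logdet_XtHX
            - logdet_XtX
        )

    lo, hi = np.log(gamma_bounds[0]), np.log(gamma_bounds[1])
    res = minimize_scalar(
        m2ll_gamma, bounds=(lo, hi), method="bounded",
        options={"xatol": xtol * (hi - lo)},
    )
    loggam = float(res.x)
    # flatness / boundary diagnostics on a coarse grid
    grid = np.array([m2ll_gamma(v) for v in np.linspace(lo, hi, 9)])
    flat = float(np.nanmax(grid) - np.nanmin(grid)) < 1e-6
    boundary = (loggam - lo) < 1e-3 * (hi - lo) or (hi - loggam) < 1e-3 * (hi - lo)
    if flat:
        log.warning("restricted likelihood is flat in gamma (M proportional to I?)")
    if boundary:
        log.warning("gamma solution at search boundary (V_A near 0 or V_E negligible)")

    gamma = float(np.exp(loggam))
    h = gamma * d + 1.0
    hinv = 1.0 / h
    XtHX = Xt.T @ (Xt * hinv[:, None])
    beta = np.linalg.solve(XtHX, Xt.T @ (yt * hinv))
    r = yt - Xt @ beta
    VE = float(r @ (r * hinv)) / (n - p)
    VA = gamma * VE
    logL = -0.5 * m2ll_gamma(loggam)

    # observed information of the 2-parameter restricted likelihood
    se_VA = se_VE = se_h2 = np.nan
    if not flat:
        step_A = max(1e-4, 1e-4 * max(VA, VE))
        step_E = max(1e-4, 1e-4 * VE)

        def f(a, e):
            return 0.5 * _restricted_m2ll(a, e, d, yt, Xt, logdet_XtX)

        H = np.empty((2, 2))
        f0 = f(VA, VE)
        H[0, 0] = (f(VA + step_A, VE) - 2 * f0 + f(VA - step_A, VE)) / step_A**2
        H[1, 1] = (f(VA, VE + step_E) - 2 * f0 + f(VA, VE - step_E)) / step_E**2
        H[0, 1] = H[1, 0] = (
            f(VA + step_A, VE + step_E)
            - f(VA + step_A, VE - step_E)
            - f(VA - step_A, VE + step_E)
            + f(VA - step_A, VE - step_E)
        ) / (4 * step_A * step_E)
        try:
            cov = np.linalg.inv(H)
            if cov[0, 0] > 0 and cov[1, 1] > 0:
                se_VA = float(np.sqrt(cov[0, 0]))
                se_VE = float(np.sqrt(cov[1, 1]))
                tot = VA + VE
                grad = np.array([VE, -VA]) / tot**2
                var_h2 = float(grad @ cov @ grad)
                se_h2 = float(np.sqrt(var_h2)) if var_h2 > 0 else np.nan
        except np.linalg.LinAlgError:
            pass

    tau = pd.Series(beta, index=names, name="tau_hat")
    fit = RemlFit(
        V_A=VA,
        V_E=VE,
        h2=VA / (VA + VE),
        logL=float(logL),
        se_VA=se_VA,
        se_VE=se_VE,
        se_h2=se_h2,
        gamma=gamma,
        tau=tau,
        converged=bool(res.success) and not flat,
        boundary=boundary,
        flat_likelihood=flat,
        n=n,
        p=p,
        n_clamped_eigenvalues=n_clamped,
        meta={
            "logL_convention": "full restricted logL incl. -(n-p)/2 log 2pi "
            "and -1/2(log|X'V^-1X| - log|X'X|)",
            "eig_floor": EIG_FLOOR,
        },
        _state={
            "U": U,
            "d": d,
            "X": X,
            "y": y,
            "beta": beta,
            "trn_ids": phen["id"].to_numpy(),
        },
    )
    return fit


def predict_ebv(
    fit: RemlFit,
    M_full: RelationshipMatrix,
    trn_ids=None,
    all_ids=None,
) -> pd.Series:
    """BLUP breeding values for all individuals given training phenotypes.

    u_hat = V_A * M[:, TRN] V^-1 (y - X tau_hat) with
    V = V_A * M_TRN + V_E * I; equals the mixed-model-equations solution
    for the training individuals.
    """
    st = fit._state
    trn_ids = st["trn_ids"] if trn_ids is None else np.asarray(trn_ids)
    all_ids = M_full.ids if all_ids is None else np.asarray(all_ids)
    col = pd.Index(M_full.ids).get_indexer(pd.Index(trn_ids))
    row = pd.Index(M_full.ids).get_indexer(pd.Index(all_ids))
    if (col < 0).any() or (row < 0).any():
        raise KeyError("ids absent from the full relationship matrix")
    resid = st["y"] - st["X"] @ st["beta"]
    if fit.V_A == 0:
        return pd.Series(np.zeros(len(all_ids)), index=all_ids, name="ebv")
    U, d = st["U"], st["d"]
    vinv_r = U @ ((U.T @ resid) / (fit.V_A * d + fit.V_E))
    u = fit.V_A * (M_full.values[np.ix_(row, col)] @ vinv_r)
    ebv = pd.Series(u, index=all_ids, name="ebv")
    fit.ebv = ebv
    return ebv


@dataclass
class LambdaProfile:
    """Grid of REML fits over the blending weight lambda."""

    table: pd.DataFrame  # lambda, logL, VA, seVA, VE, seVE, h2, seh2, converged
    fits: dict
    peak_lambda: float
    support_interval: tuple[float, float]
    sequence: str = ""
    failures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.support_interval
        if not (lo <= self.peak_lambda <= hi):
            raise ValueError("support interval must contain the peak")


def profile_lambda(
    M1: RelationshipMatrix,
    M2: RelationshipMatrix,
    phenotypes: pd.DataFrame,
    grid_step: float = 0.1,
    sequence: str = "",
    fixed: tuple[str, ...] = ("sex", "hatch_week"),
) -> LambdaProfile:
    """Profile the restricted likelihood over M(lambda) = lam*M1 + (1-lam)*M2.

    The grid runs from 0 to 1 inclusive; the peak is the grid argmax of
    logL (ties broken toward smaller lambda) and the 95% support interval
    is the [min, max] of grid points whose doubled logL drop from the
    peak is below 3.84.  Failed fits are excluded from the peak search
    and reported in ``failures``.
    """
    n_steps = int(round(1.0 / grid_step))
    grid = np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)
    fits: dict[float, RemlFit] = {}
    failures: dict[float, str] = {}
    rows = []
    for lam in grid:
        try:
            fit = reml_fit(phenotypes, blend(M1, M2, float(lam)), fixed=fixed)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            log.warning("lambda=%.2f fit failed: %s", lam, exc)
            failures[float(lam)] = str(exc)
            continue
        fits[float(lam)] = fit
        rows.append(
            {
                "lambda": float(lam),
                "logL": fit.logL,
                "VA": fit.V_A,
                "seVA": fit.se_VA,
                "VE": fit.V_E,
                "seVE": fit.se_VE,
                "h2": fit.h2,
                "seh2": fit.se_h2,
                "converged": fit.converged,
            }
        )
    if not rows:
        raise RuntimeError("every lambda fit failed")
    table = pd.DataFrame(rows)
    peak_logL = table["logL"].max()
    peak_lambda = float(table.loc[table["logL"] == peak_logL, "lambda"].min())
    inside = table.loc[2.0 * (peak_logL - table["logL"]) < CHI2_1_95, "lambda"]
    interval = (float(inside.min()), float(inside.max()))
    return LambdaProfile(table, fits, peak_lambda, interval, sequence, failures)
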