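"""Multivariate random-effects meta-regression by REML.

Each location contributes an outcome vector ``y_i`` (a reduced coefficient
set, k = 3 or 4), its within-location covariance ``S_i`` from the first
stage, and meta-covariates ``x_i`` (country indicators plus summer
temperature mean and range).  The model is

    y_i ~ N(X_i b, S_i + Psi),    X_i = x_i' (kron) I_k,

with an unstructured between-location covariance ``Psi`` estimated by
restricted maximum likelihood on its Cholesky factor (quasi-Newton with the
analytic gradient), and fixed effects by GLS at the REML solution.  Downstream
utilities produce country-level predictions, empirical best linear unbiased
predictions (BLUPs), and the multivariate Wald test of the pooled interaction
coefficients (null: no within-summer change in the exposure-response curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MetaInput",
    "MetaFit",
    "build_meta_design",
    "fit_mvmeta_reml",
    "predict_country",
    "blup",
    "wald_test_interaction",
]

_RIDGE = 1e-10


@dataclass(frozen=True)
class MetaInput:
    """Stacked second-stage inputs for ``n`` locations.

    ``y``: (n, k) outcomes; ``S``: (n, k, k) within-location covariances;
    ``X``: (n, p) meta-covariate design rows; ``columns`` names the p
    covariates.
    """

    y: np.ndarray
    S: np.ndarray
    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        n, k = self.y.shape
        if self.S.shape != (n, k, k):
            raise ValueError("S must be (n, k, k)")
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("meta-covariates must be complete for every location")


@dataclass(frozen=True)
class MetaFit:
    """REML meta-regression fit.

    ``beta`` is (p, k): one row of k pooled outcome coefficients per
    meta-covariate; ``vcov`` is the (p*k, p*k) covariance of ``beta`` flattened
    row-major; ``psi`` the between-location covariance.
    """

    beta: np.ndarray
    vcov: np.ndarray
    psi: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    inputs: MetaInput
    covariate_means: np.ndarray

    @property
    def k(self) -> int:
        return self.beta.shape[1]


def build_meta_design(
    countries: list[str],
    temp_means: np.ndarray,
    temp_ranges: np.ndarray,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Country indicators plus grand-mean-centred climate covariates.

    Returns the design, column names, and the grand means used for centring
    (so country predictions can undo it).
    """
    countries = list(countries)
    levels = sorted(set(countries))
    n = len(countries)
    tm = np.asarray(temp_means, dtype=float)
    tr = np.asarray(temp_ranges, dtype=float)
    means = np.array([tm.mean(), tr.mean()])
    cols = [np.array([c == lev for c in countries], dtype=float) for lev in levels]
    X = np.column_stack(cols + [tm - means[0], tr - means[1]])
    names = [f"country:{lev}" for lev in levels] + ["temp_mean", "temp_range"]
    return X, names, means


def _sigma_inverses(S: np.ndarray, psi: np.ndarray) -> np.ndarray:
    n, k, _ = S.shape
    sig = S + psi[None, :, :]
    try:
        np.linalg.cholesky(sig)
    except np.linalg.LinAlgError:
        warnings.warn("near-singular marginal covariance; adding ridge jitter", stacklevel=3)
        sig = sig + _RIDGE * np.eye(k)[None, :, :]
    return np.linalg.inv(sig)


def _gls(y: np.ndarray, X: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS fixed effects for given per-location weights W_i = Sigma_i^-1.

    Returns (b, A_inv, resid) with b the (p*k,) coefficient vector and
    A = sum_i U_i' W_i U_i the information matrix, U_i = kron(x_i, I_k).
    """
    n, k = y.shape
    p = X.shape[1]
    A = np.einsum("ia,ib,icd->acbd", X, X, W).reshape(p * k, p * k)
    rhs = np.einsum("ia,icd,id->ac", X, W, y).reshape(p * k)
    A_inv = np.linalg.inv(A)
    b = A_inv @ rhs
    fitted = X @ b.reshape(p, k)  # (n, k)
    return b, A_inv, y - fitted


def _reml_value_grad(
    params: np.ndarray, y: np.ndarray, S: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative REML log-likelihood and its gradient w.r.t. the lower
    triangle of the Cholesky factor L of Psi."""
    n, k = y.shape
    p = X.shape[1]
    L = _unpack_L(np.asarray(params, dtype=float), k)
    psi = L @ L.T
    W = _sigma_inverses(S, psi)
    b, A_inv, r = _gls(y, X, W)

    _, ldW = np.linalg.slogdet(W)
    logdet_sig = -float(ldW.sum())  # log|Sigma_i| = -log|W_i|
    q = np.einsum("icd,id->ic", W, r)
    quad = float((r * q).sum())
    # P_ii = W_i - W_i M_i W_i with M_i = (x_i' (x) I) A^-1 (x_i (x) I)
    M = np.einsum("ia,ib,acbd->icd", X, X, A_inv.reshape(p, k, p, k))
    WMW = np.einsum("ice,ief,ifd->icd", W, M, W)
    G = -0.5 * ((W - WMW).sum(axis=0) - np.einsum("ic,id->cd", q, q))
    _, logdet_a = np.linalg.slogdet(np.linalg.inv(A_inv))
    const = 0.5 * (n * k - p * k) * np.log(2 * np.pi)
    loglik = -0.5 * (logdet_sig + logdet_a + quad) - const
    grad_L = (G + G.T) @ L
    tril = np.tril_indices(k)
    return -loglik, -grad_L[tril]


def _unpack_L(params: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = params
    return L


def fit_mvmeta_reml(
    y,
    S,
    X,
    *,
    columns: list[str] | None = None,
    covariate_means: np.ndarray | None = None,
    gtol: float = 1e-9,
    maxiter: int = 500,
) -> MetaFit:
    """Fit the multivariate random-effects meta-regression by REML.

    Parameters
    ----------
    y : (n, k) outcomes (reduced coefficient sets per location).
    S : (n, k, k) within-location covariances.
    X : (n, p) meta-covariate design.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    S = np.asarray(S, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = y.shape
    p = X.shape[1]
    if n < p:
        raise ValueError("need at least as many locations as meta-coefficients")
    if S.shape == (n, k):  # allow diagonal shorthand
        S = np.array([np.diag(s) for s in S])
    inputs = MetaInput(
        y=y, S=S, X=X, columns=list(columns) if columns else [f"x{j}" for j in range(p)]
    )

    x0 = (np.sqrt(0.1) * np.eye(k))[np.tril_indices(k)]
    res = optimize.minimize(
        _reml_value_grad,
        x0,
        args=(y, S, X),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    # BFGS can stop with a line-search precision warning near the Psi = 0
    # boundary (a stationary point of the Cholesky parameterisation); accept
    # a small gradient, otherwise polish briefly with Nelder-Mead.
    grad_ok = np.max(np.abs(res.jac)) < 1e-5 * max(1.0, abs(res.fun))
    if not (res.success or grad_ok):
        res2 = optimize.minimize(
            lambda t, *a: _reml_value_grad(t, *a)[0],
            res.x,
            args=(y, S, X),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 200 * len(res.x)},
        )
        if res2.fun <= res.fun:
            res = res2
    L = _unpack_L(res.x, k)
    psi = L @ L.T
    W = _sigma_inverses(S, psi)
    b, A_inv, _ = _gls(y, X, W)
    value, _ = _reml_value_grad(res.x, y, S, X)
    return MetaFit(
        beta=b.reshape(p, k),
        vcov=A_inv,
        psi=psi,
        loglik=-value,
        converged=bool(res.success or np.max(np.abs(getattr(res, "jac", [0]))) < 1e-4),
        n_iter=int(getattr(res, "nit", 0)),
        inputs=inputs,
        covariate_means=np.zeros(0) if covariate_means is None else np.asarray(covariate_means),
    )


def _contrast_vector(fit: MetaFit, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = fit.k
    U = np.kron(x[None, :], np.eye(k))  # k x pk
    pred = U @ fit.beta.reshape(-1)
    vc = U @ fit.vcov @ U.T
    return pred, vc


def predict_country(
    fit: MetaFit,
    country: str,
    covariate_values: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Country-level pooled coefficients and covariance.

    The contrast sets the country indicator to one and the climate
    meta-covariates to the supplied country averages (values on the original
    scale; centring applied by the fit is undone automatically).  Omitted
    covariates default to the grand mean (a zero centred value).
    """
    cols = fit.inputs.columns
    key = f"country:{country}"
    if key not in cols:
        raise ValueError(f"country {country!r} not in meta-regression design")
    x = np.zeros(len(cols))
    x[cols.index(key)] = 1.0
    covariate_values = covariate_values or {}
    extra = [c for c in cols if not c.startswith("country:")]
    for j, name in enumerate(extra):
        if name in covariate_values:
            centre = fit.covariate_means[j] if fit.covariate_means.size else 0.0
            val = covariate_values[name] - centre
            col_data = fit.inputs.X[:, cols.index(name)]
            if val < col_data.min() - 1e-9 or val > col_data.max() + 1e-9:
                warnings.warn(f"covariate {name} outside the fitted range", stacklevel=2)
            x[cols.index(name)] = val
    return _contrast_vector(fit, x)


def blup(fit: MetaFit) -> tuple[np.ndarray, np.ndarray]:
    """Empirical best linear unbiased predictions for every location.

    ``y_blup_i = X_i b + Psi (S_i + Psi)^-1 (y_i - X_i b)``; the returned
    covariances account for shrinkage and fixed-effect uncertainty.
    """
    y, S, X = fit.inputs.y, fit.inputs.S, fit.inputs.X
    n, k = y.shape
    psi = fit.psi
    W = _sigma_inverses(S, psi)
    preds = np.empty_like(y)
    vcovs = np.empty((n, k, k))
    b = fit.beta.reshape(-1)
    for i in range(n):
        Ui = np.kron(X[i][None, :], np.eye(k))
        fixed = Ui @ b
        shrink = psi @ W[i]
        preds[i] = fixed + shrink @ (y[i] - fixed)
        correction = (np.eye(k) - shrink) @ Ui
        vcovs[i] = psi - shrink @ psi + correction @ fit.vcov @ correction.T
    return preds, vcovs


def wald_test_interaction(coef: np.ndarray, vcov: np.ndarray) -> tuple[float, int, float]:
    """Multivariate Wald test of pooled interaction coefficients.

    Null hypothesis: all coefficients zero, i.e. no change in the overall
    cumulative exposure-response association across the summer.  Returns
    ``(statistic, df, p)``; a singular covariance falls back to the
    pseudo-inverse with rank-adjusted df (flagged by a warning).
    """
    b = np.asarray(coef, dtype=float)
    V = np.atleast_2d(np.asarray(vcov, dtype=float))
    k = b.size
    try:
        stat = float(b @ np.linalg.solve(V, b))
        df = k
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance in Wald test; using pseudo-inverse", stacklevel=2)
        stat = float(b @ np.linalg.pinv(V) @ b)
        df = int(np.linalg.matrix_rank(V))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p
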