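"""Quasibinomial (logit-link) GLM, exceedance test, and BH false discovery.

The quasibinomial model is the inferential atom of the per-ASV screen: a
binomial-family logistic regression on relative abundances whose variance
is inflated by a free dispersion φ estimated from Pearson residuals.
Per-coefficient inference uses t statistics (β̂ / SE with SE scaled by √φ,
n − p residual df); model-level inference uses the quasi-F test

    F = [(D₀ − D) / q] / φ̂ ,   q = number of non-intercept terms,

with D the binomial deviance and φ̂ the Pearson dispersion of the full
model — the drop-in-deviance F test used for quasi-families in practice.

Fitting is iteratively reweighted least squares on the working response,
written here directly so the screen has no model-fitting dependency; an
established GLM implementation serves only as an independent cross-check in
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import logger

_ETA_CLIP = 30.0


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def _irls(y, X, w, max_iter, tol):
    """Logit-link binomial IRLS.  Returns (beta, mu, deviance, converged, it)."""
    n = y.shape[0]
    mu = (w * y + 0.5) / (w + 1.0)
    eta = np.log(mu / (1 - mu))
    dev = _binomial_deviance(y, mu, w)
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        var = mu * (1 - mu)
        W = w * var
        z = eta + (y - mu) / var
        sw = np.sqrt(W)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = np.clip(X @ beta_new, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        # guard exact 0/1 fitted values (complete separation)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        dev_new = _binomial_deviance(y, mu, w)
        delta = abs(dev_new - dev) / (abs(dev_new) + 0.1)
        beta, dev = beta_new, dev_new
        if delta < tol:
            converged = True
            break
    return beta, mu, dev, converged, it


class QuasibinomialLogit:
    """Quasibinomial GLM with logit link.

    Parameters
    ----------
    endog : array-like of proportions in [0, 1]
    exog : design matrix including an intercept column
    var_weights : prior weights (per-sample binomial totals, or unit);
        default unit weights.
    exog_names : optional column names for summaries.
    """

    def __init__(self, endog, exog, var_weights=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("exog must be 2-D (n x p)")
        n, p = self.exog.shape
        if self.endog.shape[0] != n:
            raise ValueError("endog/exog length mismatch")
        if np.any((self.endog < 0) | (self.endog > 1)):
            raise ValueError("endog must lie in [0, 1]")
        if n < p + 2:
            raise ValueError(f"need at least p+2={p+2} samples, got {n}")
        rank = np.linalg.matrix_rank(self.exog)
        if rank < p:
            names = exog_names or [f"x{j}" for j in range(p)]
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {p}); columns: {names}"
            )
        if var_weights is None:
            var_weights = np.ones(n)
        self.var_weights = np.asarray(var_weights, dtype=float)
        self.exog_names = list(exog_names) if exog_names else [f"x{j}" for j in range(p)]

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "QuasibinomialLogitResults":
        y, X, w = self.endog, self.exog, self.var_weights
        n, p = X.shape
        beta, mu, dev, converged, it = _irls(y, X, w, max_iter, tol)
        var = mu * (1 - mu)
        pearson = float(np.sum(w * (y - mu) ** 2 / var))
        df_resid = n - p
        phi = pearson / df_resid
        W = w * var
        XtWX = X.T @ (X * W[:, None])
        cov_unscaled = np.linalg.pinv(XtWX)
        bse = np.sqrt(np.maximum(phi * np.diag(cov_unscaled), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvalues = np.where(bse > 0, beta / bse, 0.0)
        pvalues = 2 * stats.t.sf(np.abs(tvalues), df_resid)
        # intercept-only null fit: weighted mean closed form, but iterate for
        # exactness of the deviance under the same convergence rule
        beta0, mu0, dev0, conv0, _ = _irls(y, np.ones((n, 1)), w, max_iter, tol)
        df_model = p - 1
        if df_model > 0 and phi > 0:
            fvalue = ((dev0 - dev) / df_model) / phi
            fvalue = max(fvalue, 0.0)
            f_pvalue = float(stats.f.sf(fvalue, df_model, df_resid))
        elif df_model > 0 and dev0 - dev <= 1e-12:
            fvalue, f_pvalue = 0.0, 1.0  # degenerate perfect fit
        else:
            fvalue, f_pvalue = np.nan, np.nan
        return QuasibinomialLogitResults(
            model=self,
            params=beta,
            bse=bse,
            tvalues=tvalues,
            pvalues=pvalues,
            scale=phi,
            deviance=dev,
            null_deviance=dev0,
            fittedvalues=mu,
            df_model=df_model,
            df_resid=df_resid,
            fvalue=float(fvalue),
            f_pvalue=float(f_pvalue),
            converged=bool(converged and conv0),
            n_iter=it,
        )


@dataclass
class QuasibinomialLogitResults:
    """One fitted quasibinomial GLM."""

    model: QuasibinomialLogit
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    scale: float  # Pearson dispersion phi
    deviance: float
    null_deviance: float
    fittedvalues: np.ndarray
    df_model: int
    df_resid: int
    fvalue: float
    f_pvalue: float
    converged: bool
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=self.model.exog_names,
        )


def fit_quasibinomial(
    y, X, weights=None, max_iter: int = 100, tol: float = 1e-8, exog_names=None
) -> QuasibinomialLogitResults:
    """Convenience wrapper: build and fit a :class:`QuasibinomialLogit`."""
    return QuasibinomialLogit(y, X, var_weights=weights, exog_names=exog_names).fit(
        max_iter=max_iter, tol=tol
    )


# ---------------------------------------------------------------------------
# Permutation-calibrated model-level p


def _batched_quasi_f(Y, X, w, max_iter: int = 60, tol: float = 1e-7) -> np.ndarray:
    """Quasi-F statistics for a batch of response vectors on one design.

    ``Y`` is (B, n): each row a response (e.g. permutations of one feature's
    relative abundances).  Runs logit-link binomial IRLS on every row
    simultaneously; returns the quasi-F of full vs intercept-only per row.
    """
    Y = np.asarray(Y, dtype=float)
    B, n = Y.shape
    p = X.shape[1]

    def fit_batch(Xd):
        q = Xd.shape[1]
        mu = (w * Y + 0.5) / (w + 1.0)
        eta = np.log(mu / (1 - mu))
        dev_prev = np.full(B, np.inf)
        for _ in range(max_iter):
            var = mu * (1 - mu)
            W = w * var
            z = eta + (Y - mu) / var
            XtWX = np.einsum("ni,bn,nj->bij", Xd, W, Xd)
            XtWz = np.einsum("ni,bn,bn->bi", Xd, W, z)
            beta = np.linalg.solve(XtWX + 1e-12 * np.eye(q), XtWz[..., None])[..., 0]
            eta = np.clip(beta @ Xd.T, -_ETA_CLIP, _ETA_CLIP)
            mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(Y > 0, Y * np.log(Y / mu), 0.0)
                t2 = np.where(Y < 1, (1 - Y) * np.log((1 - Y) / (1 - mu)), 0.0)
            dev = 2.0 * np.sum(w * (t1 + t2), axis=1)
            if np.all(np.abs(dev - dev_prev) / (np.abs(dev) + 0.1) < tol):
                dev_prev = dev
                break
            dev_prev = dev
        return dev_prev, mu

    dev_full, mu_full = fit_batch(X)
    dev_null, _ = fit_batch(np.ones((n, 1)))
    var = mu_full * (1 - mu_full)
    pearson = np.sum(w * (Y - mu_full) ** 2 / var, axis=1)
    phi = pearson / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.maximum(dev_null - dev_full, 0.0) / (p - 1) / phi
    return np.where(np.isfinite(f), f, 0.0)


def permutation_f_pvalue(
    y,
    X,
    perms: np.ndarray,
    weights=None,
    max_iter: int = 60,
    tol: float = 1e-7,
) -> float:
    """Permutation p for the quasi-F of ``y`` on ``X``.

    ``perms`` is a (B, n) array of row permutations (the covariate labels
    shuffled; equivalently the response is permuted here).  The observed
    statistic is computed through the identical batched code path, so the
    comparison is exact; p = (1 + #{F_perm >= F_obs}) / (B + 1).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    Y = np.vstack([y[None, :], y[perms]])
    # permuting the response permutes the weights with it when they differ
    if weights is not None:
        raise NotImplementedError(
            "permutation p-values support unit weights only; use p_mode='analytic'"
        )
    f = _batched_quasi_f(Y, np.asarray(X, dtype=float), w, max_iter=max_iter, tol=tol)
    return float((1 + np.sum(f[1:] >= f[0])) / (len(perms) + 1))


# ---------------------------------------------------------------------------
# Exceedance test and FDR


@dataclass
class ExceedanceResult:
    """χ² goodness-of-fit of the significant-model count against a flat null.

    Asks whether the number of nominally significant per-feature models
    exceeds what ``null_rate`` (default 5%) false positives would produce.
    One df, no continuity correction, two-sided p.
    """

    n_models: int
    n_significant: int
    null_rate: float = 0.05
    alpha_level: float = 0.05
    model: str = ""
    chi2: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self):
        if self.n_models <= 0:
            raise ValueError("n_models must be positive")
        if not (0 < self.null_rate < 1):
            raise ValueError("null_rate must be in (0, 1)")
        if not (0 <= self.n_significant <= self.n_models):
            raise ValueError("n_significant out of range")
        exp_sig = self.n_models * self.null_rate
        exp_not = self.n_models - exp_sig
        obs_not = self.n_models - self.n_significant
        self.chi2 = float(
            (self.n_significant - exp_sig) ** 2 / exp_sig
            + (obs_not - exp_not) ** 2 / exp_not
        )
        self.p_value = float(stats.chi2.sf(self.chi2, df=1))

    @property
    def proportion(self) -> float:
        return self.n_significant / self.n_models


def exceedance_test(
    n_significant: int, n_models: int, null_rate: float = 0.05
) -> ExceedanceResult:
    """χ²₁ test of ``n_significant`` of ``n_models`` against ``null_rate``."""
    return ExceedanceResult(n_models=n_models, n_significant=n_significant, null_rate=null_rate)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1.

    NaN inputs propagate as NaN (with a warning) and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        logger.warning("bh_fdr: %d NaN p-values propagated", int(nan_mask.sum()))
    pv = p[~nan_mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(m)
    res[order] = q
    out[~nan_mask] = res
    return out
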