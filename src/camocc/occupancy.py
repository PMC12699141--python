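"""Single-season site-occupancy model with imperfect detection.

The model: each site i is occupied with probability psi_i; conditional on
occupancy, each survey occasion j yields a detection with probability
p_ij; unoccupied sites never yield detections (no false positives).  With
the closure assumption (occupancy state fixed across occasions) the site
likelihood is the zero-inflated Bernoulli product

    L_i = psi_i * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi_i) * I(all observed y_ij = 0),

missing occasions dropping out of the product.  Both psi and p carry
logit-linear site covariates; detection covariates are site-level (habitat
descriptors), so p is constant over occasions within a site and the
likelihood depends on the data only through each site's detection count
and surveyed-occasion count.  Maximum likelihood is by BFGS with the
analytic gradient; the covariance matrix is the inverse observed
information (central-difference Hessian of the negative log-likelihood).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "FitResult",
    "Prediction",
    "OccupancyModel",
    "site_likelihood",
    "negative_log_likelihood",
    "fit_occupancy",
    "predict",
    "site_probabilities",
    "aicc",
]

_LABEL_RE = re.compile(r"^p\((?P<p>.*)\)Ψ\((?P<psi>.*)\)$")


@dataclass(frozen=True)
class ModelSpec:
    """Covariate selection for one candidate model.

    Both linear predictors always include an intercept; ``psi_terms`` and
    ``p_terms`` name the standardized covariate columns entering the
    occupancy and detection parts respectively.
    """

    psi_terms: tuple = ()
    p_terms: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "psi_terms", tuple(self.psi_terms))
        object.__setattr__(self, "p_terms", tuple(self.p_terms))
        for terms, part in ((self.psi_terms, "psi"), (self.p_terms, "p")):
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate {part} terms: {terms}")

    @property
    def label(self) -> str:
        p = "+".join(self.p_terms) or "."
        psi = "+".join(self.psi_terms) or "."
        return f"p({p})Ψ({psi})"

    @property
    def k(self) -> int:
        """Number of free parameters (two intercepts plus slopes)."""
        return len(self.psi_terms) + len(self.p_terms) + 2

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"cannot parse model label {label!r}")

        def split(s):
            return () if s in (".", "") else tuple(t.strip() for t in s.split("+"))

        return cls(psi_terms=split(m["psi"]), p_terms=split(m["p"]))


@dataclass
class FitResult:
    """Maximum-likelihood fit of one occupancy model.

    ``names`` label the coefficient vector as ``psi:(Intercept)``,
    ``psi:<covariate>``, ..., ``p:(Intercept)``, ``p:<covariate>``, ...
    ``c_hat`` records an applied overdispersion adjustment (None if none).
    """

    spec: ModelSpec
    names: list
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_sites: int
    aicc: float
    converged: bool
    boundary: bool = False
    c_hat: float | None = None

    @property
    def K(self) -> int:
        return len(self.beta)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    @property
    def n_psi(self) -> int:
        return len(self.spec.psi_terms) + 1

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label,
            "names": list(self.names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "K": self.K,
            "n_sites": self.n_sites,
            "aicc": self.aicc,
            "converged": self.converged,
            "boundary": self.boundary,
            "c_hat": self.c_hat,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2))

    @classmethod
    def from_json(cls, path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        return cls(
            spec=ModelSpec.from_label(d["model"]),
            names=list(d["names"]),
            beta=np.asarray(d["beta"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float),
            loglik=float(d["loglik"]),
            n_sites=int(d["n_sites"]),
            aicc=float(d["aicc"]),
            converged=bool(d["converged"]),
            boundary=bool(d["boundary"]),
            c_hat=d.get("c_hat"),
        )


@dataclass(frozen=True)
class Prediction:
    """Probability-scale prediction with a Wald interval built on the logit scale."""

    quantity: str
    point: float
    lower: float
    upper: float
    eta: float
    se_eta: float
    level: float = 0.95


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1); undefined for n <= k + 1.
    The effective sample size n is the number of sites.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def site_likelihood(history, psi: float, p) -> float:
    """Likelihood of one site's detection history.

    ``history`` is a 0/1 vector with nan marking unsurveyed occasions;
    ``p`` is a scalar or per-occasion vector of detection probabilities.
    """
    y = np.asarray(history, dtype=float)
    p = np.broadcast_to(np.asarray(p, dtype=float), y.shape)
    if not 0 <= psi <= 1 or np.any((p < 0) | (p > 1)):
        raise ValueError("psi and p must lie in [0, 1]")
    obs = ~np.isnan(y)
    yo, po = y[obs], p[obs]
    cond = float(np.prod(np.where(yo == 1, po, 1 - po)))
    return psi * cond + (1 - psi) * float(np.all(yo == 0))


def _detection_stats(data: np.ndarray):
    """Sufficient statistics per site: detections d and surveyed occasions m."""
    obs = ~np.isnan(data)
    m = obs.sum(axis=1).astype(float)
    d = np.nansum(data, axis=1)
    return d, m


def _as_data(y) -> np.ndarray:
    if hasattr(y, "data") and hasattr(y, "site_ids"):
        return np.asarray(y.data, dtype=float)
    if isinstance(y, pd.DataFrame):
        return y.to_numpy(dtype=float)
    return np.asarray(y, dtype=float)


def _design(spec: ModelSpec, cov, n_sites: int):
    """Intercept-augmented design matrices for the psi and p parts."""

    def block(terms):
        X = np.ones((n_sites, 1 + len(terms)))
        for k, t in enumerate(terms):
            if cov is None or t not in cov.columns:
                raise KeyError(f"covariate {t!r} not found in covariate table")
            X[:, k + 1] = cov[t].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite covariate values")
        return X

    return block(spec.psi_terms), block(spec.p_terms)


def _nll_grad(theta, Xpsi, Xp, d, m):
    k_psi = Xpsi.shape[1]
    psi = expit(Xpsi @ theta[:k_psi])
    p = expit(Xp @ theta[k_psi:])
    with np.errstate(divide="ignore"):
        log_a = d * np.log(np.clip(p, 1e-300, 1.0)) + (m - d) * np.log(
            np.clip(1.0 - p, 1e-300, 1.0)
        )
    a = np.exp(log_a)
    zero = (d == 0).astype(float)
    lik = psi * a + (1.0 - psi) * zero
    lik = np.clip(lik, 1e-300, None)
    nll = -float(np.sum(np.log(lik)))
    # dL/d(eta_psi) = (A - I0) psi(1-psi); dL/d(eta_p) = psi A (d - m p)
    g_psi = (a - zero) * psi * (1.0 - psi) / lik
    g_p = psi * a * (d - m * p) / lik
    grad = -np.concatenate([Xpsi.T @ g_psi, Xp.T @ g_p])
    return nll, grad


def negative_log_likelihood(params, spec: ModelSpec, matrix, cov=None) -> float:
    """Joint negative log-likelihood at a coefficient vector (psi block first)."""
    data = _as_data(matrix)
    theta = np.asarray(params, dtype=float)
    if theta.size != spec.k:
        raise ValueError(f"expected {spec.k} parameters, got {theta.size}")
    Xpsi, Xp = _design(spec, cov, data.shape[0])
    d, m = _detection_stats(data)
    return _nll_grad(theta, Xpsi, Xp, d, m)[0]


def _hessian(theta, Xpsi, Xp, d, m) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    for i in range(k):
        h = 1e-5 * (1.0 + abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        H[:, i] = (_nll_grad(up, Xpsi, Xp, d, m)[1] - _nll_grad(dn, Xpsi, Xp, d, m)[1]) / (
            2.0 * h
        )
    return 0.5 * (H + H.T)


def fit_occupancy(
    spec: ModelSpec,
    matrix,
    cov: pd.DataFrame | None = None,
    gtol: float = 1e-8,
    restart: bool = True,
) -> FitResult:
    """Fit one occupancy model by maximum likelihood.

    Starts from all-zero coefficients (psi = p = 0.5); if BFGS fails to
    converge, restarts once from the naive-occupancy and naive-detection
    logits.  ``converged`` is honest: True only when the optimizer reports
    success or the final gradient infinity-norm is below 1e-5.  Boundary
    estimates (|coefficient| > 10 on the logit scale, or a singular
    Hessian) are flagged.
    """
    data = _as_data(matrix)
    n = data.shape[0]
    if n <= spec.k + 1:
        raise ValueError(f"need more than K+1={spec.k + 1} sites, have {n}")
    Xpsi, Xp = _design(spec, cov, n)
    d, m = _detection_stats(data)

    def objective(t):
        return _nll_grad(t, Xpsi, Xp, d, m)

    starts = [np.zeros(spec.k)]
    if restart:
        naive = float(np.mean(d > 0))
        det = float(d.sum() / m[d > 0].sum()) if (d > 0).any() else 0.1
        s = np.zeros(spec.k)
        s[0] = logit(np.clip(naive, 0.02, 0.98))
        s[Xpsi.shape[1]] = logit(np.clip(det, 0.02, 0.98))
        starts.append(s)

    best = None
    for i, start in enumerate(starts):
        res = minimize(
            objective,
            start,
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": 1000},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        ok = bool(res.success) or grad_norm < 1e-5
        # prefer a converged fit; among equals, the lower objective
        if best is None or (ok, -res.fun) > (best[1], -best[0].fun):
            best = (res, ok)
        if ok and i == 0:
            break
    res, converged = best

    theta = res.x
    H = _hessian(theta, Xpsi, Xp, d, m)
    boundary = bool(np.max(np.abs(theta)) > 10.0)
    try:
        vcov = np.linalg.inv(H)
        if not np.isfinite(vcov).all() or np.any(np.diag(vcov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        boundary = True

    loglik = -float(res.fun)
    names = (
        ["psi:(Intercept)"]
        + [f"psi:{t}" for t in spec.psi_terms]
        + ["p:(Intercept)"]
        + [f"p:{t}" for t in spec.p_terms]
    )
    return FitResult(
        spec=spec,
        names=names,
        beta=theta,
        vcov=vcov,
        loglik=loglik,
        n_sites=n,
        aicc=aicc(loglik, spec.k, n),
        converged=converged,
        boundary=boundary,
    )


def site_probabilities(fit: FitResult, cov: pd.DataFrame | None, n_sites: int | None = None):
    """Fitted per-site (psi_i, p_i) under a fit, for a covariate table."""
    if n_sites is None:
        if cov is None:
            raise ValueError("n_sites required when cov is None")
        n_sites = len(cov)
    Xpsi, Xp = _design(fit.spec, cov, n_sites)
    k_psi = fit.n_psi
    return expit(Xpsi @ fit.beta[:k_psi]), expit(Xp @ fit.beta[k_psi:])


def predict(
    fit: FitResult,
    cov_values: dict | None = None,
    quantity: str = "psi",
    level: float = 0.95,
    strict: bool = True,
) -> Prediction:
    """Predict occupancy or detection probability at given covariate values.

    Covariates absent from ``cov_values`` sit at 0, i.e. their
    standardized mean.  The Wald interval is formed on the logit scale
    from the joint coefficient covariance and back-transformed, which
    keeps it inside [0, 1].
    """
    if quantity not in ("psi", "p"):
        raise ValueError("quantity must be 'psi' or 'p'")
    cov_values = dict(cov_values or {})
    terms = fit.spec.psi_terms if quantity == "psi" else fit.spec.p_terms
    if strict:
        unknown = set(cov_values) - set(fit.spec.psi_terms) - set(fit.spec.p_terms)
        if unknown:
            raise KeyError(f"unknown covariate name(s): {sorted(unknown)}")
    x = np.array([1.0] + [float(cov_values.get(t, 0.0)) for t in terms])
    k_psi = fit.n_psi
    sl = slice(0, k_psi) if quantity == "psi" else slice(k_psi, fit.K)
    eta = float(x @ fit.beta[sl])
    var = float(x @ fit.vcov[sl, sl] @ x)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.5 + level / 2.0)
    return Prediction(
        quantity=quantity,
        point=float(expit(eta)),
        lower=float(expit(eta - z * se)),
        upper=float(expit(eta + z * se)),
        eta=eta,
        se_eta=se,
        level=level,
    )


class OccupancyModel(BaseEstimator):
    """Scikit-learn-style estimator wrapping the occupancy maximum-likelihood fit.

    Parameters
    ----------
    psi_terms, p_terms : tuple of str
        Covariate columns entering the occupancy and detection linear
        predictors (an intercept is always included).
    gtol : float
        Gradient-norm convergence tolerance for BFGS.
    restart : bool
        Retry from naive-summary logits if the first optimization fails.

    Examples
    --------
    >>> model = OccupancyModel(psi_terms=("forest_d",))
    >>> model.fit(covariates, matrix).predict_psi(covariates)  # doctest: +SKIP
    """

    def __init__(self, psi_terms=(), p_terms=(), gtol: float = 1e-8, restart: bool = True):
        self.psi_terms = psi_terms
        self.p_terms = p_terms
        self.gtol = gtol
        self.restart = restart

    def fit(self, X, y):
        """Fit to covariates ``X`` (DataFrame or None) and detection data ``y``."""
        spec = ModelSpec(psi_terms=tuple(self.psi_terms), p_terms=tuple(self.p_terms))
        result = fit_occupancy(spec, y, X, gtol=self.gtol, restart=self.restart)
        self.result_ = result
        self.spec_ = spec
        self.coef_ = result.beta
        self.se_ = result.se
        self.vcov_ = result.vcov
        self.loglik_ = result.loglik
        self.aicc_ = result.aicc
        self.n_sites_ = result.n_sites
        self.converged_ = result.converged
        self.boundary_ = result.boundary
        if not result.converged:
            warnings.warn(f"optimizer did not converge for {spec.label}", stacklevel=2)
        return self

    def predict_psi(self, X) -> np.ndarray:
        psi, _ = site_probabilities(self.result_, X, None if X is not None else 1)
        return psi

    def predict_p(self, X) -> np.ndarray:
        _, p = site_probabilities(self.result_, X, None if X is not None else 1)
        return p

    def predict(self, X) -> np.ndarray:
        """Unconditional per-occasion detection probability psi_i * p_i."""
        psi, p = site_probabilities(self.result_, X, None if X is not None else 1)
        return psi * p

    def score(self, X, y) -> float:
        """Mean per-site log-likelihood of ``y`` under the fitted coefficients."""
        data = _as_data(y)
        nll = negative_log_likelihood(self.coef_, self.spec_, data, X)
        return -nll / data.shape[0]


def adjusted(fit: FitResult, factor: float) -> FitResult:
    """Return a copy of ``fit`` with vcov scaled by ``factor`` (internal)."""
    return replace(fit, vcov=fit.vcov * factor)
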