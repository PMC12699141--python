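"""Model assessment: Pearson X² goodness of fit, overdispersion, cross-validation.

Goodness of fit follows the parametric-bootstrap recipe for occupancy
models: the Pearson X² statistic over detection histories is computed on
the data, then on B datasets simulated from the fitted model (same design
and missingness); the overdispersion ratio is

    c_hat = X²_observed / mean(X²_bootstrap)

and the bootstrap p-value is the share of simulated statistics at least as
large as the observed one.  When c_hat exceeds 1, standard errors are
inflated by sqrt(c_hat) (variances by c_hat); point estimates are never
altered.  Predictive performance is assessed by site-level k-fold
cross-validation on the per-cell Brier score (mean squared error of the
unconditional detection probability psi_hat * p_hat against the 0/1
record).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .detection import DetectionMatrix
from .occupancy import FitResult, ModelSpec, fit_occupancy, site_probabilities

__all__ = [
    "GofResult",
    "CvResult",
    "pearson_chi2",
    "bootstrap_gof",
    "adjust_se",
    "cross_validate",
    "simulate_from_fit",
]


@dataclass
class GofResult:
    """Parametric-bootstrap goodness-of-fit summary."""

    observed_chi2: float
    bootstrap_chi2: np.ndarray
    c_hat: float
    p_value: float
    B: int
    seed: int | None
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_chi2": self.observed_chi2,
            "c_hat": self.c_hat,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "n_failed": self.n_failed,
            "bootstrap_mean_chi2": float(np.mean(self.bootstrap_chi2)),
        }


@dataclass
class CvResult:
    """k-fold cross-validation summary (site-level folds)."""

    k: int
    fold_mse: list
    mean_mse: float
    seed: int | None
    skipped_folds: list

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fold_mse": list(self.fold_mse),
            "mean_mse": self.mean_mse,
            "seed": self.seed,
            "skipped_folds": list(self.skipped_folds),
        }


def _history_chi2(rows: np.ndarray, psi, p, average: bool) -> float:
    """Pearson X² for one cohort of complete 0/1 histories.

    Expected counts under the fitted model depend on a history only through
    its detection count s:  Pr(h) = psi p^s (1-p)^(J-s) + (1-psi) I(s=0).
    Unobserved histories contribute (0-E)^2/E = E, so their total equals
    n_cohort minus the expected count of the observed ones — no 2^J
    enumeration is needed at any J.
    """
    n_c, j = rows.shape
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    s = uniq.sum(axis=1)
    if average:
        psi0, p0 = float(np.mean(psi)), float(np.mean(p))
        pr = psi0 * p0**s * (1 - p0) ** (j - s) + (1 - psi0) * (s == 0)
        expected = n_c * pr
    else:
        # exact: sum site-specific history probabilities
        pr = psi[None, :] * p[None, :] ** s[:, None] * (1 - p[None, :]) ** (
            j - s[:, None]
        ) + (1 - psi[None, :]) * (s[:, None] == 0)
        expected = pr.sum(axis=1)
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    chi2 += float(n_c - expected.sum())  # mass on unobserved histories
    return chi2


def pearson_chi2(
    fit: FitResult, matrix, cov=None, mode: str = "average"
) -> float:
    """Pearson X² over detection histories, summed over missingness cohorts.

    Sites sharing a missingness pattern form a cohort; within a cohort the
    fitted (psi, p) are averaged (``mode="average"``, the default
    approximation) or kept site-specific (``mode="exact"``).
    """
    if mode not in ("average", "exact"):
        raise ValueError("mode must be 'average' or 'exact'")
    data = np.asarray(matrix.data if isinstance(matrix, DetectionMatrix) else matrix, float)
    psi, p = site_probabilities(fit, cov, data.shape[0])
    obs = ~np.isnan(data)
    patterns = [tuple(r) for r in obs]
    chi2 = 0.0
    for pat in sorted(set(patterns)):
        idx = np.array([i for i, q in enumerate(patterns) if q == pat])
        cols = np.array(pat)
        rows = data[np.ix_(idx, np.where(cols)[0])]
        chi2 += _history_chi2(rows, psi[idx], p[idx], mode == "average")
    return chi2


def simulate_from_fit(fit: FitResult, matrix, cov, rng) -> np.ndarray:
    """One parametric-bootstrap dataset: same design, same missingness."""
    data = np.asarray(matrix.data if isinstance(matrix, DetectionMatrix) else matrix, float)
    n, j = data.shape
    psi, p = site_probabilities(fit, cov, n)
    z = rng.random(n) < psi
    y = (rng.random((n, j)) < p[:, None]) & z[:, None]
    out = np.where(np.isnan(data), np.nan, y.astype(float))
    return out


def bootstrap_gof(
    fit: FitResult,
    matrix,
    cov=None,
    B: int = 500,
    seed: int | None = None,
    mode: str = "average",
) -> GofResult:
    """Parametric-bootstrap goodness of fit and overdispersion ratio c_hat.

    Each of the B replicates is simulated from the fitted model, refit
    under the same specification, and its X² recomputed under its own
    refit.  Replicates whose refit does not converge are dropped; more
    than 10% failures raises.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = pearson_chi2(fit, matrix, cov, mode=mode)
    boot, failed = [], 0
    for _ in range(B):
        sim = simulate_from_fit(fit, matrix, cov, rng)
        try:
            refit = fit_occupancy(fit.spec, sim, cov)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        if not refit.converged:
            failed += 1
            continue
        boot.append(pearson_chi2(refit, sim, cov, mode=mode))
    if failed > 0.1 * B:
        raise RuntimeError(f"{failed}/{B} bootstrap refits failed")
    boot = np.asarray(boot)
    return GofResult(
        observed_chi2=observed,
        bootstrap_chi2=boot,
        c_hat=float(observed / boot.mean()),
        p_value=float(np.mean(boot >= observed)),
        B=B,
        seed=seed,
        n_failed=failed,
    )


def adjust_se(fit: FitResult, c_hat: float) -> FitResult:
    """Inflate standard errors by sqrt(c_hat) when c_hat > 1.

    The coefficient covariance is scaled by c_hat; point estimates are
    untouched; c_hat <= 1 leaves the fit unchanged.  The applied value is
    recorded on the returned fit.
    """
    if c_hat <= 0:
        raise ValueError("c_hat must be positive")
    if c_hat <= 1:
        return replace(fit, c_hat=float(c_hat))
    return replace(fit, vcov=fit.vcov * c_hat, c_hat=float(c_hat))


def brier_score(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error of probability predictions against 0/1 outcomes,
    over non-missing cells."""
    obs = np.asarray(observed, float)
    pred = np.broadcast_to(np.asarray(predicted, float), obs.shape)
    mask = ~np.isnan(obs)
    return float(np.mean((obs[mask] - pred[mask]) ** 2))


def cross_validate(
    spec: ModelSpec,
    matrix: DetectionMatrix,
    cov=None,
    k: int = 5,
    seed: int | None = None,
    prediction: str = "unconditional",
) -> CvResult:
    """Site-level k-fold cross-validation of per-cell predictions.

    Folds partition sites (never occasions).  For each fold the model is
    fit on the training sites and each held-out cell's detection
    probability is predicted as psi_hat * p_hat (``"unconditional"``) or
    p_hat alone (``"conditional"``, probability given occupancy); the MSE
    runs over the fold's non-missing cells.  A fold whose training data
    contain no detections cannot be fit and is skipped with a warning.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if prediction not in ("unconditional", "conditional"):
        raise ValueError("prediction must be 'unconditional' or 'conditional'")
    n = matrix.n_sites
    if k > n:
        raise ValueError("more folds than sites")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    fold_mse, skipped = [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        train = matrix.data[train_idx]
        if np.nansum(train) == 0:
            warnings.warn(f"fold {f}: no detections in training data; skipped",
                          stacklevel=2)
            skipped.append(f)
            continue
        cov_train = cov.iloc[train_idx] if cov is not None else None
        cov_test = cov.iloc[test_idx] if cov is not None else None
        try:
            fit = fit_occupancy(spec, train, cov_train)
        except (ValueError, np.linalg.LinAlgError):
            warnings.warn(f"fold {f}: training fit failed; skipped", stacklevel=2)
            skipped.append(f)
            continue
        psi, p = site_probabilities(fit, cov_test, len(test_idx))
        pred = (psi * p if prediction == "unconditional" else p)[:, None]
        fold_mse.append(brier_score(matrix.data[test_idx], pred))
    if not fold_mse:
        raise RuntimeError("every cross-validation fold was skipped")
    return CvResult(
        k=k,
        fold_mse=fold_mse,
        mean_mse=float(np.mean(fold_mse)),
        seed=seed,
        skipped_folds=skipped,
    )
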