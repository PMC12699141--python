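"""AICc multimodel inference: enumeration, ranking, weights, model averaging.

All covariate subsets for the detection part are crossed with all subsets
for the occupancy part (2^|p| * 2^|psi| candidate models, intercept-only
included).  Models are ranked by AICc; Akaike weights w_i are softmax of
-ΔAICc/2; a confidence set keeps models with ΔAICc strictly below a
threshold (2.0 by default) and renormalizes.  Model-averaged coefficients
use shrinkage (zero-substitution) averaging by default — a model that
excludes a term contributes 0 — with the unconditional standard error

    SE_u = sum_i w_i sqrt(var_i + (b_i - b_bar)^2)

which folds between-model spread into the reported uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .occupancy import FitResult, ModelSpec, Prediction, fit_occupancy, predict

__all__ = [
    "ModelSet",
    "AveragedEstimate",
    "enumerate_models",
    "fit_models",
    "rank_and_weight",
    "confidence_set",
    "model_average",
    "average_predictions",
    "read_model_table",
]


@dataclass
class ModelSet:
    """Fits ranked by AICc with ΔAICc and Akaike weights.

    ``renormalized`` is True for a confidence set whose weights were
    renormalized over its members.
    """

    results: list
    delta: np.ndarray
    weights: np.ndarray
    n_excluded: int = 0
    renormalized: bool = False

    def __len__(self) -> int:
        return len(self.results)

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.spec.label for f in self.results],
                "K": [f.spec.k for f in self.results],
                "AICc": [f.aicc for f in self.results],
                "dAICc": self.delta,
                "wAICc": self.weights,
            }
        )

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path, index=False)


@dataclass(frozen=True)
class AveragedEstimate:
    """Model-averaged coefficient with its unconditional standard error."""

    term: str
    estimate: float
    unconditional_se: float
    weight_containing: float  # summed weight of models containing the term


def read_model_table(path) -> pd.DataFrame:
    """Read a model table written by :meth:`ModelSet.to_csv`."""
    return pd.read_csv(path)


def enumerate_models(
    psi_candidates,
    p_candidates,
    max_terms: int | None = None,
    budget: int = 20_000,
):
    """All detection-subset x occupancy-subset model specifications.

    The outer loop runs over detection subsets and the inner loop over
    occupancy subsets.  Without a ``max_terms`` cap the count is
    2^|psi| * 2^|p|; exceeding ``budget`` raises with advice to cap.
    """
    psi_candidates = list(psi_candidates)
    p_candidates = list(p_candidates)

    def subsets(names):
        cap = len(names) if max_terms is None else min(max_terms, len(names))
        out = []
        for r in range(cap + 1):
            out.extend(combinations(names, r))
        return out

    psi_subsets = subsets(psi_candidates)
    p_subsets = subsets(p_candidates)
    count = len(psi_subsets) * len(p_subsets)
    if count > budget:
        raise ValueError(
            f"{count} candidate models exceed the budget of {budget}; "
            "pass max_terms to cap subset size or raise the budget"
        )
    return [
        ModelSpec(psi_terms=s, p_terms=pp) for pp in p_subsets for s in psi_subsets
    ]


def fit_models(specs, matrix, cov, n_jobs: int = 1, **fit_kwargs):
    """Fit every candidate model; results keep the input order.

    Fits are independent, so they may run concurrently (joblib); output
    ordering and values are identical to sequential execution.
    """
    if n_jobs == 1:
        return [fit_occupancy(s, matrix, cov, **fit_kwargs) for s in specs]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs)(
        delayed(fit_occupancy)(s, matrix, cov, **fit_kwargs) for s in specs
    )


def rank_and_weight(fits) -> ModelSet:
    """Rank converged fits by AICc and attach ΔAICc and Akaike weights."""
    fits = list(fits)
    converged = [f for f in fits if f.converged]
    n_excluded = len(fits) - len(converged)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} non-converged fit(s)", stacklevel=2)
    if not converged:
        raise ValueError("no converged fits to rank")
    converged.sort(key=lambda f: (f.aicc, f.spec.k, f.spec.label))
    aiccs = np.array([f.aicc for f in converged])
    delta = aiccs - aiccs[0]
    w = np.exp(-delta / 2.0)
    return ModelSet(converged, delta, w / w.sum(), n_excluded)


def confidence_set(model_set: ModelSet, threshold: float = 2.0) -> ModelSet:
    """Members with ΔAICc strictly below ``threshold``, weights renormalized."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = model_set.delta < threshold
    w = model_set.weights[keep]
    return ModelSet(
        [f for f, k in zip(model_set.results, keep) if k],
        model_set.delta[keep],
        w / w.sum(),
        model_set.n_excluded,
        renormalized=True,
    )


def _term_entries(model_set: ModelSet, term: str):
    """(weight, estimate, variance, present) per member for a named coefficient."""
    rows = []
    for w, f in zip(model_set.weights, model_set.results):
        if term in f.names:
            i = f.names.index(term)
            rows.append((w, float(f.beta[i]), float(f.vcov[i, i]), True))
        else:
            rows.append((w, 0.0, 0.0, False))
    return rows


def model_average(
    model_set: ModelSet, term: str, mode: str = "shrinkage"
) -> AveragedEstimate:
    """Model-averaged coefficient for ``term`` (e.g. ``"psi:forest_d"``).

    ``mode="shrinkage"`` averages over every member, substituting 0 where
    the term is absent; ``mode="conditional"`` averages only over models
    containing the term, with weights renormalized over those models.
    """
    if mode not in ("shrinkage", "conditional"):
        raise ValueError("mode must be 'shrinkage' or 'conditional'")
    rows = _term_entries(model_set, term)
    w_in = sum(w for w, *_ , present in rows if present)
    if w_in == 0:
        raise KeyError(f"term {term!r} appears in no member of the model set")
    if mode == "conditional":
        rows = [(w / w_in, b, v, pr) for w, b, v, pr in rows if pr]
    est = sum(w * b for w, b, _, _ in rows)
    se = sum(w * np.sqrt(v + (b - est) ** 2) for w, b, v, _ in rows)
    return AveragedEstimate(term, float(est), float(se), float(w_in))


def average_predictions(
    model_set: ModelSet,
    cov_values: dict | None = None,
    quantity: str = "psi",
    level: float = 0.95,
) -> Prediction:
    """Model-averaged probability prediction across a confidence set.

    The point value is the weight-averaged probability-scale prediction;
    the interval carries the unconditional (between-model) spread on the
    logit scale and is back-transformed around the averaged point.
    """
    cov_values = dict(cov_values or {})
    known = set()
    for f in model_set.results:
        known |= set(f.spec.psi_terms) | set(f.spec.p_terms)
    unknown = set(cov_values) - known
    if unknown:
        raise KeyError(f"unknown covariate name(s): {sorted(unknown)}")

    preds = [
        predict(f, cov_values, quantity=quantity, level=level, strict=False)
        for f in model_set.results
    ]
    w = model_set.weights
    point = float(np.sum(w * np.array([pr.point for pr in preds])))
    eta = np.array([pr.eta for pr in preds])
    se_eta = np.array([pr.se_eta for pr in preds])
    eta_bar = float(np.sum(w * eta))
    se_u = float(np.sum(w * np.sqrt(se_eta**2 + (eta - eta_bar) ** 2)))
    z = norm.ppf(0.5 + level / 2.0)
    eta_point = float(logit(np.clip(point, 1e-12, 1 - 1e-12)))
    return Prediction(
        quantity=quantity,
        point=point,
        lower=float(expit(eta_point - z * se_u)),
        upper=float(expit(eta_point + z * se_u)),
        eta=eta_point,
        se_eta=se_u,
        level=level,
    )
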