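"""Incremental mixture importance sampling (IMIS) on the simulator itself.

The comparison arm to the emulator-based calibration: no surrogate, the
likelihood is evaluated by running the deterministic cohort model directly.
Starting from prior draws, each iteration adds a batch of points from a
multivariate normal centred at the current highest-weight point (covariance
estimated from its nearest neighbours), rebuilds the defensive mixture
importance density, and reweights.  Iteration stops once the expected
fraction of unique points in a hypothetical resample reaches 1 - 1/e, and
the posterior sample is drawn by weighted resampling with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .calibrate import CalibrationTargets, PosteriorDraws
from .doe import PriorSpec
from .nathist import LifeTable, NaturalHistoryParams, run_cohort, \
    summarize_outputs

__all__ = ["ImisState", "imis_calibrate", "simulator_loglik"]

_LOG_2PI = np.log(2.0 * np.pi)


def simulator_loglik(targets: CalibrationTargets, priors: PriorSpec,
                     life_table: LifeTable | None = None
                     ) -> Callable[[np.ndarray], float]:
    """Normal log likelihood of the targets under a direct cohort-model run."""
    life_table = life_table or LifeTable.default()
    y, sigma = targets.y, targets.sigma
    const = -np.sum(np.log(sigma)) - 0.5 * len(y) * _LOG_2PI
    names = priors.names

    def loglik(theta: np.ndarray) -> float:
        params = NaturalHistoryParams(**dict(zip(names, theta)))
        phi = summarize_outputs(run_cohort(params, life_table)).to_vector()
        return float(-0.5 * np.sum((y - phi) ** 2 / sigma ** 2) + const)

    return loglik


def _mixture_logpdf(points: np.ndarray, priors: PriorSpec,
                    components: list[tuple[np.ndarray, np.ndarray]],
                    n0: int, b: int) -> np.ndarray:
    """Defensive mixture density: prior and all Gaussian components,
    weighted by the number of points each contributed."""
    log_prior_pdf = -np.sum(np.log(priors.upper - priors.lower))
    total = n0 + b * len(components)
    parts = [np.log(n0 / total) + np.full(len(points), log_prior_pdf)]
    for center, cov in components:
        lp = multivariate_normal.logpdf(points, mean=center, cov=cov,
                                        allow_singular=True)
        parts.append(np.log(b / total) + np.atleast_1d(lp))
    return np.logaddexp.reduce(np.vstack(parts), axis=0)


def _neighbour_cov(points: np.ndarray, weights: np.ndarray, center: np.ndarray,
                   b: int, prior_scale: np.ndarray) -> np.ndarray:
    """Weighted covariance of the b nearest neighbours of ``center``.

    Distances are scaled by the prior ranges so no parameter dominates.
    Neighbour weights follow the usual IMIS recipe (importance weight plus a
    uniform floor); a small diagonal ridge guards against degeneracy.
    """
    z = (points - center) / prior_scale
    order = np.argsort(np.einsum("ij,ij->i", z, z))
    idx = order[:min(b, len(points))]
    w = weights[idx] + 1.0 / len(points)
    w /= w.sum()
    diff = points[idx] - center
    cov = (w[:, None] * diff).T @ diff
    ridge = 1e-12 + 1e-6 * np.mean(np.diag(cov))
    if not np.all(np.linalg.eigvalsh(cov) > ridge):
        warnings.warn("degenerate neighbour covariance; adding diagonal "
                      "regularisation", stacklevel=2)
    cov[np.diag_indices_from(cov)] += ridge + 1e-10 * prior_scale ** 2
    return cov


def _sample_truncated(rng: np.random.Generator, center: np.ndarray,
                      cov: np.ndarray, n: int, priors: PriorSpec) -> np.ndarray:
    """Multivariate-normal draws kept inside the prior box (rejection)."""
    out = np.empty((0, len(center)))
    for _ in range(1000):
        cand = rng.multivariate_normal(center, cov, size=2 * n,
                                       method="eigh")
        cand = cand[priors.contains(cand)]
        out = np.vstack([out, cand])
        if len(out) >= n:
            return out[:n]
    raise RuntimeError("could not draw proposal points inside the prior box")


@dataclass
class ImisState:
    """Final sampler state plus the per-iteration maximum importance weight."""

    points: np.ndarray
    loglik: np.ndarray
    components: list[tuple[np.ndarray, np.ndarray]]
    weights: np.ndarray
    max_weight_history: list[float]

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("importance weights must be a distribution")


def imis_calibrate(loglik: Callable[[np.ndarray], float],
                   priors: PriorSpec, n0: int = 1000, b: int = 100,
                   n_resample: int = 10000, max_iter: int = 100,
                   seed: int = 0, method: str = "imis",
                   return_state: bool = False
                   ) -> PosteriorDraws | tuple[PosteriorDraws, ImisState]:
    """Posterior sample by incremental mixture importance sampling.

    ``loglik`` must be evaluable anywhere in the prior box.  ``n0`` initial
    points are drawn from the uniform prior; each of up to ``max_iter``
    iterations adds ``b`` points from an adapted Gaussian centred at the
    highest-weight point.  Returns ``n_resample`` draws resampled with
    replacement by the final importance weights; identical seeds give
    identical draws.
    """
    rng = np.random.default_rng(seed)
    d = len(priors)
    points = rng.uniform(priors.lower, priors.upper, size=(n0, d))
    ll = np.array([loglik(p) for p in points])
    components: list[tuple[np.ndarray, np.ndarray]] = []
    prior_scale = priors.upper - priors.lower

    log_w = ll.copy()  # q = prior initially, so w ∝ L
    weights = _normalise(log_w)
    max_w_history = [float(weights.max())]
    for _ in range(max_iter):
        frac_unique = np.sum(1.0 - (1.0 - weights) ** n_resample) / n_resample
        if frac_unique >= 1.0 - 1.0 / np.e:
            break
        center = points[np.argmax(weights)]
        cov = _neighbour_cov(points, weights, center, b, prior_scale)
        new = _sample_truncated(rng, center, cov, b, priors)
        points = np.vstack([points, new])
        ll = np.concatenate([ll, [loglik(p) for p in new]])
        components.append((center, cov))
        log_q = _mixture_logpdf(points, priors, components, n0, b)
        log_prior_pdf = -np.sum(np.log(prior_scale))
        log_w = ll + log_prior_pdf - log_q
        weights = _normalise(log_w)
        max_w_history.append(float(weights.max()))

    idx = rng.choice(len(points), size=n_resample, replace=True, p=weights)
    resampled = points[idx]
    draws = PosteriorDraws(pd.DataFrame(resampled, columns=priors.names),
                           ll[idx],  # flat prior: log posterior ∝ log likelihood
                           np.zeros(n_resample, dtype=int),
                           np.arange(n_resample), method)
    if return_state:
        return draws, ImisState(points, ll, components, weights, max_w_history)
    return draws


def _normalise(log_w: np.ndarray) -> np.ndarray:
    w = np.exp(log_w - log_w.max())
    return w / w.sum()
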