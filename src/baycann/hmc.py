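"""No-U-Turn Hamiltonian Monte Carlo on an unconstrained space.

A compact dynamic-HMC sampler: leapfrog integration with a diagonal or
dense mass matrix, trajectory doubling until the no-U-turn criterion fires,
slice acceptance over the doubled tree, dual-averaging step-size adaptation
toward a target acceptance statistic, and a warmup schedule that estimates
the metric from an intermediate adaptation window.  A dense metric is the
default: strongly correlated (weakly identified) posteriors are the normal
case in calibration problems, and a diagonal metric mixes poorly along
their ridges.

The caller supplies ``logp_and_grad(u) -> (float, ndarray)`` for the log
target density and its gradient; everything here is pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nuts_chain"]

_MAX_DELTA_ENERGY = 1000.0  # divergence threshold


class _Metric:
    """Euclidean metric M = Sigma^{-1} given a target covariance Sigma.

    Momenta are N(0, M); the leapfrog velocity is Sigma @ p, so the sampler
    moves fastest along the posterior's long directions.
    """

    def __init__(self, cov: np.ndarray):
        cov = np.atleast_2d(cov)
        self._cov = cov
        self._chol = np.linalg.cholesky(cov)  # Sigma = L L^T

    @classmethod
    def identity(cls, d: int) -> "_Metric":
        return cls(np.eye(d))

    @classmethod
    def from_draws(cls, draws: np.ndarray, dense: bool) -> "_Metric":
        d = draws.shape[1]
        if dense and len(draws) > d + 2:
            cov = np.cov(draws, rowvar=False)
            # shrink toward the diagonal for stability (light regularisation)
            w = len(draws) / (len(draws) + 5.0)
            cov = w * cov + (1 - w) * np.diag(np.diag(cov))
            cov[np.diag_indices_from(cov)] += 1e-8
        else:
            var = np.clip(np.var(draws, axis=0, ddof=1), 1e-8, None)
            cov = np.diag(var)
        try:
            return cls(cov)
        except np.linalg.LinAlgError:
            return cls(np.diag(np.diag(cov)))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        # p = L^{-T} z has covariance (L L^T)^{-1} = M
        z = rng.standard_normal(self._cov.shape[0])
        return np.linalg.solve(self._chol.T, z)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self._cov @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self._cov @ p)


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance delta)."""

    mu: float
    delta: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _t: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    def update(self, accept_stat: float) -> float:
        self._t += 1
        eta = 1.0 / (self._t + self.t0)
        self._h_bar = (1 - eta) * self._h_bar + eta * (self.delta - accept_stat)
        log_eps = self.mu - np.sqrt(self._t) / self.gamma * self._h_bar
        w = self._t ** (-self.kappa)
        self._log_eps_bar = w * log_eps + (1 - w) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


def _leapfrog(logp_and_grad, u, p, grad, eps, metric):
    p = p + 0.5 * eps * grad
    u = u + eps * metric.velocity(p)
    logp, grad = logp_and_grad(u)
    p = p + 0.5 * eps * grad
    return u, p, logp, grad


def _hamiltonian(logp, p, metric) -> float:
    h = logp - metric.kinetic(p)
    return h if np.isfinite(h) else -np.inf


def _find_initial_step(logp_and_grad, u0, metric, rng) -> float:
    """Heuristic: double/halve eps until one leapfrog step crosses 50% accept."""
    eps = 1.0
    logp0, grad0 = logp_and_grad(u0)
    p0 = metric.sample_momentum(rng)
    h0 = _hamiltonian(logp0, p0, metric)
    _, p1, logp1, _ = _leapfrog(logp_and_grad, u0, p0, grad0, eps, metric)
    h1 = _hamiltonian(logp1, p1, metric)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_and_grad, u0, p0, grad0, eps, metric)
        h1 = _hamiltonian(logp1, p1, metric)
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


@dataclass
class _Tree:
    u_minus: np.ndarray
    p_minus: np.ndarray
    grad_minus: np.ndarray
    u_plus: np.ndarray
    p_plus: np.ndarray
    grad_plus: np.ndarray
    u_prop: np.ndarray
    logp_prop: float
    n_ok: int
    keep_going: bool
    accept_sum: float
    n_steps: int


def _build_tree(logp_and_grad, u, p, grad, log_slice, direction, depth, eps,
                h0, metric, rng) -> _Tree:
    if depth == 0:
        u1, p1, logp1, grad1 = _leapfrog(
            logp_and_grad, u, p, grad, direction * eps, metric)
        h1 = _hamiltonian(logp1, p1, metric)
        n_ok = int(log_slice <= h1)
        diverged = log_slice - _MAX_DELTA_ENERGY >= h1
        accept = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
        return _Tree(u1, p1, grad1, u1, p1, grad1, u1, logp1,
                     n_ok, not diverged, accept, 1)
    # recursively build left and right subtrees
    t = _build_tree(logp_and_grad, u, p, grad, log_slice, direction,
                    depth - 1, eps, h0, metric, rng)
    if t.keep_going:
        if direction == -1:
            t2 = _build_tree(logp_and_grad, t.u_minus, t.p_minus, t.grad_minus,
                             log_slice, direction, depth - 1, eps, h0,
                             metric, rng)
            t.u_minus, t.p_minus, t.grad_minus = t2.u_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(logp_and_grad, t.u_plus, t.p_plus, t.grad_plus,
                             log_slice, direction, depth - 1, eps, h0,
                             metric, rng)
            t.u_plus, t.p_plus, t.grad_plus = t2.u_plus, t2.p_plus, t2.grad_plus
        total = t.n_ok + t2.n_ok
        if t2.n_ok > 0 and rng.random() < t2.n_ok / max(total, 1):
            t.u_prop, t.logp_prop = t2.u_prop, t2.logp_prop
        span = t.u_plus - t.u_minus
        no_uturn = (span @ metric.velocity(t.p_minus) >= 0
                    and span @ metric.velocity(t.p_plus) >= 0)
        t.n_ok = total
        t.keep_going = t.keep_going and t2.keep_going and no_uturn
        t.accept_sum += t2.accept_sum
        t.n_steps += t2.n_steps
    return t


def _nuts_step(logp_and_grad, u, logp, grad, eps, metric, rng, max_depth):
    p0 = metric.sample_momentum(rng)
    h0 = _hamiltonian(logp, p0, metric)
    log_slice = h0 + np.log1p(-rng.random())  # log of slice ~ U(0, exp(h0))
    u_minus = u_plus = u
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    u_cur, logp_cur = u, logp
    n_ok, accept_sum, n_steps = 1, 0.0, 0
    for depth in range(max_depth):
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            t = _build_tree(logp_and_grad, u_minus, p_minus, grad_minus,
                            log_slice, direction, depth, eps, h0, metric, rng)
            u_minus, p_minus, grad_minus = t.u_minus, t.p_minus, t.grad_minus
        else:
            t = _build_tree(logp_and_grad, u_plus, p_plus, grad_plus,
                            log_slice, direction, depth, eps, h0, metric, rng)
            u_plus, p_plus, grad_plus = t.u_plus, t.p_plus, t.grad_plus
        accept_sum += t.accept_sum
        n_steps += t.n_steps
        if t.keep_going and t.n_ok > 0 and rng.random() < t.n_ok / n_ok:
            u_cur, logp_cur = t.u_prop, t.logp_prop
        n_ok += t.n_ok
        span = u_plus - u_minus
        if not (t.keep_going
                and span @ metric.velocity(p_minus) >= 0
                and span @ metric.velocity(p_plus) >= 0):
            break
    _, grad_cur = logp_and_grad(u_cur) if u_cur is not u else (logp, grad)
    accept_stat = accept_sum / max(n_steps, 1)
    return u_cur, logp_cur, grad_cur, accept_stat


def nuts_chain(logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
               u0: np.ndarray, n_warmup: int, n_draws: int,
               rng: np.random.Generator, max_depth: int = 12,
               target_accept: float = 0.9, dense_mass: bool = True
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run one NUTS chain; returns (draws, log-densities, accept statistics).

    Warmup adapts the step size throughout and re-estimates the mass matrix
    (dense by default) from the middle 60% of warmup draws; post-warmup
    draws use the frozen step size and metric.
    """
    u = np.asarray(u0, dtype=float).copy()
    d = len(u)
    metric = _Metric.identity(d)
    logp, grad = logp_and_grad(u)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_and_grad, u, metric, rng)
    da = _DualAveraging(mu=np.log(10.0 * eps), delta=target_accept)
    window_lo, window_hi = int(0.2 * n_warmup), int(0.8 * n_warmup)
    window: list[np.ndarray] = []
    for i in range(n_warmup):
        u, logp, grad, astat = _nuts_step(
            logp_and_grad, u, logp, grad, eps, metric, rng, max_depth)
        eps = da.update(astat)
        if window_lo <= i < window_hi:
            window.append(u.copy())
        if i == window_hi - 1 and len(window) >= 10:
            metric = _Metric.from_draws(np.asarray(window), dense_mass)
            eps = _find_initial_step(logp_and_grad, u, metric, rng)
            da = _DualAveraging(mu=np.log(10.0 * eps), delta=target_accept)
    eps = da.adapted if n_warmup > 0 else eps

    draws = np.empty((n_draws, d))
    logps = np.empty(n_draws)
    astats = np.empty(n_draws)
    for s in range(n_draws):
        u, logp, grad, astat = _nuts_step(
            logp_and_grad, u, logp, grad, eps, metric, rng, max_depth)
        draws[s], logps[s], astats[s] = u, logp, astat
    return draws, logps, astats
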