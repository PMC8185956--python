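"""Bayesian calibration of the emulated simulator.

The posterior over the nine natural-history parameters combines a uniform
prior over the scaled box [-1, 1]^9 with an independent-normal likelihood on
the 36 calibration targets: each target mean ``y_ti`` is normal around the
model-predicted outcome ``phi_ti`` (the emulator's prediction at theta) with
its reported standard error ``sigma_ti``.  Sampling is gradient-based
Hamiltonian Monte Carlo (NUTS) run on an unconstrained transform of the box,
so draws respect the prior support exactly; draws are reported back in
natural parameter units.

``BayesianCalibration(targets, emulator).fit()`` returns a
``CalibrationResults`` with draws, convergence diagnostics, credible
intervals, the maximum-a-posteriori draw and posterior-predictive outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from .doe import PriorSpec
from .emulator import AnnEmulator, AnnWeights, ScalingSpec, ann_forward, \
    ann_forward_grad
from .hmc import nuts_chain
from .nathist import AGE_GROUP_STARTS, TARGET_TYPES, ModelOutputs

__all__ = ["CalibrationTargets", "PosteriorDraws", "log_prior",
           "log_likelihood", "sample_posterior", "map_estimate",
           "posterior_summary", "posterior_predictive",
           "BayesianCalibration", "CalibrationResults"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class CalibrationTargets:
    """The 36 target means and standard errors, in canonical column order.

    Ordering (series alphabetical, then ascending age group) matches the
    emulator's output columns; construction enforces it.
    """

    table: pd.DataFrame  # columns: target_type, age_group_start, mean, se

    def __post_init__(self) -> None:
        required = {"target_type", "age_group_start", "mean", "se"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"targets table needs columns {sorted(required)}")
        expect = [(t, a) for t in TARGET_TYPES for a in AGE_GROUP_STARTS]
        got = list(zip(self.table["target_type"], self.table["age_group_start"]))
        if sorted(got) != sorted(expect):
            raise ValueError("targets must contain exactly the 36 canonical "
                             "(series, age group) pairs")
        if got != expect:  # re-sort into canonical order
            self.table = (self.table
                          .sort_values(["target_type", "age_group_start"])
                          .reset_index(drop=True))
        if (self.table["se"] <= 0).any():
            raise ValueError("all target standard errors must be positive")

    @property
    def y(self) -> np.ndarray:
        return self.table["mean"].to_numpy(dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return self.table["se"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_arrays(cls, means: np.ndarray, ses: np.ndarray) -> "CalibrationTargets":
        out = ModelOutputs.from_vector(means).to_frame()
        out["se"] = np.asarray(ses, dtype=float)
        return cls(out.rename(columns={"value": "mean"}))

    @classmethod
    def from_csv(cls, path) -> "CalibrationTargets":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def log_prior(theta_scaled: np.ndarray) -> float:
    """Uniform prior on the closed scaled box: 0 inside, -inf outside."""
    theta_scaled = np.asarray(theta_scaled, dtype=float)
    inside = np.all(np.abs(theta_scaled) <= 1.0)
    return 0.0 if inside else -np.inf


def log_likelihood(theta_scaled: np.ndarray, targets: CalibrationTargets,
                   weights: AnnWeights, scaling: ScalingSpec) -> float:
    """Independent-normal log likelihood of the targets at scaled theta."""
    phi = scaling.unscale_outputs(ann_forward(weights, np.asarray(theta_scaled)))
    z = (targets.y - phi) / targets.sigma
    return float(-0.5 * np.sum(z ** 2) - np.sum(np.log(targets.sigma))
                 - 0.5 * len(targets) * _LOG_2PI)


def _loglik_and_grad(theta_scaled, y, sigma, weights, scaling):
    """Log likelihood and its gradient w.r.t. the scaled parameters."""
    out_scaled, J = ann_forward_grad(weights, theta_scaled)
    phi = scaling.unscale_outputs(out_scaled)
    r = (y - phi) / sigma ** 2
    ll = (-0.5 * np.sum((y - phi) ** 2 / sigma ** 2)
          - np.sum(np.log(sigma)) - 0.5 * len(y) * _LOG_2PI)
    grad = (scaling.output_halfwidth * r) @ J
    return ll, grad


@dataclass
class PosteriorDraws:
    """Posterior sample in natural units with per-draw log posterior.

    ``log_posterior`` is the unnormalised log posterior density over the
    scaled parameter box (log likelihood plus the constant log prior).
    """

    draws: pd.DataFrame  # S x d, natural units
    log_posterior: np.ndarray
    chain: np.ndarray
    iteration: np.ndarray
    method: str = "baycann"
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        S = len(self.draws)
        if S < 1:
            raise ValueError("need at least one draw")
        if not (len(self.log_posterior) == len(self.chain)
                == len(self.iteration) == S):
            raise ValueError("draw annotations must match the draw count")
        if not np.all(np.isfinite(self.log_posterior)):
            raise ValueError("retained draws must have finite log posterior")

    @property
    def names(self) -> list[str]:
        return list(self.draws.columns)

    @property
    def values(self) -> np.ndarray:
        return self.draws.to_numpy(dtype=float)

    @property
    def map_index(self) -> int:
        return int(np.argmax(self.log_posterior))

    def __len__(self) -> int:
        return len(self.draws)

    def to_csv(self, path) -> None:
        df = self.draws.copy()
        df["log_posterior"] = self.log_posterior
        df["chain"] = self.chain
        df["iteration"] = self.iteration
        df["method"] = self.method
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        method = str(df["method"].iloc[0]) if "method" in df else "baycann"
        meta = [c for c in ("log_posterior", "chain", "iteration", "method")
                if c in df]
        return cls(df.drop(columns=meta), df["log_posterior"].to_numpy(),
                   df["chain"].to_numpy(), df["iteration"].to_numpy(), method)


def map_estimate(draws: PosteriorDraws) -> np.ndarray:
    """The draw with the highest log posterior (first index on ties)."""
    return draws.values[draws.map_index]


def sample_posterior(targets: CalibrationTargets, weights: AnnWeights,
                     scaling: ScalingSpec, priors: PriorSpec | None = None,
                     n_draws: int = 10000, n_chains: int = 4,
                     n_warmup: int = 1000, seed: int = 0,
                     target_accept: float = 0.8,
                     rhat_threshold: float = 1.01) -> PosteriorDraws:
    """Draw from the posterior with NUTS over the scaled parameter box.

    ``n_draws`` is the total retained post-warmup sample, split evenly over
    ``n_chains`` independent chains.  The sampler works on an unconstrained
    transform ``theta_scaled = tanh(u / 2)`` (a scaled logit), whose Jacobian
    is included in the sampled density, so the prior box is respected
    exactly.  Split-R-hat and effective sample size are attached; parameters
    with R-hat above ``rhat_threshold`` are flagged with a warning, never
    silently accepted.
    """
    priors = priors or PriorSpec.default()
    y, sigma = targets.y, targets.sigma
    if len(y) != weights.n_outputs:
        raise ValueError("target count does not match emulator outputs")

    # log-mapped input columns: the uniform prior on natural units has
    # density ∝ exp(slope * scaled) in scaled coordinates
    prior_slope = scaling.input_log_slope

    def logp_and_grad(u):
        ts = np.tanh(0.5 * u)
        ll, gl = _loglik_and_grad(ts, y, sigma, weights, scaling)
        ll += ts @ prior_slope
        gl = gl + prior_slope
        # log(0.5 * (1 - ts^2)) = log 2 - |u| - 2 log(1 + exp(-|u|)), stable
        # under the underflow of 1 - ts^2 at large |u|
        au = np.abs(u)
        log_jac = np.log(2.0) - au - 2.0 * np.log1p(np.exp(-au))
        logp = ll + np.sum(log_jac)
        grad = gl * (0.5 * (1.0 - ts ** 2)) - ts
        return logp, grad

    per_chain = int(np.ceil(n_draws / n_chains))
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    all_u, all_lp, chain_ids, iters = [], [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        u0 = 2.0 * np.arctanh(rng.uniform(-0.5, 0.5, size=len(priors)))
        u_draws, lp, _ = nuts_chain(logp_and_grad, u0, n_warmup, per_chain, rng)
        all_u.append(u_draws)
        all_lp.append(lp)
        chain_ids.append(np.full(per_chain, c))
        iters.append(np.arange(per_chain))

    U = np.concatenate(all_u)[:n_draws]
    theta_s = np.tanh(0.5 * U)
    # report the natural-units log posterior (uniform prior, so equal to the
    # log likelihood up to a constant): strip the transform terms
    au = np.abs(U)
    log_jac = np.log(2.0) - au - 2.0 * np.log1p(np.exp(-au))
    lp_box = (np.concatenate(all_lp)[:n_draws]
              - log_jac.sum(axis=1) - theta_s @ scaling.input_log_slope)
    theta_nat = scaling.unscale_inputs(theta_s)

    posterior_4d = np.tanh(0.5 * np.stack(all_u))  # (chains, draws, dim)
    idata = az.from_dict(posterior={n: posterior_4d[:, :, i]
                                    for i, n in enumerate(priors.names)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata).to_pandas()
        ess = az.ess(idata).to_pandas()
    diagnostics = pd.DataFrame({"rhat": rhat, "ess": ess})
    bad = diagnostics.index[diagnostics["rhat"] > rhat_threshold]
    if len(bad):
        warnings.warn(
            "convergence flag: split-R-hat exceeds "
            f"{rhat_threshold} for {list(bad)}", stacklevel=2)

    return PosteriorDraws(pd.DataFrame(theta_nat, columns=priors.names),
                          lp_box,
                          np.concatenate(chain_ids)[:n_draws],
                          np.concatenate(iters)[:n_draws],
                          "baycann", diagnostics)


def posterior_summary(draws: PosteriorDraws,
                      truth: np.ndarray | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-parameter summary and the posterior correlation matrix.

    Returns ``(summary, corr)``: the summary has posterior mean, equal-tailed
    95% credible bounds and, when a truth vector is supplied, whether the
    interval covers it; ``corr`` is the Pearson correlation matrix of the
    draws.
    """
    X = draws.values
    mean = X.mean(axis=0)
    lo, hi = np.percentile(X, [2.5, 97.5], axis=0)
    summary = pd.DataFrame({"mean": mean, "ci_lo": lo, "ci_hi": hi},
                           index=draws.names)
    summary["map"] = map_estimate(draws)
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        summary["truth"] = truth
        summary["covered"] = (lo <= truth) & (truth <= hi)
    if len(X) >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            C = np.corrcoef(X, rowvar=False)
        C = np.where(np.isfinite(C), C, 0.0)  # zero-variance margins
        np.fill_diagonal(C, 1.0)
    else:
        C = np.eye(X.shape[1])
    corr = pd.DataFrame(C, index=draws.names, columns=draws.names)
    return summary, corr


def posterior_predictive(draws: PosteriorDraws, weights: AnnWeights,
                         scaling: ScalingSpec, n_use: int = 1000
                         ) -> pd.DataFrame:
    """Push posterior draws through the emulator; summarise each outcome.

    Uses ``n_use`` evenly spaced draws (deterministic thinning).  Returns a
    36-row table with the posterior-predicted mean, equal-tailed 95% interval
    and the outcome at the maximum-a-posteriori draw.
    """
    if n_use > len(draws):
        raise ValueError("n_use exceeds the number of draws")
    idx = np.unique(np.linspace(0, len(draws) - 1, n_use).astype(int))
    theta_s = scaling.scale_inputs(draws.values[idx])
    phi = scaling.unscale_outputs(ann_forward(weights, theta_s))
    phi_map = scaling.unscale_outputs(
        ann_forward(weights, scaling.scale_inputs(map_estimate(draws))))
    lo, hi = np.percentile(phi, [2.5, 97.5], axis=0)
    out = ModelOutputs.from_vector(phi.mean(axis=0)).to_frame()
    out = out.rename(columns={"value": "pred_mean"})
    out["pred_lo"] = lo
    out["pred_hi"] = hi
    out["pred_map"] = phi_map
    return out


class BayesianCalibration:
    """Calibration model: targets + trained emulator + uniform prior box.

    Mirrors the usual model/results split: the model object holds the data
    and likelihood specification, ``fit`` runs the sampler and returns a
    ``CalibrationResults``.
    """

    def __init__(self, targets: CalibrationTargets, emulator: AnnEmulator,
                 priors: PriorSpec | None = None):
        self.targets = targets
        self.emulator = emulator
        self.priors = priors or PriorSpec.default()

    def log_posterior(self, theta_scaled: np.ndarray) -> float:
        lp = log_prior(theta_scaled)
        if not np.isfinite(lp):
            return lp
        return lp + log_likelihood(theta_scaled, self.targets,
                                   self.emulator.weights, self.emulator.scaling)

    def fit(self, n_draws: int = 10000, n_chains: int = 4,
            n_warmup: int = 1000, seed: int = 0,
            target_accept: float = 0.8) -> "CalibrationResults":
        draws = sample_posterior(self.targets, self.emulator.weights,
                                 self.emulator.scaling, self.priors,
                                 n_draws, n_chains, n_warmup, seed,
                                 target_accept)
        return CalibrationResults(self, draws)


class CalibrationResults:
    """Posterior sample with summaries, diagnostics and predictive checks."""

    def __init__(self, model: BayesianCalibration, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def map_estimate(self) -> np.ndarray:
        return map_estimate(self.draws)

    @property
    def diagnostics(self) -> pd.DataFrame | None:
        return self.draws.diagnostics

    def summary(self, truth: np.ndarray | None = None) -> pd.DataFrame:
        table, _ = posterior_summary(self.draws, truth)
        if self.diagnostics is not None:
            table = table.join(self.diagnostics)
        return table

    def corr(self) -> pd.DataFrame:
        return posterior_summary(self.draws)[1]

    def posterior_predictive(self, n_use: int = 1000) -> pd.DataFrame:
        return posterior_predictive(self.draws, self.model.emulator.weights,
                                    self.model.emulator.scaling, n_use)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(directory / "posterior_draws.csv")
        self.summary().to_csv(directory / "posterior_summary.csv")
        self.corr().to_csv(directory / "posterior_correlations.csv")
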