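"""Deep neural-network emulator of the simulator's input-output map.

A fully connected network with two hidden tanh layers and a linear output
layer approximates the mapping from the nine natural-history parameters to
the 36 age-grouped outcomes:

    h1 = tanh(W1 theta + b1)
    h2 = tanh(W2 h1 + b2)
    y  = W3 h2 + b3

Inputs are scaled linearly to [-1, 1] by the prior bounds and outputs by the
training-set min/max, so the network always sees well-conditioned values.
Training minimises mean-squared error with Adam (scikit-learn backend); the
fitted weights are exported as plain matrices so the posterior sampler can
evaluate the network — and its gradient — without any training framework.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .doe import DoeDataset, PriorSpec

__all__ = ["ScalingSpec", "AnnWeights", "TrainingConfig", "ValidationReport",
           "activation", "ann_forward", "ann_forward_grad", "train_ann",
           "validate_ann", "AnnEmulator"]


@dataclass(frozen=True)
class ScalingSpec:
    """Maps between natural units and the network's [-1, 1] scale.

    Input bounds come from the prior box (not the realised draws) so that
    the prior support maps exactly onto [-1, 1]^d; output bounds are the
    per-column min/max of the training outputs.  Input columns whose prior
    spans a decade or more (``upper / lower >= 10``) are mapped
    log-linearly: hazard scale parameters enter multiplicatively, and a
    linear map would compress their lower decade into a sliver of the
    network's input range and bend the likelihood ridge the posterior
    sampler must traverse.  Either way the column's prior endpoints land
    exactly on -1 and +1.
    """

    in_lower: np.ndarray
    in_upper: np.ndarray
    out_lower: np.ndarray
    out_upper: np.ndarray
    in_log: np.ndarray = None  # bool per input column

    def __post_init__(self) -> None:
        if self.in_log is None:
            object.__setattr__(self, "in_log",
                               np.zeros(len(self.in_lower), dtype=bool))

    @classmethod
    def fit(cls, priors: PriorSpec, Y_train: np.ndarray) -> "ScalingSpec":
        Y_train = np.asarray(Y_train, dtype=float)
        lo, hi = Y_train.min(axis=0), Y_train.max(axis=0)
        degenerate = hi - lo < 1e-300
        if degenerate.any():
            # constant output column: map the constant to 0
            hi = np.where(degenerate, lo + 1.0, hi)
        in_log = (priors.lower > 0) & (priors.upper >= 10.0 * priors.lower)
        return cls(priors.lower.copy(), priors.upper.copy(), lo, hi, in_log)

    @staticmethod
    def _scale(x, lo, hi):
        return 2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0

    @staticmethod
    def _unscale(z, lo, hi):
        return lo + (np.asarray(z, dtype=float) + 1.0) * (hi - lo) / 2.0

    def scale_inputs(self, theta):
        theta = np.asarray(theta, dtype=float)
        x = np.where(self.in_log, np.log(np.clip(theta, 1e-300, None)), theta)
        lo = np.where(self.in_log, np.log(self.in_lower), self.in_lower)
        hi = np.where(self.in_log, np.log(self.in_upper), self.in_upper)
        return self._scale(x, lo, hi)

    def unscale_inputs(self, z):
        lo = np.where(self.in_log, np.log(self.in_lower), self.in_lower)
        hi = np.where(self.in_log, np.log(self.in_upper), self.in_upper)
        x = self._unscale(z, lo, hi)
        return np.where(self.in_log, np.exp(x), x)

    def scale_outputs(self, y):
        return self._scale(y, self.out_lower, self.out_upper)

    def unscale_outputs(self, z):
        return self._unscale(z, self.out_lower, self.out_upper)

    @property
    def output_halfwidth(self) -> np.ndarray:
        """d(natural)/d(scaled) for each output column."""
        return (self.out_upper - self.out_lower) / 2.0

    @property
    def input_log_slope(self) -> np.ndarray:
        """d(log theta_j)/d(scaled_j) for log columns, 0 for linear ones.

        A uniform prior density on a log-mapped column is proportional to
        ``exp(slope * scaled)`` in scaled coordinates; the sampler adds this
        term so the prior stays uniform in natural units.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = 0.5 * (np.log(self.in_upper) - np.log(self.in_lower))
        return np.where(self.in_log, slope, 0.0)

    def to_json(self, path) -> None:
        doc = {k: getattr(self, k).tolist()
               for k in ("in_lower", "in_upper", "out_lower", "out_upper")}
        doc["in_log"] = self.in_log.astype(int).tolist()
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "ScalingSpec":
        doc = json.loads(Path(path).read_text())
        in_log = np.asarray(doc.pop("in_log", []), dtype=bool)
        spec = {k: np.asarray(v, dtype=float) for k, v in doc.items()}
        if len(in_log) == 0:
            in_log = np.zeros(len(spec["in_lower"]), dtype=bool)
        return cls(**spec, in_log=in_log)


@dataclass
class AnnWeights:
    """Weights and biases of the two-hidden-layer network.

    Shapes: ``W1 (J, I)``, ``W2 (K, J)``, ``W3 (O, K)`` with bias vectors to
    match; defaults I=9 inputs, J=K=100 hidden nodes, O=36 outputs.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def __post_init__(self) -> None:
        J, I = self.W1.shape
        K = self.W2.shape[0]
        O = self.W3.shape[0]
        ok = (self.b1.shape == (J,) and self.W2.shape == (K, J)
              and self.b2.shape == (K,) and self.W3.shape == (O, K)
              and self.b3.shape == (O,))
        if not ok:
            raise ValueError("inconsistent weight dimensions")
        for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W3.shape[0]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
            np.savetxt(directory / f"{name}.csv",
                       np.atleast_2d(getattr(self, name)), delimiter=",")
        arch = {"I": self.n_inputs, "J": self.W1.shape[0],
                "K": self.W2.shape[0], "O": self.n_outputs}
        (directory / "arch.json").write_text(json.dumps(arch))

    @classmethod
    def load(cls, directory) -> "AnnWeights":
        directory = Path(directory)
        vals = {}
        for name in ("W1", "W2", "W3"):
            vals[name] = np.loadtxt(directory / f"{name}.csv", delimiter=",",
                                    ndmin=2)
        for name in ("b1", "b2", "b3"):
            vals[name] = np.loadtxt(directory / f"{name}.csv",
                                    delimiter=",").ravel()
        return cls(**vals)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the emulator fit.

    Two hidden layers of 100 nodes; Adam with learning rate 1e-3 and
    minibatches of 256; up to 2000 epochs with early stopping (patience 50)
    on a 10% split of the training set.
    """

    hidden_layers: int = 2
    nodes_per_layer: int = 100
    epochs: int = 2000
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 50
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_layers", "nodes_per_layer", "epochs",
                     "batch_size", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def activation(z):
    """Hidden-layer activation ``2 / (1 + exp(-2 z)) - 1``.

    Algebraically identical to the hyperbolic tangent; implemented as tanh
    for numerical stability at large |z|.
    """
    return np.tanh(z)


def ann_forward(weights: AnnWeights, theta_scaled: np.ndarray) -> np.ndarray:
    """Evaluate the network on scaled inputs (single vector or batch rows)."""
    theta_scaled = np.asarray(theta_scaled, dtype=float)
    single = theta_scaled.ndim == 1
    X = np.atleast_2d(theta_scaled)
    if X.shape[1] != weights.n_inputs:
        raise ValueError(f"expected {weights.n_inputs} inputs, got {X.shape[1]}")
    h1 = activation(X @ weights.W1.T + weights.b1)
    h2 = activation(h1 @ weights.W2.T + weights.b2)
    Y = h2 @ weights.W3.T + weights.b3
    return Y[0] if single else Y


def ann_forward_grad(weights: AnnWeights, theta_scaled: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Network output and its Jacobian d y / d theta at one scaled input.

    Exact backpropagation through the two tanh layers; the Jacobian has
    shape (n_outputs, n_inputs) and is what the Hamiltonian sampler needs.
    """
    theta_scaled = np.asarray(theta_scaled, dtype=float)
    h1 = activation(weights.W1 @ theta_scaled + weights.b1)
    h2 = activation(weights.W2 @ h1 + weights.b2)
    y = weights.W3 @ h2 + weights.b3
    # d tanh(z)/dz = 1 - tanh(z)^2
    J2 = (weights.W3 * (1.0 - h2 ** 2)) @ weights.W2  # (O, J)
    J = (J2 * (1.0 - h1 ** 2)) @ weights.W1  # (O, I)
    return y, J


def train_ann(train: DoeDataset, config: TrainingConfig | None = None,
              scaling: ScalingSpec | None = None,
              priors: PriorSpec | None = None
              ) -> tuple[AnnWeights, np.ndarray]:
    """Fit the network on a training design, returning weights and loss history.

    Minimises mean-squared error on the scaled pairs with Adam.  The fit is
    deterministic for a fixed config seed.  Raises if the optimiser produces
    a non-finite loss.
    """
    config = config or TrainingConfig()
    if scaling is None:
        scaling = ScalingSpec.fit(priors or PriorSpec.default(), train.Y)
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    Xs = scaling.scale_inputs(train.X)
    Ys = scaling.scale_outputs(train.Y)
    mlp = MLPRegressor(
        hidden_layer_sizes=(config.nodes_per_layer,) * config.hidden_layers,
        activation="tanh",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(train)),
        max_iter=config.epochs,
        early_stopping=len(train) * config.validation_fraction >= 2,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.patience,
        tol=1e-6,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        # reaching max_iter without the tol criterion is acceptable here
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        mlp.fit(Xs, Ys)
    loss_history = np.asarray(mlp.loss_curve_)
    if not np.all(np.isfinite(loss_history)):
        raise RuntimeError("training diverged: non-finite loss encountered")
    (W1, W2, W3), (b1, b2, b3) = mlp.coefs_, mlp.intercepts_
    weights = AnnWeights(W1.T.copy(), b1.copy(), W2.T.copy(), b2.copy(),
                         W3.T.copy(), b3.copy())
    return weights, loss_history


@dataclass
class ValidationReport:
    """Per-output and pooled emulator fidelity on held-out simulator runs."""

    r2_per_output: pd.Series
    r2_pooled: float
    scatter: pd.DataFrame  # columns: output, observed, predicted (scaled)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        df = self.r2_per_output.rename("r2").rename_axis("output").reset_index()
        df.to_csv(directory / "validation_r2.csv", index=False)
        self.scatter.to_csv(directory / "validation_scatter.csv", index=False)


def validate_ann(weights: AnnWeights, valid: DoeDataset,
                 scaling: ScalingSpec) -> ValidationReport:
    """Coefficient of determination of emulator predictions on a held-out design.

    R^2 is computed per output column on the scaled values, plus a pooled
    R^2 over all columns; columns with zero variance in the validation set
    are reported as NaN and excluded from the pooled value.
    """
    if len(valid) == 0:
        raise ValueError("validation dataset is empty")
    Ys = scaling.scale_outputs(valid.Y)
    pred = ann_forward(weights, scaling.scale_inputs(valid.X))
    ss_res = ((Ys - pred) ** 2).sum(axis=0)
    ss_tot = ((Ys - Ys.mean(axis=0)) ** 2).sum(axis=0)
    cols = list(valid.outputs.columns)
    constant = ss_tot <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} output column(s) have zero variance; "
            "their R^2 is undefined and excluded from the pooled value",
            stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(constant, np.nan, 1.0 - ss_res / ss_tot)
    pooled = 1.0 - ss_res[~constant].sum() / ss_tot[~constant].sum()
    scatter = pd.DataFrame({
        "output": np.repeat(cols, len(valid)),
        "observed": Ys.T.ravel(),
        "predicted": pred.T.ravel(),
    })
    return ValidationReport(pd.Series(r2, index=cols), float(pooled), scatter)


class AnnEmulator:
    """Trained surrogate bound to its scaling: evaluates in natural units.

    ``AnnEmulator.fit(train, priors)`` trains the network;
    ``emulator.predict(theta)`` maps natural-unit parameter rows to
    natural-unit outcome predictions.
    """

    def __init__(self, weights: AnnWeights, scaling: ScalingSpec,
                 loss_history: np.ndarray | None = None):
        self.weights = weights
        self.scaling = scaling
        self.loss_history = loss_history

    @classmethod
    def fit(cls, train: DoeDataset, priors: PriorSpec | None = None,
            config: TrainingConfig | None = None) -> "AnnEmulator":
        priors = priors or PriorSpec.default()
        scaling = ScalingSpec.fit(priors, train.Y)
        weights, history = train_ann(train, config, scaling)
        return cls(weights, scaling, history)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        z = self.scaling.scale_inputs(theta)
        return self.scaling.unscale_outputs(ann_forward(self.weights, z))

    def validate(self, valid: DoeDataset) -> ValidationReport:
        return validate_ann(self.weights, valid, self.scaling)

    def save(self, directory) -> None:
        directory = Path(directory)
        self.weights.save(directory)
        self.scaling.to_json(directory / "scaling.json")

    @classmethod
    def load(cls, directory) -> "AnnEmulator":
        directory = Path(directory)
        return cls(AnnWeights.load(directory),
                   ScalingSpec.from_json(directory / "scaling.json"))
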