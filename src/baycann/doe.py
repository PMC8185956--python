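"""Latin hypercube design of experiments over the prior box.

The emulator is trained on pairs (parameter draw, simulator outputs).  Draws
come from a Latin hypercube over the uniform prior ranges: each parameter's
interval is split into ``n`` equal-width strata, each stratum receives
exactly one draw (uniform within the stratum), and stratum assignments are
permuted independently per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nathist import (LifeTable, ModelOutputs, NaturalHistoryParams,
                      run_cohort, summarize_outputs)

__all__ = ["PriorSpec", "DoeDataset", "lhs_sample", "generate_doe"]

#: Uniform prior ranges for the nine calibrated parameters.
DEFAULT_PRIOR_BOUNDS = {
    "l": (2e-6, 2e-5),
    "gamma": (2.00, 4.00),
    "lambda2": (0.01, 0.10),
    "lambda3": (0.01, 0.04),
    "lambda4": (0.20, 0.50),
    "lambda5": (0.20, 0.30),
    "lambda6": (0.30, 0.70),
    "p_adeno": (0.25, 0.35),
    "p_small": (0.38, 0.95),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: one (lower, upper) interval per parameter."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: lower must be < upper")

    @classmethod
    def default(cls) -> "PriorSpec":
        return cls(dict(DEFAULT_PRIOR_BOUNDS))

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()])

    def __len__(self) -> int:
        return len(self.bounds)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        """Elementwise membership of draws (…, d) in the closed prior box."""
        theta = np.asarray(theta)
        return ((theta >= self.lower) & (theta <= self.upper)).all(axis=-1)

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        block = doc["priors"] if "priors" in doc else doc
        return cls({name: (float(lo), float(hi)) for name, (lo, hi) in block.items()})

    def to_yaml(self, path) -> None:
        doc = {"priors": {k: [float(lo), float(hi)]
                          for k, (lo, hi) in self.bounds.items()}}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class DoeDataset:
    """Paired design matrix and simulator outputs.

    Row ``i`` of ``outputs`` was produced by the simulator at row ``i`` of
    ``inputs`` (natural parameter units); this pairing is the file contract.
    """

    inputs: pd.DataFrame
    outputs: pd.DataFrame
    role: str = "train"

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.outputs):
            raise ValueError("inputs and outputs must have the same row count")
        if self.inputs.isna().any().any() or self.outputs.isna().any().any():
            raise ValueError("design-of-experiments data must be complete")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def X(self) -> np.ndarray:
        return self.inputs.to_numpy(dtype=float)

    @property
    def Y(self) -> np.ndarray:
        return self.outputs.to_numpy(dtype=float)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.inputs.to_csv(directory / f"doe_{self.role}_inputs.csv", index=False)
        self.outputs.to_csv(directory / f"doe_{self.role}_outputs.csv", index=False)

    @classmethod
    def load(cls, directory, role: str = "train") -> "DoeDataset":
        directory = Path(directory)
        return cls(pd.read_csv(directory / f"doe_{role}_inputs.csv"),
                   pd.read_csv(directory / f"doe_{role}_outputs.csv"), role)


def lhs_sample(priors: PriorSpec, n: int,
               seed: int | np.random.SeedSequence | np.random.Generator = 0
               ) -> np.ndarray:
    """Latin hypercube sample of ``n`` points from the prior box.

    Returns an ``n x d`` matrix in natural units.  For every parameter the
    sorted draws occupy the ``n`` equal-width strata of its prior interval
    exactly once.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d = len(priors)
    # stratum index permuted per column, uniform jitter within stratum
    u = (np.stack([rng.permutation(n) for _ in range(d)], axis=1)
         + rng.random((n, d))) / n
    return priors.lower + u * (priors.upper - priors.lower)


def generate_doe(priors: PriorSpec | None = None,
                 n_train: int = 8000, n_valid: int = 2000,
                 seed: int = 0,
                 life_table: LifeTable | None = None,
                 fixed_params: dict | None = None
                 ) -> tuple[DoeDataset, DoeDataset]:
    """Build the training and validation design-of-experiments datasets.

    Draws two independent Latin hypercubes (seeded ``seed`` and ``seed + 1``)
    and runs the deterministic cohort model on every row, yielding the
    ``n x 36`` output matrices.  The deterministic model, not the
    microsimulation, generates these pairs so the emulator learns a
    noise-free input-output map.
    """
    priors = priors or PriorSpec.default()
    life_table = life_table or LifeTable.default()
    fixed_params = fixed_params or {}

    def _one(n: int, s, role: str) -> DoeDataset:
        X = lhs_sample(priors, n, s)
        Y = np.empty((n, len(ModelOutputs.column_names())))
        for i, row in enumerate(X):
            try:
                params = NaturalHistoryParams(
                    **{**fixed_params, **dict(zip(priors.names, row))})
                trace = run_cohort(params, life_table)
                Y[i] = summarize_outputs(trace).to_vector()
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"simulator failed on design row {i}: "
                    f"{dict(zip(priors.names, row))}") from exc
        return DoeDataset(pd.DataFrame(X, columns=priors.names),
                          pd.DataFrame(Y, columns=ModelOutputs.column_names()),
                          role)

    if isinstance(seed, (int, np.integer)):
        s_train, s_valid = int(seed), int(seed) + 1
    else:
        s_train, s_valid = np.random.SeedSequence(seed).spawn(2)
    return _one(n_train, s_train, "train"), _one(n_valid, s_valid, "valid")
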