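"""Colorectal-cancer natural-history model.

A nine-state state-transition model of the adenoma-carcinoma sequence:
disease-free individuals develop small adenomas at an age-dependent Weibull
rate, adenomas may grow and progress to preclinical then clinical cancer by
stage, and every alive state is exposed to background mortality.  Transitions
follow a continuous-time age-inhomogeneous Markov process; annual cycle
probabilities are obtained by exponentiating the age-specific generator, so
competing risks within a cycle are handled exactly.

Two evaluation modes share the same generator: a deterministic cohort model
(expected state occupancy propagated through the annual transition matrices)
and a stochastic microsimulation (individual trajectories sampled one
categorical draw per person-cycle).  Both are summarised into the same four
age-grouped outcome series used as calibration targets: adenoma prevalence,
the proportion of adenomas that are small, and clinical cancer incidence for
early and late stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "STATES",
    "NaturalHistoryParams",
    "LifeTable",
    "CohortTrace",
    "ModelOutputs",
    "CrcModel",
    "weibull_adenoma_hazard",
    "build_generator",
    "transition_matrix",
    "run_cohort",
    "summarize_outputs",
    "run_microsim",
    "AGE_GROUP_STARTS",
    "TARGET_TYPES",
]

#: Ordered health states.  Progression only ever moves to a higher index,
#: so every generator built here is upper triangular.
STATES = (
    "normal",
    "small_adenoma",
    "large_adenoma",
    "preclin_early",
    "preclin_late",
    "clin_early",
    "clin_late",
    "crc_death",
    "other_death",
)

_IDX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)
_ALIVE = slice(0, 7)  # all states before the two absorbing death states
_NONCLIN_ALIVE = slice(0, 5)  # alive and not clinically detected

#: Nine 5-year age groups starting at these ages; 4 series x 9 groups = 36 outcomes.
AGE_GROUP_STARTS = tuple(range(50, 95, 5))

#: Outcome series in canonical (alphabetical) order.  This ordering is the
#: column contract shared by the design-of-experiments files, the emulator
#: outputs and the calibration-target files.
TARGET_TYPES = ("adenoma_prev", "inc_early", "inc_late", "prop_small")


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Parameters of the natural-history model.

    Rates are annual transition intensities.  ``l`` and ``gamma`` are the
    scale and shape of the Weibull adenoma-onset hazard
    ``lambda1(a) = l * gamma * a**(gamma - 1)``.  ``lambda7`` and ``lambda8``
    (stage-specific cancer mortality after clinical detection) are treated as
    known and held fixed; the remaining nine parameters are calibrated.
    """

    l: float = 2.86e-6
    gamma: float = 2.78
    lambda2: float = 0.0346  # small adenoma -> large adenoma
    lambda3: float = 0.0215  # large adenoma -> preclinical early CRC
    lambda4: float = 0.3697  # preclinical early -> preclinical late
    lambda5: float = 0.2382  # preclinical early -> clinical early
    lambda6: float = 0.4852  # preclinical late -> clinical late
    lambda7: float = 0.0302  # clinical early CRC mortality (fixed)
    lambda8: float = 0.2099  # clinical late CRC mortality (fixed)
    p_adeno: float = 0.27  # adenoma prevalence at age 50
    p_small: float = 0.71  # proportion of adenomas small at age 50
    #: absolute cohort proportions in preclinical CRC at age 50
    p_preclin_early: float = 0.12
    p_preclin_late: float = 0.08

    #: names of the nine calibrated parameters, in canonical order
    CALIBRATED: tuple[str, ...] = field(
        default=("l", "gamma", "lambda2", "lambda3", "lambda4",
                 "lambda5", "lambda6", "p_adeno", "p_small"),
        init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for f in ("l", "lambda2", "lambda3", "lambda4", "lambda5",
                  "lambda6", "lambda7", "lambda8"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for f in ("p_adeno", "p_small", "p_preclin_early", "p_preclin_late"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1]")

    def calibrated_vector(self) -> np.ndarray:
        """The nine calibrated parameters as a vector in canonical order."""
        return np.array([getattr(self, n) for n in self.CALIBRATED])

    @classmethod
    def from_calibrated_vector(cls, theta: np.ndarray,
                               **fixed) -> "NaturalHistoryParams":
        """Build a parameter set from the nine calibrated values.

        Fixed parameters (``lambda7``, ``lambda8``, preclinical seeds) keep
        their defaults unless overridden through ``fixed``.
        """
        theta = np.asarray(theta, dtype=float)
        base = cls()
        names = base.CALIBRATED
        if theta.shape != (len(names),):
            raise ValueError(f"expected {len(names)} values, got {theta.shape}")
        return replace(cls(**fixed) if fixed else base,
                       **dict(zip(names, theta)))

    def initial_distribution(self) -> np.ndarray:
        """Cohort state distribution at the starting age (50)."""
        x = np.zeros(N_STATES)
        x[_IDX["small_adenoma"]] = self.p_adeno * self.p_small
        x[_IDX["large_adenoma"]] = self.p_adeno * (1.0 - self.p_small)
        x[_IDX["preclin_early"]] = self.p_preclin_early
        x[_IDX["preclin_late"]] = self.p_preclin_late
        x[_IDX["normal"]] = 1.0 - x.sum()
        if x[_IDX["normal"]] < 0:
            raise ValueError("initial state proportions exceed 1")
        return x


class LifeTable:
    """All-cause mortality rates by single year of age.

    Parameters
    ----------
    age, mu : array-like
        Contiguous integer ages and the corresponding annual mortality
        rates (1/year).  Rates must be non-negative and non-decreasing.
    """

    def __init__(self, age, mu):
        age = np.asarray(age, dtype=int)
        mu = np.asarray(mu, dtype=float)
        if age.ndim != 1 or age.shape != mu.shape:
            raise ValueError("age and mu must be 1-D and the same length")
        if np.any(np.diff(age) != 1):
            raise ValueError("ages must be contiguous integers")
        if np.any(mu < 0):
            raise ValueError("mortality rates must be non-negative")
        if np.any(np.diff(mu) < 0):
            raise ValueError("mortality rates must be non-decreasing in age")
        self.age = age
        self.mu = mu

    def rate(self, a):
        """Mortality rate at integer age(s) ``a``."""
        a = np.asarray(a, dtype=int)
        if np.any(a < self.age[0]) or np.any(a > self.age[-1]):
            raise ValueError(
                f"age outside life-table range [{self.age[0]}, {self.age[-1]}]")
        return self.mu[a - self.age[0]]

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["mu"].to_numpy())

    @classmethod
    def default(cls) -> "LifeTable":
        """The bundled synthetic life table.

        A Gompertz schedule ``mu(a) = 5e-5 * exp(0.085 a)`` over ages
        50-100, approximating a U.S. female period life table.  Synthetic:
        generated from the parametric form, not transcribed from a register.
        """
        ref = resources.files("baycann.data") / "lifetable_synthetic.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.age, "mu": self.mu}).to_csv(path, index=False)


@dataclass
class CohortTrace:
    """Annual state occupancy of a closed cohort.

    ``occupancy[t]`` is the state distribution at the start of the cycle
    beginning at ``ages[t]``; the final row is the distribution at the end
    age.  ``inflow_clin_early`` / ``inflow_clin_late`` hold, for each of the
    ``len(ages) - 1`` cycles, the cohort proportion newly entering the
    clinical state during that cycle.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    inflow_clin_early: np.ndarray
    inflow_clin_late: np.ndarray

    def __post_init__(self) -> None:
        if self.occupancy.shape != (len(self.ages), N_STATES):
            raise ValueError("occupancy must be len(ages) x 9")
        if np.any(self.occupancy < -1e-12):
            raise ValueError("negative occupancy")
        if np.any(np.abs(self.occupancy.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("occupancy rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df["inflow_clin_early"] = np.append(self.inflow_clin_early, 0.0)
        df["inflow_clin_late"] = np.append(self.inflow_clin_late, 0.0)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ModelOutputs:
    """The 36 age-grouped outcomes: four series over nine 5-year age groups.

    ``adenoma_prev`` and ``prop_small`` are proportions among alive,
    not-yet-clinical individuals; ``inc_early`` and ``inc_late`` are annual
    clinical-detection incidence rates per person-year at risk.
    """

    adenoma_prev: np.ndarray
    prop_small: np.ndarray
    inc_early: np.ndarray
    inc_late: np.ndarray

    def __post_init__(self) -> None:
        for name in ("adenoma_prev", "prop_small", "inc_early", "inc_late"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(AGE_GROUP_STARTS),):
                raise ValueError(f"{name} must have {len(AGE_GROUP_STARTS)} values")
            setattr(self, name, v)

    def to_vector(self) -> np.ndarray:
        """All 36 outcomes, series in canonical order then ascending age group."""
        return np.concatenate([getattr(self, t) for t in TARGET_TYPES])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ModelOutputs":
        v = np.asarray(v, dtype=float)
        n = len(AGE_GROUP_STARTS)
        if v.shape != (n * len(TARGET_TYPES),):
            raise ValueError(f"expected {n * len(TARGET_TYPES)} values")
        parts = dict(zip(TARGET_TYPES, v.reshape(len(TARGET_TYPES), n)))
        return cls(**parts)

    @staticmethod
    def column_names() -> list[str]:
        return [f"{t}_{a}" for t in TARGET_TYPES for a in AGE_GROUP_STARTS]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per outcome."""
        return pd.DataFrame({
            "target_type": np.repeat(TARGET_TYPES, len(AGE_GROUP_STARTS)),
            "age_group_start": np.tile(AGE_GROUP_STARTS, len(TARGET_TYPES)),
            "value": self.to_vector(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def weibull_adenoma_hazard(l: float, gamma: float, a) -> np.ndarray | float:
    """Age-dependent adenoma-onset hazard ``l * gamma * a**(gamma - 1)``.

    Increasing in age for ``gamma > 1`` and constant for ``gamma == 1``.
    """
    if l < 0:
        raise ValueError("scale l must be non-negative")
    if gamma <= 0:
        raise ValueError("shape gamma must be positive")
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("age must be positive")
    out = l * gamma * a ** (gamma - 1.0)
    return out.item() if out.ndim == 0 else out


def build_generator(params: NaturalHistoryParams, a: float, mu: float) -> np.ndarray:
    """Continuous-time rate matrix at age ``a`` with background mortality ``mu``.

    Off-diagonal entries carry the progression arrows; every alive state also
    flows to death from other causes at rate ``mu``.  Rows of the two death
    states are zero (absorbing) and each row sums to zero.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    Q = np.zeros((N_STATES, N_STATES))
    Q[_IDX["normal"], _IDX["small_adenoma"]] = weibull_adenoma_hazard(
        params.l, params.gamma, a)
    Q[_IDX["small_adenoma"], _IDX["large_adenoma"]] = params.lambda2
    Q[_IDX["large_adenoma"], _IDX["preclin_early"]] = params.lambda3
    Q[_IDX["preclin_early"], _IDX["preclin_late"]] = params.lambda4
    Q[_IDX["preclin_early"], _IDX["clin_early"]] = params.lambda5
    Q[_IDX["preclin_late"], _IDX["clin_late"]] = params.lambda6
    Q[_IDX["clin_early"], _IDX["crc_death"]] = params.lambda7
    Q[_IDX["clin_late"], _IDX["crc_death"]] = params.lambda8
    Q[_ALIVE, _IDX["other_death"]] = mu
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Cycle transition probabilities ``expm(Q * dt)`` for a generator ``Q``.

    The matrix exponential embeds the continuous-time process exactly over
    the cycle, including multi-step paths (e.g. adenoma onset and growth
    within one year), which per-arrow ``1 - exp(-r)`` conversions would miss.
    """
    Q = np.asarray(Q, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(np.diag(Q) > 1e-12) or np.any(off < -1e-12):
        raise ValueError("Q is not a generator (positive diagonal or "
                         "negative off-diagonal entries)")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-9):
        raise ValueError("generator rows must sum to zero")
    P = expm(Q * dt)
    # expm can return tiny negative round-off; clip and renormalise
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _transition_matrices(params: NaturalHistoryParams, life_table: LifeTable,
                         ages: np.ndarray) -> np.ndarray:
    # internal fast path: generators built here are valid by construction,
    # so skip transition_matrix's re-validation
    mus = life_table.rate(ages)
    out = np.empty((len(ages), N_STATES, N_STATES))
    for k, (a, m) in enumerate(zip(ages, mus)):
        P = expm(build_generator(params, float(a), float(m)))
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        out[k] = P
    return out


def run_cohort(params: NaturalHistoryParams, life_table: LifeTable | None = None,
               age_start: int = 50, age_end: int = 95) -> CohortTrace:
    """Propagate expected state occupancy annually from ``age_start`` to ``age_end``.

    Cycles start at integer ages ``age_start .. age_end - 1``.  Each cycle
    applies the transition matrix built from the generator at the cycle's
    starting age.  Per-cycle inflows into the clinical states (new clinical
    detections) are recorded for the incidence outcomes.
    """
    if life_table is None:
        life_table = LifeTable.default()
    cycle_ages = np.arange(age_start, age_end)
    if cycle_ages[0] < life_table.age[0] or cycle_ages[-1] > life_table.age[-1]:
        raise ValueError("life table does not cover the simulated ages")
    P = _transition_matrices(params, life_table, cycle_ages)

    n_cycles = len(cycle_ages)
    occ = np.empty((n_cycles + 1, N_STATES))
    occ[0] = params.initial_distribution()
    inflow_e = np.empty(n_cycles)
    inflow_l = np.empty(n_cycles)
    ce, cl = _IDX["clin_early"], _IDX["clin_late"]
    for t in range(n_cycles):
        x = occ[t]
        inflow_e[t] = x @ P[t, :, ce] - x[ce] * P[t, ce, ce]
        inflow_l[t] = x @ P[t, :, cl] - x[cl] * P[t, cl, cl]
        occ[t + 1] = x @ P[t]
    return CohortTrace(np.arange(age_start, age_end + 1), occ, inflow_e, inflow_l)


def _bin_slices(ages: np.ndarray):
    """Cycle-index slices for each 5-year age group."""
    out = []
    for start in AGE_GROUP_STARTS:
        mask = (ages[:-1] >= start) & (ages[:-1] < start + 5)
        if not mask.any():
            raise ValueError(f"trace does not cover age group starting {start}")
        out.append(np.nonzero(mask)[0])
    return out


def summarize_outputs(trace: CohortTrace) -> ModelOutputs:
    """Collapse an annual trace into the 36 age-grouped outcomes.

    Within each 5-year group, person-time in each state is accumulated over
    the group's cycles (occupancy at cycle start).  Adenoma prevalence and
    the small-adenoma proportion are ratios of accumulated person-time;
    incidence divides accumulated new clinical detections by accumulated
    at-risk (alive, not yet clinical) person-time.
    """
    occ = trace.occupancy
    small, large = _IDX["small_adenoma"], _IDX["large_adenoma"]
    prev, psmall, ince, incl = [], [], [], []
    for idx in _bin_slices(trace.ages):
        o = occ[idx]
        at_risk = o[:, _NONCLIN_ALIVE].sum()
        adeno_small = o[:, small].sum()
        adeno_large = o[:, large].sum()
        adeno = adeno_small + adeno_large
        prev.append(adeno / at_risk if at_risk > 1e-12 else 0.0)
        if adeno < 1e-12:
            warnings.warn("no adenoma occupancy in an age group; "
                          "prop_small reported as 0", stacklevel=2)
            psmall.append(0.0)
        else:
            psmall.append(adeno_small / adeno)
        if at_risk > 1e-12:
            ince.append(trace.inflow_clin_early[idx].sum() / at_risk)
            incl.append(trace.inflow_clin_late[idx].sum() / at_risk)
        else:
            ince.append(0.0)
            incl.append(0.0)
    return ModelOutputs(np.array(prev), np.array(psmall),
                        np.array(ince), np.array(incl))


def run_microsim(params: NaturalHistoryParams, n: int,
                 life_table: LifeTable | None = None,
                 seed: int | np.random.SeedSequence | np.random.Generator = 0,
                 age_start: int = 50, age_end: int = 95,
                 empty_as_nan: bool = False) -> ModelOutputs:
    """Stochastic microsimulation of ``n`` individual trajectories.

    Each alive individual makes one categorical draw per cycle from the row
    of the current transition matrix for their state.  Outputs use the same
    age grouping and denominators as the cohort summary, with person-counts
    in place of expected occupancy.  The same seed reproduces the same
    outputs exactly.

    With ``empty_as_nan`` an outcome whose denominator has no person-time in
    an age group is reported as NaN instead of 0, so replicate aggregation
    can drop it.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if life_table is None:
        life_table = LifeTable.default()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cycle_ages = np.arange(age_start, age_end)
    P = _transition_matrices(params, life_table, cycle_ages)
    cum = np.cumsum(P, axis=2)

    init = params.initial_distribution()
    state = rng.choice(N_STATES, size=n, p=init)
    small, large = _IDX["small_adenoma"], _IDX["large_adenoma"]
    ce, cl = _IDX["clin_early"], _IDX["clin_late"]

    n_cycles = len(cycle_ages)
    counts = np.zeros((n_cycles, N_STATES))
    new_e = np.zeros(n_cycles)
    new_l = np.zeros(n_cycles)
    for t in range(n_cycles):
        counts[t] = np.bincount(state, minlength=N_STATES)
        alive = state < _IDX["crc_death"]
        u = rng.random(alive.sum())
        rows = cum[t, state[alive]]
        nxt = (rows < u[:, None]).sum(axis=1)
        was = state[alive]
        new_e[t] = np.count_nonzero((nxt == ce) & (was != ce))
        new_l[t] = np.count_nonzero((nxt == cl) & (was != cl))
        state[alive] = nxt

    empty = np.nan if empty_as_nan else 0.0
    prev, psmall, ince, incl = [], [], [], []
    for idx in _bin_slices(np.append(cycle_ages, age_end)):
        c = counts[idx]
        at_risk = c[:, _NONCLIN_ALIVE].sum()
        adeno_small = c[:, small].sum()
        adeno = adeno_small + c[:, large].sum()
        prev.append(adeno / at_risk if at_risk > 0 else empty)
        psmall.append(adeno_small / adeno if adeno > 0 else empty)
        ince.append(new_e[idx].sum() / at_risk if at_risk > 0 else empty)
        incl.append(new_l[idx].sum() / at_risk if at_risk > 0 else empty)
    return ModelOutputs(np.array(prev), np.array(psmall),
                        np.array(ince), np.array(incl))


class CrcModel:
    """Convenience wrapper binding parameters to a life table.

    ``CrcModel(params).cohort_outputs()`` runs the deterministic cohort model
    and summarises it; ``microsim_outputs(n, seed)`` runs the stochastic
    counterpart.
    """

    def __init__(self, params: NaturalHistoryParams | None = None,
                 life_table: LifeTable | None = None,
                 age_start: int = 50, age_end: int = 95):
        self.params = params or NaturalHistoryParams()
        self.life_table = life_table or LifeTable.default()
        self.age_start = age_start
        self.age_end = age_end

    def cohort_trace(self) -> CohortTrace:
        return run_cohort(self.params, self.life_table,
                          self.age_start, self.age_end)

    def cohort_outputs(self) -> ModelOutputs:
        return summarize_outputs(self.cohort_trace())

    def microsim_outputs(self, n: int, seed=0) -> ModelOutputs:
        return run_microsim(self.params, n, self.life_table, seed,
                            self.age_start, self.age_end)
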