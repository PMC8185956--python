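"""End-to-end confirmatory study: can calibration recover known parameters?

The study generates synthetic calibration targets by running the
microsimulation at a known "true" parameter set, builds the Latin-hypercube
design, trains and validates the emulator, samples the posterior, and
reports whether each parameter's 95% credible interval covers its true
value.  An importance-sampling comparison arm (IMIS, run directly on the
simulator) can be added alongside.

All randomness flows from one master seed through named substreams
(targets, design, training, sampler, imis), so each stage can be re-run in
isolation and two runs with the same master seed produce identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import (BayesianCalibration, CalibrationResults,
                        CalibrationTargets, PosteriorDraws, posterior_summary)
from .doe import DoeDataset, PriorSpec, generate_doe
from .emulator import AnnEmulator, TrainingConfig, ValidationReport
from .imis import imis_calibrate, simulator_loglik
from .nathist import (LifeTable, ModelOutputs, NaturalHistoryParams,
                      run_microsim)

__all__ = ["StudyConfig", "StudyReport", "generate_targets", "run_baycann",
           "run_comparison"]

_SEED_STREAMS = ("targets", "doe", "training", "sampler", "imis")


def _substream_seeds(master_seed: int) -> dict[str, int]:
    """Named 31-bit sub-seeds derived from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_SEED_STREAMS))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_SEED_STREAMS, children)}


@dataclass
class StudyConfig:
    """Everything the confirmatory pipeline needs, in one place.

    Defaults reproduce the full-scale study: targets from 100 microsimulation
    replicates (500 individuals for adenoma series, 100,000 for incidence),
    an 8,000/2,000 design, the 2x100 tanh network, and 10,000 posterior
    draws.  The ``test`` profile scales these down for quick runs.
    """

    truth: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    priors: PriorSpec = field(default_factory=PriorSpec.default)
    reps: int = 100
    n_adenoma: int = 500
    n_incidence: int = 100000
    n_train: int = 8000
    n_valid: int = 2000
    training: TrainingConfig = field(default_factory=TrainingConfig)
    sampler: dict = field(default_factory=lambda: {
        "n_draws": 10000, "n_chains": 4, "n_warmup": 1000})
    imis: dict = field(default_factory=lambda: {
        "n0": 1000, "b": 100, "n_resample": 10000, "max_iter": 100})
    fidelity_r2: float = 0.999
    #: "sd": target uncertainty is the across-replicate SD — the sampling
    #: uncertainty a single study of the stated N would carry, which is what
    #: the two cohort sizes are meant to emulate.  "se": SD/sqrt(reps), the
    #: uncertainty of the replicate mean itself.
    target_sigma: str = "sd"
    seed: int = 0
    outdir: Path | None = None

    def __post_init__(self) -> None:
        for name in ("reps", "n_adenoma", "n_incidence", "n_train", "n_valid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.target_sigma not in ("se", "sd"):
            raise ValueError("target_sigma must be 'se' or 'sd'")
        if not self.priors.contains(self.truth.calibrated_vector()):
            raise ValueError("truth must lie inside the prior box")
        if self.outdir is not None:
            self.outdir = Path(self.outdir)

    @property
    def seeds(self) -> dict[str, int]:
        return _substream_seeds(self.seed)

    @classmethod
    def from_profile(cls, profile: str = "paper", **overrides) -> "StudyConfig":
        """Load a bundled profile ('paper' full scale, 'test' desk scale)."""
        ref = resources.files("baycann.profiles") / f"{profile}.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path, **overrides)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        if "training" in doc and isinstance(doc["training"], dict):
            doc["training"] = TrainingConfig(**doc["training"])
        if "priors" in doc and isinstance(doc["priors"], dict):
            doc["priors"] = PriorSpec({k: tuple(v)
                                       for k, v in doc["priors"].items()})
        if "truth" in doc and isinstance(doc["truth"], dict):
            doc["truth"] = NaturalHistoryParams(**doc["truth"])
        return cls(**doc)

    def echo(self) -> dict:
        """JSON-serialisable snapshot of the configuration."""
        doc = {
            "truth": {f: getattr(self.truth, f)
                      for f in self.truth.CALIBRATED},
            "priors": {k: list(v) for k, v in self.priors.bounds.items()},
            "training": asdict(self.training),
            "sampler": dict(self.sampler),
            "imis": dict(self.imis),
        }
        for name in ("reps", "n_adenoma", "n_incidence", "n_train", "n_valid",
                     "fidelity_r2", "target_sigma", "seed"):
            doc[name] = getattr(self, name)
        return doc


def generate_targets(config: StudyConfig,
                     life_table: LifeTable | None = None
                     ) -> CalibrationTargets:
    """Synthetic calibration targets from replicate microsimulations at truth.

    Runs the microsimulation ``reps`` times with ``n_adenoma`` individuals
    (feeding the adenoma prevalence and small-proportion series) and
    ``reps`` times with ``n_incidence`` individuals (feeding the two
    incidence series), on independent random streams.  Each target's mean is
    the replicate average; its uncertainty is the replicate SD divided by
    sqrt(reps) (standard error of the mean) or the raw SD, per
    ``config.target_sigma``.  Replicates with an empty denominator for a
    target are dropped from that target's aggregate with a warning.
    """
    if config.reps < 2:
        raise ValueError("at least 2 replicates are needed to estimate "
                         "target uncertainty")
    life_table = life_table or LifeTable.default()
    ss = np.random.SeedSequence(config.seeds["targets"])
    streams = ss.spawn(2 * config.reps)
    rows = []
    for r in range(config.reps):
        small_n = run_microsim(config.truth, config.n_adenoma, life_table,
                               np.random.default_rng(streams[r]),
                               empty_as_nan=True)
        big_n = run_microsim(config.truth, config.n_incidence, life_table,
                             np.random.default_rng(streams[config.reps + r]),
                             empty_as_nan=True)
        row = np.concatenate([
            small_n.adenoma_prev, big_n.inc_early, big_n.inc_late,
            small_n.prop_small])  # canonical series order
        rows.append(row)
    M = np.asarray(rows)
    n_valid = np.sum(np.isfinite(M), axis=0)
    if (n_valid < config.reps).any():
        warnings.warn(
            f"{int((config.reps - n_valid).sum())} replicate outcome(s) had "
            "empty denominators and were excluded", stacklevel=2)
    if (n_valid < 2).any():
        raise RuntimeError("fewer than 2 valid replicates for some target")
    means = np.nanmean(M, axis=0)
    sds = np.nanstd(M, axis=0, ddof=1)
    ses = sds / np.sqrt(n_valid) if config.target_sigma == "se" else sds
    # a target that never varies across replicates carries no information;
    # give it a tiny positive uncertainty so the likelihood stays proper
    ses = np.clip(ses, 1e-12, None)
    return CalibrationTargets.from_arrays(means, ses)


@dataclass
class StudyReport:
    """Artifacts of one confirmatory run."""

    config: StudyConfig
    targets: CalibrationTargets
    train: DoeDataset
    valid: DoeDataset
    emulator: AnnEmulator
    validation: ValidationReport
    results: CalibrationResults
    summary: pd.DataFrame
    predictive: pd.DataFrame
    imis_draws: "PosteriorDraws | None" = None
    comparison: pd.DataFrame | None = None

    @property
    def covered_count(self) -> int:
        return int(self.summary["covered"].sum())

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.targets.to_csv(outdir / "targets.csv")
        self.train.save(outdir)
        self.valid.save(outdir)
        self.emulator.save(outdir / "emulator")
        self.validation.save(outdir)
        self.results.save(outdir)
        self.summary.to_csv(outdir / "recovery_summary.csv")
        self.predictive.to_csv(outdir / "posterior_predictive.csv", index=False)
        if self.imis_draws is not None:
            self.imis_draws.to_csv(outdir / "imis_draws.csv")
        if self.comparison is not None:
            self.comparison.to_csv(outdir / "comparison.csv")
        self._write_manifest(outdir)

    def _write_manifest(self, outdir: Path) -> None:
        checksums = {}
        for p in sorted(outdir.rglob("*.csv")):
            checksums[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
        manifest = {
            "config": self.config.echo(),
            "seeds": self.config.seeds,
            "validation_r2_pooled": self.validation.r2_pooled,
            "covered_count": self.covered_count,
            "artifact_sha256": checksums,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_baycann(config: StudyConfig,
                life_table: LifeTable | None = None,
                targets: CalibrationTargets | None = None) -> StudyReport:
    """The five study stages: targets, design, emulator, validation, sampling.

    Stops with a ``RuntimeError`` carrying the validation report if the
    emulator's pooled validation R^2 falls below the fidelity gate —
    calibrating a low-fidelity surrogate gives confidently wrong posteriors.
    """
    life_table = life_table or LifeTable.default()
    seeds = config.seeds
    if targets is None:
        targets = generate_targets(config, life_table)
    train, valid = generate_doe(config.priors, config.n_train, config.n_valid,
                                seeds["doe"], life_table)
    tcfg = TrainingConfig(**{**asdict(config.training),
                             "seed": seeds["training"]})
    emulator = AnnEmulator.fit(train, config.priors, tcfg)
    validation = emulator.validate(valid)
    if validation.r2_pooled < config.fidelity_r2:
        raise RuntimeError(
            f"emulator fidelity gate failed: pooled validation R^2 = "
            f"{validation.r2_pooled:.5f} < {config.fidelity_r2}; "
            "adjust the network or enlarge the design before calibrating")
    model = BayesianCalibration(targets, emulator, config.priors)
    results = model.fit(seed=seeds["sampler"], **config.sampler)
    summary = results.summary(truth=config.truth.calibrated_vector())
    n_use = min(len(results.draws), 2000)
    predictive = results.posterior_predictive(n_use=n_use)
    report = StudyReport(config, targets, train, valid, emulator, validation,
                         results, summary, predictive)
    if config.outdir is not None:
        report.save(config.outdir)
    return report


def run_comparison(config: StudyConfig,
                   life_table: LifeTable | None = None,
                   report: StudyReport | None = None) -> StudyReport:
    """Add the IMIS arm and a side-by-side recovery table to a study run."""
    life_table = life_table or LifeTable.default()
    if report is None:
        report = run_baycann(config, life_table)
    loglik = simulator_loglik(report.targets, config.priors, life_table)
    imis_draws = imis_calibrate(loglik, config.priors,
                                seed=config.seeds["imis"], **config.imis)
    imis_summary, _ = posterior_summary(
        imis_draws, config.truth.calibrated_vector())
    bay = report.summary
    comparison = pd.DataFrame({
        "truth": bay["truth"],
        "baycann_mean": bay["mean"], "baycann_lo": bay["ci_lo"],
        "baycann_hi": bay["ci_hi"], "baycann_covered": bay["covered"],
        "baycann_map": bay["map"],
        "imis_mean": imis_summary["mean"], "imis_lo": imis_summary["ci_lo"],
        "imis_hi": imis_summary["ci_hi"],
        "imis_covered": imis_summary["covered"],
        "imis_map": imis_summary["map"],
    })
    report.imis_draws = imis_draws
    report.comparison = comparison
    if config.outdir is not None:
        report.save(config.outdir)
    return report
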