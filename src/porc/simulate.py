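"""Synthetic patient cohorts with the statistical structure of a PACU study.

The generator emulates a cohort of awake, freshly extubated patients in whom
residual neuromuscular block is quantified by a latent train-of-four ratio
(TOFR):

* the latent TOFR follows a truncated normal distribution (published cohorts
  report a mean near 0.61, SD near 0.31, observed range 0.0-1.15 at the time
  of assessment);
* calibrated EMG measures the latent TOFR with small additive noise (the
  gold standard); uncalibrated AMG overestimates it by a multiplicative bias
  with extra noise;
* each of the eight bedside test scores follows an ordered-threshold
  (cumulative logistic) link, so the expected score is nondecreasing in TOFR
  with muscle-group-specific location and steepness;
* tactile fading after nerve stimulation is detectable only at low TOFR and
  never above a detection limit (~0.4);
* EMG traces sampled at 20 s intervals occasionally contain artefactual
  drops of more than 20%, the pattern the stability QC rule screens for.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .cohort import (
    INTRAORAL_MISSING,
    NOT_PALPABLE,
    PALPABLE,
    SCORE_RANGES,
    TEST_NAMES,
    EmgTrace,
    PatientRecord,
    TestScores,
)
from .errors import ConfigError


@dataclass(frozen=True)
class ScoreProfile:
    """Monotone link parameters of one test.

    ``location`` is the TOFR at which the expected score sits mid-scale;
    ``steepness`` is the inverse scale of the logistic latent noise (use
    ``math.inf`` for a deterministic, noiseless link).
    """

    location: float
    steepness: float


#: Default per-test link parameters.  Locations encode the well-known
#: muscle-group ordering of sensitivity to residual block: facial muscles
#: recover early (low location), lifts and upper-airway function require
#: near-complete recovery (high location).
DEFAULT_PROFILES: dict[str, ScoreProfile] = {
    "open_eyes": ScoreProfile(0.30, 10.0),
    "diplopia": ScoreProfile(0.45, 8.0),
    "tongue": ScoreProfile(0.35, 10.0),
    "spatula": ScoreProfile(0.35, 9.0),
    "head_lift": ScoreProfile(0.50, 10.0),
    "arm_lift": ScoreProfile(0.55, 10.0),
    "hand_press": ScoreProfile(0.40, 9.0),
    "swallow": ScoreProfile(0.55, 8.0),
}


@dataclass
class SimulationConfig:
    """Parameters of the cohort generator.

    Defaults target the published development-cohort summary statistics:
    TOFR at assessment 0.61 +/- 0.31 on the observed range [0, 1.15], AMG
    overestimating EMG, an intraoral-surgery fraction of 9/200 and an
    instability rate that loses roughly 13% of traces to the QC rule.
    """

    n_patients: int = 165
    tofr_mean: float = 0.61
    tofr_sd: float = 0.31
    tofr_range: tuple[float, float] = (0.0, 1.15)
    emg_noise_sd: float = 0.02
    amg_bias: float = 1.10
    amg_noise_sd: float = 0.05
    test_profiles: dict[str, ScoreProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    tactile_detect_limit: float = 0.4
    tactile_detect_prob: float = 0.9
    tactile_full_below: float = 0.1
    instability_rate: float = 0.045
    trace_length: int = 15
    trace_jitter: float = 0.05
    intraoral_rate: float = 0.045
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 <= self.tofr_mean <= 1.3:
            raise ConfigError("tofr_mean must lie in [0, 1.3]")
        if self.tofr_sd < 0:
            raise ConfigError("tofr_sd must be >= 0")
        lo, hi = self.tofr_range
        if not lo < hi:
            raise ConfigError("tofr_range must satisfy min < max")
        if self.amg_bias < 1.0:
            raise ConfigError("amg_bias must be >= 1")
        if self.amg_noise_sd < 0 or self.emg_noise_sd < 0:
            raise ConfigError("amg_noise_sd / emg_noise_sd must be >= 0")
        if self.trace_length < 2:
            raise ConfigError("trace_length must be >= 2")
        if not 0.0 <= self.instability_rate <= 1.0:
            raise ConfigError("instability_rate must lie in [0, 1]")
        if not 0.0 <= self.intraoral_rate <= 1.0:
            raise ConfigError("intraoral_rate must lie in [0, 1]")
        if not 0.0 <= self.tactile_detect_prob <= 1.0:
            raise ConfigError("tactile_detect_prob must lie in [0, 1]")
        if not 0.0 <= self.tactile_full_below <= self.tactile_detect_limit:
            raise ConfigError(
                "tactile_full_below must lie in [0, tactile_detect_limit]"
            )
        for name in self.test_profiles:
            if name not in SCORE_RANGES:
                raise ConfigError(f"unknown test in test_profiles: {name!r}")
        for name in SCORE_RANGES:
            if name not in self.test_profiles:
                raise ConfigError(f"test_profiles missing test {name!r}")

    # -- file round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["test_profiles"] = {
            k: [v.location, v.steepness] for k, v in self.test_profiles.items()
        }
        d["tofr_range"] = list(self.tofr_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "test_profiles" in d:
            d["test_profiles"] = {
                k: ScoreProfile(*v) for k, v in d["test_profiles"].items()
            }
        if "tofr_range" in d:
            d["tofr_range"] = tuple(d["tofr_range"])
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "seed" not in data:
            raise ConfigError("config file must set 'seed'")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Latent TOFR


def truncated_normal_mean(config: SimulationConfig) -> float:
    """Mean of the truncated normal the latent TOFR is drawn from."""
    lo, hi = config.tofr_range
    if config.tofr_sd == 0:
        return float(np.clip(config.tofr_mean, lo, hi))
    a = (lo - config.tofr_mean) / config.tofr_sd
    b = (hi - config.tofr_mean) / config.tofr_sd
    return float(truncnorm.mean(a, b, loc=config.tofr_mean, scale=config.tofr_sd))


def _draw_latent_tofr(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.tofr_range
    if config.tofr_sd == 0:
        return np.full(config.n_patients, np.clip(config.tofr_mean, lo, hi))
    a = (lo - config.tofr_mean) / config.tofr_sd
    b = (hi - config.tofr_mean) / config.tofr_sd
    return truncnorm.rvs(
        a, b, loc=config.tofr_mean, scale=config.tofr_sd,
        size=config.n_patients, random_state=rng,
    )


# ---------------------------------------------------------------------------
# Test scores


def _cutpoints(name: str, profile: ScoreProfile) -> np.ndarray:
    lo, hi = SCORE_RANGES[name]
    m = hi - lo
    # m cutpoints centred on the location, spanning ~0.5 TOFR units.
    k = np.arange(1, m + 1)
    delta = 0.5 / m
    return profile.location + (k - (m + 1) / 2.0) * delta


def simulate_scores(
    tofr: float,
    profiles: Mapping[str, ScoreProfile],
    rng: np.random.Generator,
    missing: Sequence[str] = (),
) -> TestScores:
    """Draw one patient's eight test scores from their monotone links.

    Each test uses an ordered-threshold model: a logistic latent variable
    centred on the patient's TOFR is compared against evenly spaced
    cutpoints around the test's location; the score is the number of
    cutpoints exceeded.  The expected score is therefore nondecreasing in
    TOFR, and clipping is never needed.
    """
    if tofr < 0:
        raise ValueError("tofr must be >= 0")
    out: dict[str, Optional[int]] = {}
    for name in TEST_NAMES:
        prof = profiles[name]
        if name in missing:
            out[name] = None
            # burn one draw regardless, keeping the stream layout stable
            rng.logistic()
            continue
        noise = 0.0 if math.isinf(prof.steepness) else rng.logistic(
            0.0, 1.0 / prof.steepness
        )
        z = tofr + noise
        out[name] = int(np.sum(z >= _cutpoints(name, prof)))
    return TestScores(**out)


# ---------------------------------------------------------------------------
# Tactile fading


def tactile_detection_prob(tofr: float, config: SimulationConfig) -> float:
    """Probability that fading is palpable at the given TOFR.

    Piecewise linear: full detection probability below
    ``tactile_full_below``, a ramp down to zero at ``tactile_detect_limit``,
    and exactly zero above the limit (fading is never palpable once TOFR
    exceeds the limit).
    """
    if tofr >= config.tactile_detect_limit:
        return 0.0
    if tofr <= config.tactile_full_below:
        return config.tactile_detect_prob
    span = config.tactile_detect_limit - config.tactile_full_below
    return config.tactile_detect_prob * (config.tactile_detect_limit - tofr) / span


def simulate_tactile(
    tofr: float, config: SimulationConfig, rng: np.random.Generator
) -> str:
    if tofr < 0:
        raise ValueError("tofr must be >= 0")
    p = tactile_detection_prob(tofr, config)
    return PALPABLE if rng.random() < p else NOT_PALPABLE


# ---------------------------------------------------------------------------
# EMG traces


def simulate_trace(
    final_tofr: float, config: SimulationConfig, rng: np.random.Generator
) -> EmgTrace:
    """Simulate an assessment-period EMG trace sampled every 20 s.

    Baseline readings jitter multiplicatively within ``+/- trace_jitter``
    (default 5%), which can never produce a relative drop above 20%; with
    probability ``instability_rate`` a reading is replaced by an
    artefactually depressed value (30-70% of baseline), the signature of a
    disconnected electrode or arm movement.
    """
    if config.trace_length < 2:
        raise ConfigError("trace_length must be >= 2")
    n = config.trace_length
    t = np.arange(n, dtype=float) * 20.0
    readings = final_tofr * (1.0 + rng.uniform(-config.trace_jitter,
                                               config.trace_jitter, size=n))
    artefact = rng.random(n) < config.instability_rate
    artefact[0] = False  # an artefact needs a preceding reading to drop from
    depressed = readings * rng.uniform(0.3, 0.7, size=n)
    readings = np.where(artefact, depressed, readings)
    return EmgTrace(t, np.clip(readings, 0.0, None))


def inject_artefacts(
    trace: EmgTrace, indices: Sequence[int], drop: float = 0.3
) -> EmgTrace:
    """Return a copy of ``trace`` with deterministic artefactual drops.

    Reading ``i`` is replaced by ``(1 - drop)`` times reading ``i - 1``, so
    every injected index contributes exactly one relative drop of ``drop``.
    """
    tofr = trace.tofr.copy()
    for i in indices:
        if i < 1 or i >= len(tofr):
            raise ValueError("artefact index must satisfy 1 <= i < len(trace)")
        tofr[i] = tofr[i - 1] * (1.0 - drop)
    return EmgTrace(trace.t_seconds.copy(), tofr)


# ---------------------------------------------------------------------------
# Whole cohort


def simulate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Generate a cohort of simulated patients.

    Deterministic for a fixed ``config.seed``: identical configurations
    yield byte-identical CSV serialisations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    latent = _draw_latent_tofr(config, rng)
    records: list[PatientRecord] = []
    for i, true_tofr in enumerate(latent):
        emg = max(0.0, true_tofr + rng.normal(0.0, config.emg_noise_sd)
                  if config.emg_noise_sd > 0 else true_tofr)
        amg = true_tofr * config.amg_bias + (
            rng.normal(0.0, config.amg_noise_sd) if config.amg_noise_sd > 0 else 0.0
        )
        amg = max(0.0, amg)
        t1_t0 = float(np.clip(0.25 + 0.7 * true_tofr + rng.normal(0.0, 0.1),
                              0.0, 1.2))
        intraoral = bool(rng.random() < config.intraoral_rate)
        missing = INTRAORAL_MISSING if intraoral else ()
        scores = simulate_scores(true_tofr, config.test_profiles, rng,
                                 missing=missing)
        tactile = simulate_tactile(emg, config, rng)
        trace = simulate_trace(emg, config, rng)
        records.append(
            PatientRecord(
                id=f"P{i + 1:04d}",
                true_tofr=float(true_tofr),
                emg_tofr=float(emg),
                amg_tofr=float(amg),
                t1_t0=t1_t0,
                tactile_fading=tactile,
                scores=scores,
                intraoral_surgery=intraoral,
                trace=trace,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Benchmark generator for split recovery


def step_tree_cohort(
    n: int,
    rng: np.random.Generator | int,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cohort whose mean TOFR is a step function of arm lift and head lift.

    The generating mechanism mirrors the published pathway: the mean TOFR
    jumps at ``arm_lift >= 5`` and, within each arm-lift branch, at a head
    lift cut (2 s on the weak branch, 5 s on the strong branch).  Two
    distractor scores carry no signal.  Used to benchmark whether a
    regression tree recovers the root split (arm lift at 5 s).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    arm = rng.integers(0, 6, size=n)
    head = rng.integers(0, 6, size=n)
    eyes = rng.integers(0, 6, size=n)
    swallow = rng.integers(0, 4, size=n)
    mean = np.where(
        arm < 5,
        np.where(head < 2, 0.10, 0.30),
        np.where(head < 5, 0.60, 0.85),
    )
    y = np.clip(mean + rng.normal(0.0, noise_sd, size=n), 0.0, None)
    X = pd.DataFrame(
        {"open_eyes": eyes, "head_lift": head, "arm_lift": arm,
         "swallow": swallow}
    )
    return X, y
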