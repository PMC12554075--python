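"""Synthetic BRET kinetic trace generator.

Emulates the shape of a live-cell BRET association experiment: a flat
pre-stimulation baseline, ligand addition, then a mono-exponential rise to a
plateau,

    mu(t) = B0                                   for t <  t_stim
    mu(t) = B0 + A * (1 - exp(-k * (t - t_stim)))  for t >= t_stim

with per-condition additive noise drawn from one of three families:

``gaussian_iid``
    white Gaussian noise with standard deviation ``sigma``.
``ar1``
    stationary first-order autoregressive Gaussian noise with lag-1
    coefficient ``phi`` and stationary standard deviation ``sigma``.  With
    ``phi = 0`` the generator produces the *same numbers* as ``gaussian_iid``
    under the same seed (identical draw order), which the tests rely on.
``burst_renewal``
    a renewal process of signaling "bursts" whose waiting times are Pareto
    distributed (heavy tail, exponent ``burst_tail``); each burst adds an
    exponentially decaying transient of height ``burst_amplitude``.  Bursts
    start at the stimulation time.  White Gaussian noise of ``sigma`` is
    added on top.  For ``burst_tail <= 1`` the theoretical mean waiting time
    diverges; individual waiting times are truncated at the total recording
    duration so generation always terminates.

The heavy-tailed renewal family models allosteric-modulator-induced signaling
bursts with long, non-ergodic waiting times between receptor-state
transitions; the Gaussian and AR(1) families are experimental controls.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .traces import ExperimentSet, KineticTrace


class ConfigurationError(ValueError):
    """A simulation configuration violates an invariant."""


NOISE_FAMILIES = ("gaussian_iid", "ar1", "burst_renewal")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for one condition.

    ``sigma`` (BRET ratio units) applies to every family; ``phi`` only to
    ``ar1``; the ``burst_*`` fields only to ``burst_renewal``
    (``burst_rate_scale`` is the Pareto scale in seconds, ``burst_tail`` the
    tail exponent, ``burst_amplitude`` the transient height in ratio units,
    ``burst_decay`` the transient decay rate in 1/s).
    """

    family: str = "gaussian_iid"
    sigma: float = 0.0
    phi: float = 0.0
    burst_rate_scale: float = 30.0
    burst_tail: float = 1.5
    burst_amplitude: float = 0.0
    burst_decay: float = 0.02

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ConfigurationError(
                f"unknown noise family {self.family!r}; expected one of {NOISE_FAMILIES}"
            )
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if not -1.0 < self.phi < 1.0:
            raise ConfigurationError("AR(1) coefficient phi must satisfy |phi| < 1")
        if self.burst_tail <= 0:
            raise ConfigurationError("burst_tail must be > 0")
        if self.burst_decay <= 0:
            raise ConfigurationError("burst_decay must be > 0")
        if self.burst_rate_scale <= 0:
            raise ConfigurationError("burst_rate_scale must be > 0")


@dataclass(frozen=True)
class ConditionKinetics:
    """Deterministic kinetics + noise for one treatment condition.

    ``baseline`` is the pre-stimulation BRET ratio B0, ``amplitude`` the
    plateau increment A and ``rate`` the association rate k (1/s) of the
    mono-exponential response.
    """

    label: str
    baseline: float = 1.0
    amplitude: float = 0.0
    rate: float = 0.004
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ConfigurationError("baseline must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.rate <= 0:
            raise ConfigurationError("rate must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Plate/protocol layout for a simulated experiment set.

    Defaults mirror a typical real-time BRET protocol: samples every 30 s,
    a 5 min baseline, then 30 min of post-stimulation recording (71 samples).
    """

    conditions: tuple[ConditionKinetics, ...] = ()
    n_experiments: int = 3
    n_wells: int = 3
    dt: float = 30.0
    baseline_duration: float = 300.0
    total_duration: float = 2100.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if not self.total_duration > self.baseline_duration > 0:
            raise ConfigurationError("need total_duration > baseline_duration > 0")
        if self.n_experiments < 1 or self.n_wells < 1:
            raise ConfigurationError("n_experiments and n_wells must be >= 1")
        if self.n_samples < 10:
            raise ConfigurationError(
                f"only {self.n_samples} samples per trace; at least 10 required"
            )

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.total_duration / self.dt)) + 1

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def trace_seed(self, experiment: int, condition: int, well: int) -> np.random.SeedSequence:
        """Deterministic per-trace seed.

        Uses ``numpy.random.SeedSequence(config.seed,
        spawn_key=(experiment, condition, well))`` — a documented, stable
        hash that numpy guarantees reproducible across platforms.
        """
        return np.random.SeedSequence(self.seed, spawn_key=(experiment, condition, well))


def _pareto_waiting_times(
    rng: np.random.Generator, scale: float, tail: float, horizon: float, n_max: int = 100_000
) -> np.ndarray:
    """Draw Pareto(type I) waiting times until their cumsum exceeds horizon.

    Each waiting time is truncated at ``horizon`` so the loop terminates even
    when tail <= 1 (diverging mean).
    """
    waits: list[float] = []
    total = 0.0
    while total <= horizon and len(waits) < n_max:
        u = rng.uniform()
        w = min(scale * u ** (-1.0 / tail), horizon)
        waits.append(w)
        total += w
    return np.asarray(waits)


def _draw_noise(rng: np.random.Generator, spec: NoiseSpec, n: int) -> np.ndarray:
    """Additive noise for the whole trace (bursts handled separately)."""
    eps = rng.standard_normal(n)
    if spec.family == "gaussian_iid" or spec.family == "burst_renewal":
        return spec.sigma * eps
    # ar1: stationary initialization, innovation variance sigma^2*(1-phi^2)
    x = np.empty(n)
    x[0] = spec.sigma * eps[0]
    c = spec.sigma * np.sqrt(1.0 - spec.phi**2)
    for t in range(1, n):
        x[t] = spec.phi * x[t - 1] + c * eps[t]
    return x


def _burst_component(
    rng: np.random.Generator, spec: NoiseSpec, times: np.ndarray, stim_time: float, horizon: float
) -> np.ndarray:
    """Sum of exponentially decaying transients at renewal event times.

    Events start at stimulation; the first event occurs one waiting time
    after ``stim_time``.
    """
    if spec.burst_amplitude == 0.0:
        return np.zeros_like(times)
    waits = _pareto_waiting_times(rng, spec.burst_rate_scale, spec.burst_tail, horizon)
    event_times = stim_time + np.cumsum(waits)
    event_times = event_times[event_times <= times[-1]]
    out = np.zeros_like(times)
    for te in event_times:
        mask = times >= te
        out[mask] += spec.burst_amplitude * np.exp(-spec.burst_decay * (times[mask] - te))
    return out


def mean_response(
    times: np.ndarray, kinetics: ConditionKinetics, stim_time: float
) -> np.ndarray:
    """Noise-free mono-exponential association curve."""
    times = np.asarray(times, dtype=float)
    out = np.full_like(times, kinetics.baseline)
    post = times >= stim_time
    out[post] += kinetics.amplitude * (1.0 - np.exp(-kinetics.rate * (times[post] - stim_time)))
    return out


def simulate_trace(
    kinetics: ConditionKinetics,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    experiment_id: str = "E1",
    well_id: str = "W1",
) -> KineticTrace:
    """Simulate one well: mean curve + family noise (+ bursts post-stim).

    Identical seed gives an identical trace.  The stimulation time equals
    ``config.baseline_duration``.
    """
    rng = np.random.default_rng(seed)
    times = config.time_grid
    stim = config.baseline_duration
    values = mean_response(times, kinetics, stim)
    values = values + _draw_noise(rng, kinetics.noise, len(times))
    if kinetics.noise.family == "burst_renewal":
        horizon = config.total_duration
        values = values + _burst_component(rng, kinetics.noise, times, stim, horizon)
    return KineticTrace(
        experiment_id=experiment_id,
        well_id=well_id,
        condition=kinetics.label,
        times=times,
        values=values,
        stim_time=stim,
    )


def simulate_experiment_set(config: SimulationConfig) -> ExperimentSet:
    """Simulate the full plate layout: n_experiments x n_wells per condition.

    Per-trace seeds derive deterministically from ``config.seed`` via
    :meth:`SimulationConfig.trace_seed`; all traces share the time grid.
    """
    if not config.conditions:
        raise ConfigurationError("simulation needs at least one condition")
    traces = []
    for e in range(config.n_experiments):
        for c, kin in enumerate(config.conditions):
            for w in range(config.n_wells):
                traces.append(
                    simulate_trace(
                        kin,
                        config,
                        seed=config.trace_seed(e, c, w),
                        experiment_id=f"E{e + 1}",
                        well_id=f"W{w + 1}",
                    )
                )
    return ExperimentSet(
        traces=traces,
        conditions=[k.label for k in config.conditions],
        experiments=[f"E{e + 1}" for e in range(config.n_experiments)],
    )


# ---------------------------------------------------------------------------
# configuration files


def _noise_from_dict(d: dict) -> NoiseSpec:
    return NoiseSpec(**d)


def _condition_from_dict(d: dict) -> ConditionKinetics:
    d = dict(d)
    noise = d.pop("noise", {})
    return ConditionKinetics(noise=_noise_from_dict(noise), **d)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    conds = [_condition_from_dict(c) for c in d.pop("conditions", [])]
    return SimulationConfig(conditions=tuple(conds), **d)


def load_simulation_config(path: str | Path, seed: int | None = None) -> SimulationConfig:
    """Load a YAML simulation config; ``seed`` (if given) overrides the file's."""
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    cfg = config_from_dict(d.get("simulation", d))
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """The packaged four-condition default (vehicle, AngII, LVV-H7, combo).

    Condition parameters live in ``data/default_simulation.yaml`` — they are
    calibration choices that reproduce the qualitative entropy orderings of
    an allosteric-modulation BRET experiment, not measured constants.
    """
    ref = importlib.resources.files("bretropy").joinpath("data/default_simulation.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_simulation_config(path, seed=seed)


def binding_pair_config(seed: int = 0) -> SimulationConfig:
    """The packaged two-condition binding-mode default (AngII vs AngII+LVV-H7).

    A slow association ramp with burst fluctuations for AngII alone versus a
    stabilized, reduced-noise association for the combined condition; see
    ``data/binding_pair.yaml``.
    """
    ref = importlib.resources.files("bretropy").joinpath("data/binding_pair.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_simulation_config(path, seed=seed)


def _iter_conditions(config: SimulationConfig) -> Iterator[ConditionKinetics]:
    yield from config.conditions
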