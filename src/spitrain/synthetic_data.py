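"""Synthetic pulse trains and playback sessions with controllable structure.

Three interval-generating processes are provided:

``renewal``
    Independent draws from a mixture of gamma / lognormal components — the
    null model of memoryless pulse timing.
``sticky_state``
    A semi-Markov chain over per-state interval distributions.  The chain
    stays in each state for a geometrically distributed number of intervals
    (mean = the state's dwell parameter) and then jumps uniformly to another
    state.  This mimics burst/pause alternation and produces serial
    correlations whose extent grows with the dwell times.
``ar1_log``
    A first-order autoregression on log-intervals, giving smooth,
    tunable geometric correlation decay — convenient for parameter-recovery
    tests.

Two calibrated species presets emulate the qualitative contrast between a
fast bimodal "burster" profile (histogram peaks near 14 and 23 ms, roughly
3100 pulses per 120 s, short memory) and a slow broadband profile (support
roughly 25-150 ms, roughly 1300 pulses per 120 s, long memory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .playback_sop import PreferenceSession, ZoneInterval
from .pulse_io import PulseTrain

__all__ = [
    "IPIDistribution",
    "StateSpec",
    "SPIGeneratorConfig",
    "SpeciesPreset",
    "gamma_from_mode",
    "simulate_ipis",
    "simulate_spi",
    "species_preset",
    "two_state_memory_config",
    "ar1_log_config",
    "simulate_playback_cohort",
    "load_generator_config",
    "save_generator_config",
    "PRESET_NAMES",
]

PRESET_NAMES = ("bimodal_burster", "broadband_slow")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class IPIDistribution:
    """One interval-distribution component, parametrized by mean and SD (ms)."""

    family: str              # 'gamma' or 'lognormal'
    mean_ms: float
    sd_ms: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mean_ms <= 0 or self.sd_ms <= 0:
            raise ValueError("mean_ms and sd_ms must be positive")
        if self.weight <= 0:
            raise ValueError("component weight must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "gamma":
            shape = (self.mean_ms / self.sd_ms) ** 2
            scale = self.sd_ms**2 / self.mean_ms
            return rng.gamma(shape, scale, size=n)
        cv2 = (self.sd_ms / self.mean_ms) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(self.mean_ms) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def gamma_from_mode(mode_ms: float, sd_ms: float, weight: float = 1.0) -> IPIDistribution:
    """Gamma component whose density peaks at ``mode_ms`` with SD ``sd_ms``.

    Solves sqrt(k) - 1/sqrt(k) = mode/sd for the shape k, then converts to
    the (mean, SD) parametrization used by :class:`IPIDistribution`.
    """
    r = mode_ms / sd_ms
    sqrt_k = (r + math.sqrt(r * r + 4.0)) / 2.0
    k = sqrt_k**2
    theta = sd_ms / sqrt_k
    return IPIDistribution("gamma", mean_ms=k * theta, sd_ms=sd_ms, weight=weight)


@dataclass(frozen=True)
class StateSpec:
    """One state of the sticky chain: its interval distribution and dwell."""

    distribution: IPIDistribution
    dwell_intervals: float       # expected number of intervals per visit

    def __post_init__(self) -> None:
        if self.dwell_intervals < 1:
            raise ValueError("dwell_intervals must be >= 1")


@dataclass
class SPIGeneratorConfig:
    """Full specification of one synthetic pulse-train generator."""

    process: str                                    # renewal | sticky_state | ar1_log
    mixture: tuple[IPIDistribution, ...] | None = None    # renewal
    states: tuple[StateSpec, ...] | None = None           # sticky_state
    ar1_phi: float | None = None                          # ar1_log
    ar1_log_mean: float | None = None                     # mean of ln(IPI/ms)
    ar1_log_sd: float | None = None                       # stationary SD of ln IPI
    duration_s: float = 120.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.process == "renewal":
            if not self.mixture:
                raise ValueError("renewal process requires a mixture")
            self.mixture = tuple(self.mixture)
            total = sum(c.weight for c in self.mixture)
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"mixture weights must sum to 1, got {total}")
            if self.states is not None:
                raise ValueError("renewal process takes no memory parameters")
        elif self.process == "sticky_state":
            if not self.states or len(self.states) < 2:
                raise ValueError("sticky_state requires at least 2 states")
            self.states = tuple(self.states)
        elif self.process == "ar1_log":
            if self.ar1_phi is None or self.ar1_log_mean is None or self.ar1_log_sd is None:
                raise ValueError("ar1_log requires ar1_phi, ar1_log_mean and ar1_log_sd")
            if not 0 <= self.ar1_phi < 1:
                raise ValueError("ar1_phi must lie in [0, 1)")
            if self.ar1_log_sd <= 0:
                raise ValueError("ar1_log_sd must be positive")
        else:
            raise ValueError(f"unknown process {self.process!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def mean_ipi_ms(self) -> float:
        """Expected interval under the stationary law of the process."""
        if self.process == "renewal":
            return sum(c.weight * c.mean_ms for c in self.mixture)
        if self.process == "sticky_state":
            dwell = np.array([s.dwell_intervals for s in self.states])
            means = np.array([s.distribution.mean_ms for s in self.states])
            return float((dwell * means).sum() / dwell.sum())
        return math.exp(self.ar1_log_mean + self.ar1_log_sd**2 / 2.0)


def _draw_renewal(config: SPIGeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([c.weight for c in config.mixture])
    which = rng.choice(len(config.mixture), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for i, comp in enumerate(config.mixture):
        mask = which == i
        out[mask] = comp.sample(rng, int(mask.sum()))
    return out


def _draw_sticky(config: SPIGeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    states = config.states
    k = len(states)
    dwell = np.array([s.dwell_intervals for s in states])
    # stationary occupancy of the interval-indexed chain is proportional to dwell
    state = int(rng.choice(k, p=dwell / dwell.sum()))
    chunks: list[np.ndarray] = []
    drawn = 0
    while drawn < n:
        block = int(rng.geometric(1.0 / dwell[state]))
        block = min(block, n - drawn)
        chunks.append(states[state].distribution.sample(rng, block))
        drawn += block
        if k == 2:
            state = 1 - state
        else:
            others = [j for j in range(k) if j != state]
            state = int(rng.choice(others))
    return np.concatenate(chunks)


def _draw_ar1_log(config: SPIGeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    phi, mu, sigma = config.ar1_phi, config.ar1_log_mean, config.ar1_log_sd
    innov_sd = sigma * math.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(mu, sigma)
    noise = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + noise[t - 1]
    return np.exp(x)


_DRAWERS = {"renewal": _draw_renewal, "sticky_state": _draw_sticky, "ar1_log": _draw_ar1_log}


def simulate_ipis(config: SPIGeneratorConfig, n_intervals: int, seed=None) -> np.ndarray:
    """Draw exactly ``n_intervals`` intervals (milliseconds) from the process."""
    if n_intervals < 1:
        raise ValueError("n_intervals must be positive")
    rng = _rng(config.seed if seed is None else seed)
    return _DRAWERS[config.process](config, n_intervals, rng)


def simulate_spi(
    config: SPIGeneratorConfig,
    seed=None,
    individual_id: str = "",
    species_label: str = "",
    sex: str = "unknown",
) -> PulseTrain:
    """Simulate a pulse train of ``config.duration_s`` seconds.

    Intervals are drawn until their cumulative sum exceeds the duration and
    the train is truncated there (first pulse at t = 0), so the last kept
    timestamp is <= duration and the next drawn interval would overshoot it.
    Deterministic for a given seed.
    """
    rng = _rng(config.seed if seed is None else seed)
    target_ms = config.duration_s * 1000.0
    # over-draw by 20% plus slack, then top up in the rare shortfall case
    n_guess = int(target_ms / config.mean_ipi_ms * 1.2) + 50
    intervals = _DRAWERS[config.process](config, n_guess, rng)
    while intervals.sum() <= target_ms:
        intervals = np.concatenate([intervals, _DRAWERS[config.process](config, n_guess, rng)])
    times_ms = np.concatenate([[0.0], np.cumsum(intervals)])
    times_s = times_ms[times_ms <= target_ms] / 1000.0
    return PulseTrain(
        timestamps=times_s,
        species_label=species_label,
        sex=sex,
        phase="synthetic",
        individual_id=individual_id,
        duration_s=config.duration_s,
    )


@dataclass(frozen=True)
class SpeciesPreset:
    """A named, calibrated generator configuration."""

    name: str
    config: SPIGeneratorConfig
    peak_ipis_ms: tuple[float, ...]       # nominal histogram peak positions
    expected_events_120s: float


def species_preset(name: str, duration_s: float = 120.0) -> SpeciesPreset:
    """Calibrated presets for the two emulated discharge profiles.

    ``bimodal_burster``: a three-state sticky chain — two tight burst states
    whose gamma densities peak at 14 and 23 ms plus a broad lognormal pause
    state — tuned to about 3100 pulses per 120 s with short memory.
    ``broadband_slow``: two broad gamma states covering roughly 25-150 ms,
    about 1300 pulses per 120 s, with long state dwells and hence long
    memory.
    """
    if name == "bimodal_burster":
        config = SPIGeneratorConfig(
            process="sticky_state",
            states=(
                StateSpec(gamma_from_mode(14.0, 1.5), dwell_intervals=9.0),
                StateSpec(gamma_from_mode(23.0, 3.0), dwell_intervals=7.0),
                StateSpec(IPIDistribution("lognormal", mean_ms=120.0, sd_ms=80.0),
                          dwell_intervals=4.0),
            ),
            duration_s=duration_s,
        )
        return SpeciesPreset(name, config, (14.0, 23.0), 3157.0)
    if name == "broadband_slow":
        config = SPIGeneratorConfig(
            process="sticky_state",
            states=(
                StateSpec(IPIDistribution("gamma", mean_ms=55.0, sd_ms=15.0),
                          dwell_intervals=40.0),
                StateSpec(IPIDistribution("gamma", mean_ms=125.0, sd_ms=25.0),
                          dwell_intervals=40.0),
            ),
            duration_s=duration_s,
        )
        return SpeciesPreset(name, config, (51.0,), 1303.0)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def two_state_memory_config(
    dwell_intervals: float,
    fast_ms: tuple[float, float] = (20.0, 5.0),
    slow_ms: tuple[float, float] = (80.0, 20.0),
    duration_s: float = 120.0,
) -> SPIGeneratorConfig:
    """Symmetric two-state sticky chain with a single dwell knob.

    Convenient for memory-detection and parameter-recovery experiments:
    the serial-correlation extent grows monotonically with the dwell.
    """
    return SPIGeneratorConfig(
        process="sticky_state",
        states=(
            StateSpec(IPIDistribution("gamma", *fast_ms), dwell_intervals=dwell_intervals),
            StateSpec(IPIDistribution("gamma", *slow_ms), dwell_intervals=dwell_intervals),
        ),
        duration_s=duration_s,
    )


def ar1_log_config(
    phi: float,
    log_mean: float = math.log(50.0),
    log_sd: float = 0.5,
    duration_s: float = 120.0,
) -> SPIGeneratorConfig:
    """AR(1)-on-log-intervals config with stationary mean ~ exp(log_mean)."""
    return SPIGeneratorConfig(
        process="ar1_log",
        ar1_phi=phi,
        ar1_log_mean=log_mean,
        ar1_log_sd=log_sd,
        duration_s=duration_s,
    )


def simulate_playback_cohort(
    n_fish: int,
    true_preference: float,
    noise_sd: float = 0.3,
    seed=None,
    condition: str = "I",
    n_intervals: int = 8,
    interval_length_s: float = 120.0,
    response_fraction: float = 0.5,
) -> list[PreferenceSession]:
    """Simulate a cohort of two-choice playback sessions.

    Each fish carries a latent preference obtained by perturbing the cohort
    preference ``true_preference`` on the Fisher-z (atanh) scale with
    Gaussian noise of SD ``noise_sd`` — this keeps every preference inside
    [-1, 1] and leaves the boundary values ±1 exact.  Per interval, the time
    spent responding (about ``response_fraction`` of the interval) is split
    between the two stimulus zones according to the latent preference, and
    the physical side carrying stimulus 1 alternates in a balanced random
    order.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    if not -1.0 <= true_preference <= 1.0:
        raise ValueError("true_preference must lie in [-1, 1]")
    rng = _rng(seed)
    sessions = []
    for f in range(n_fish):
        if abs(true_preference) == 1.0:
            pref = true_preference
        else:
            pref = math.tanh(math.atanh(true_preference) + rng.normal(0.0, noise_sd))
        sides = np.array(["A", "E"] * ((n_intervals + 1) // 2))[:n_intervals]
        rng.shuffle(sides)
        intervals = []
        for side in sides:
            active = interval_length_s * response_fraction * rng.uniform(0.7, 1.3)
            t_stim1 = active * (1.0 + pref) / 2.0
            t_stim2 = active * (1.0 - pref) / 2.0
            t_b, t_d = (t_stim1, t_stim2) if side == "A" else (t_stim2, t_stim1)
            intervals.append(
                ZoneInterval(
                    side_of_stimulus1=str(side),
                    t_zone_b_s=t_b,
                    t_zone_c_s=interval_length_s - active,
                    t_zone_d_s=t_d,
                    length_s=interval_length_s,
                )
            )
        sessions.append(PreferenceSession(f"fish{f:02d}", condition, intervals))
    return sessions


# ---------------------------------------------------------------------------
# YAML round-tripping of generator configs

def _config_to_dict(config: SPIGeneratorConfig) -> dict:
    d = {"process": config.process, "duration_s": config.duration_s}
    if config.seed is not None:
        d["seed"] = config.seed
    if config.mixture:
        d["mixture"] = [asdict(c) for c in config.mixture]
    if config.states:
        d["states"] = [
            {"dwell_intervals": s.dwell_intervals, **asdict(s.distribution)}
            for s in config.states
        ]
    if config.process == "ar1_log":
        d.update(
            ar1_phi=config.ar1_phi,
            ar1_log_mean=config.ar1_log_mean,
            ar1_log_sd=config.ar1_log_sd,
        )
    return d


def _config_from_dict(d: dict) -> SPIGeneratorConfig:
    kwargs = dict(
        process=d["process"],
        duration_s=float(d.get("duration_s", 120.0)),
        seed=d.get("seed"),
    )
    if "mixture" in d:
        kwargs["mixture"] = tuple(IPIDistribution(**c) for c in d["mixture"])
    if "states" in d:
        kwargs["states"] = tuple(
            StateSpec(
                IPIDistribution(
                    family=s["family"], mean_ms=s["mean_ms"], sd_ms=s["sd_ms"],
                    weight=s.get("weight", 1.0),
                ),
                dwell_intervals=s["dwell_intervals"],
            )
            for s in d["states"]
        )
    for key in ("ar1_phi", "ar1_log_mean", "ar1_log_sd"):
        if key in d:
            kwargs[key] = d[key]
    return SPIGeneratorConfig(**kwargs)


def load_generator_config(path) -> SPIGeneratorConfig:
    """Read an :class:`SPIGeneratorConfig` from a YAML (or JSON) file."""
    with open(path, encoding="utf-8") as fh:
        return _config_from_dict(yaml.safe_load(fh))


def save_generator_config(config: SPIGeneratorConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
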