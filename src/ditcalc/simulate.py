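"""Seeded synthetic calorimetry: paired fasted/fed traces with known truth.

The simulator emulates a small-animal open-circuit calorimetry experiment:
3-min VO2/VCO2/activity sampling, a 12-h light cycle (lights on 0700), an
11-h fasting measurement window starting at midnight, and a 22-h fed window
starting at the 1700 h meal.  Its purpose is verification — every trace
comes with the exact baseline law and injected thermogenesis that produced
it, so the analysis pipeline can be tested for recovery rather than
eyeballed.

Generative model
----------------
* Activity: overdispersed (negative-binomial) counts/min with a
  photoperiod-dependent mean (dark > light, nocturnal animals).  Fasted
  animals optionally get an anticipatory multiplier in a window before the
  expected mealtime.
* Baseline EE: ``a + b * sqrt(A_bin)`` where ``A_bin`` is the 12-min
  bin-mean activity — the linear law is defined at the analysis (bin)
  scale, so a noiseless run sits exactly on the regression line the
  pipeline fits.  Gaussian noise (sd ``noise_sd``) is added per 3-min
  sample; negative draws are truncated at zero and counted.
* DIT: a rise/plateau/exponential-decay kernel after meal onset.  Each
  3-min sample carries the kernel's *interval mean* (from the closed-form
  antiderivative), so rectangle-rule integration downstream reproduces the
  continuous kernel integral exactly.
* RER: constant fasting value; after a meal it rises toward
  ``rer_fed_peak`` and relaxes back.  EE and RER jointly determine VO2 and
  VCO2 through the inverted energy equation, keeping all three channels
  mutually consistent.

Protocol presets (``SimConfig.for_protocol``) encode the three feeding
regimens studied with this method: ad libitum (21.6 kcal/day, DIT sustained
~10 h), 33%-restricted (15 kcal/day, food gone by ~6 h) and 66%-restricted
(7.5 kcal/day, food gone by ~3 h), with the restricted groups' higher dark
activity (food-seeking) reflected in their activity means.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    CalorimetryError,
    CalorimetryTrace,
    FeedingProtocol,
    parse_clock,
)
from .preprocess import EE_CO2_COEF, EE_O2_COEF

__all__ = [
    "SimConfig",
    "SimGroundTruth",
    "dit_kernel",
    "dit_kernel_cumulative",
    "dit_kernel_interval_mean",
    "generate_activity",
    "generate_ee",
    "rer_trajectory",
    "invert_gas_exchange",
    "simulate_mouse",
    "simulate_cohort",
]

DAY_MIN = 24 * 60


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generative model, with study-regime defaults.

    Rates are kcal/min, times minutes, activity counts/min.
    """

    # measurement design
    duration_fasted: float = 11 * 60.0
    duration_fed: float = 22 * 60.0
    sampling_interval: float = 3.0
    bin_factor: int = 4
    fasted_start: str = "0000"
    fed_start: str = "1700"
    light_on: str = "0700"
    light_off: str = "1900"
    # baseline EE law (kcal/min; slope per sqrt(count/min))
    baseline_intercept: float = 0.005
    baseline_slope: float = 0.00025
    noise_sd: float = 0.0009
    # activity process
    activity_mean_dark: float = 180.6
    activity_mean_light: float = 63.8
    activity_dispersion: float = 5.0  # NB shape; var = mu + mu^2/k
    anticipatory_factor: float = 1.5
    anticipation_min: float = 90.0  # window before meal onset, fasted only
    # DIT kernel
    dit_amplitude: float = 0.0038
    dit_rise: float = 30.0
    dit_plateau_end: float = 600.0  # minutes after meal onset
    dit_decay_tau: float = 120.0
    # RER trajectory
    rer_fasted: float = 0.75
    rer_fed_peak: float = 0.95
    rer_rise: float = 60.0
    rer_decay_tau: float = 360.0
    # feeding protocol
    protocol: FeedingProtocol = field(
        default_factory=lambda: FeedingProtocol(21.6, "1700", "ad_libitum")
    )
    # cohort-level between-animal variation (fractional sd on a and b)
    cohort_cv_intercept: float = 0.07
    cohort_cv_slope: float = 0.07

    def __post_init__(self) -> None:
        positive = (
            "duration_fasted", "duration_fed", "sampling_interval",
            "baseline_intercept", "baseline_slope", "activity_mean_dark",
            "activity_mean_light", "activity_dispersion", "dit_amplitude",
            "dit_rise", "dit_decay_tau", "rer_fasted", "rer_fed_peak",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise CalorimetryError(f"SimConfig.{name} must be positive")
        if self.noise_sd < 0 or self.dit_plateau_end < self.dit_rise:
            raise CalorimetryError(
                "noise_sd must be >= 0 and dit_plateau_end >= dit_rise"
            )

    @classmethod
    def for_protocol(cls, label: str, **overrides) -> "SimConfig":
        """Preset configurations for the three feeding regimens."""
        presets = {
            "ad_libitum": dict(
                protocol=FeedingProtocol(21.6, "1700", "ad_libitum"),
                dit_amplitude=0.0038,
                dit_plateau_end=600.0,
                activity_mean_dark=180.6,
                activity_mean_light=63.8,
            ),
            "restricted_33": dict(
                protocol=FeedingProtocol(15.0, "1700", "restricted_33"),
                dit_amplitude=0.0040,
                dit_plateau_end=360.0,
                activity_mean_dark=190.3,
                activity_mean_light=56.9,
            ),
            "restricted_66": dict(
                protocol=FeedingProtocol(7.5, "1700", "restricted_66"),
                dit_amplitude=0.0033,
                dit_plateau_end=180.0,
                activity_mean_dark=296.6,
                activity_mean_light=75.1,
            ),
        }
        if label not in presets:
            raise CalorimetryError(
                f"unknown protocol {label!r}; use one of {sorted(presets)}"
            )
        params = {**presets[label], **overrides}
        return cls(**params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = self.protocol.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "protocol" in d:
            d["protocol"] = FeedingProtocol.from_dict(d["protocol"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimGroundTruth:
    """Everything the simulator injected, for recovery testing."""

    intercept: float
    slope: float
    transform: str
    dit_bin_rates: np.ndarray  # kernel interval means on the fed bin grid
    injected_total_dit: float  # kcal, closed-form kernel integral
    rer_fed: np.ndarray
    n_truncated_fasted: int
    n_truncated_fed: int
    animal_id: str = "sim"

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "intercept": self.intercept,
            "slope": self.slope,
            "transform": self.transform,
            "injected_total_dit_kcal": self.injected_total_dit,
            "dit_bin_rates": [float(v) for v in self.dit_bin_rates],
            "n_truncated_fasted": self.n_truncated_fasted,
            "n_truncated_fed": self.n_truncated_fed,
        }


# ---------------------------------------------------------------------------
# DIT kernel


def dit_kernel(t, config: SimConfig):
    """Pointwise thermogenesis rate (kcal/min) t minutes after meal onset.

    Linear rise over ``dit_rise``, plateau at ``dit_amplitude`` until
    ``dit_plateau_end``, then exponential decay with ``dit_decay_tau``;
    zero before the meal.
    """
    t = np.asarray(t, dtype=float)
    A, r, P, tau = (
        config.dit_amplitude,
        config.dit_rise,
        config.dit_plateau_end,
        config.dit_decay_tau,
    )
    out = np.where(
        t < 0,
        0.0,
        np.where(
            t < r,
            A * t / r,
            np.where(t < P, A, A * np.exp(-np.maximum(t - P, 0.0) / tau)),
        ),
    )
    return float(out) if out.ndim == 0 else out


def dit_kernel_cumulative(t, config: SimConfig):
    """Closed-form integral of the kernel from 0 to t (kcal)."""
    t = np.asarray(t, dtype=float)
    A, r, P, tau = (
        config.dit_amplitude,
        config.dit_rise,
        config.dit_plateau_end,
        config.dit_decay_tau,
    )
    rise = A * np.minimum(np.maximum(t, 0.0), r) ** 2 / (2 * r)
    plateau = A * np.clip(t - r, 0.0, P - r)
    decay = A * tau * (1.0 - np.exp(-np.maximum(t - P, 0.0) / tau))
    out = rise + plateau + decay
    return float(out) if out.ndim == 0 else out


def dit_kernel_interval_mean(t0, t1, config: SimConfig):
    """Mean kernel rate over [t0, t1] via the closed-form antiderivative."""
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    return (
        dit_kernel_cumulative(t1, config) - dit_kernel_cumulative(t0, config)
    ) / (t1 - t0)


# ---------------------------------------------------------------------------
# stochastic channels


def _sample_clocks(config: SimConfig, start_clock: str, n_samples: int) -> np.ndarray:
    t = config.sampling_interval * np.arange(n_samples)
    return (parse_clock(start_clock) + t) % DAY_MIN


def generate_activity(
    config: SimConfig,
    condition: str,
    n_samples: int,
    seed,
    start_clock: str | None = None,
) -> np.ndarray:
    """Overdispersed beam-break counts/min, photoperiod-aware, reproducible.

    Counts are negative binomial with mean ``activity_mean_dark`` or
    ``activity_mean_light`` by clock time and shape ``activity_dispersion``
    (variance mu + mu^2/k).  Under the fasted condition the mean is
    multiplied by ``anticipatory_factor`` within ``anticipation_min``
    minutes before the protocol's meal onset — food-anticipatory activity.
    """
    if start_clock is None:
        start_clock = config.fasted_start if condition == "fasted" else config.fed_start
    rng = np.random.default_rng(seed)
    clock = _sample_clocks(config, start_clock, n_samples)
    on, off = parse_clock(config.light_on), parse_clock(config.light_off)
    light = (clock >= on) & (clock < off) if on < off else (clock >= on) | (clock < off)
    mu = np.where(light, config.activity_mean_light, config.activity_mean_dark)
    if condition == "fasted" and config.anticipatory_factor != 1.0:
        meal = parse_clock(config.protocol.meal_onset)
        delta = (meal - clock) % DAY_MIN  # minutes until next mealtime
        mu = np.where(
            (delta > 0) & (delta <= config.anticipation_min),
            mu * config.anticipatory_factor,
            mu,
        )
    k = config.activity_dispersion
    return rng.negative_binomial(k, k / (k + mu)).astype(float)


def _bin_mean_per_sample(values: np.ndarray, bin_factor: int) -> np.ndarray:
    """Each sample's bin-mean, trailing partial bin averaged over itself."""
    n = len(values)
    n_full = (n // bin_factor) * bin_factor
    out = np.empty(n)
    if n_full:
        means = values[:n_full].reshape(-1, bin_factor).mean(axis=1)
        out[:n_full] = np.repeat(means, bin_factor)
    if n > n_full:
        out[n_full:] = values[n_full:].mean()
    return out


def generate_ee(
    activity: np.ndarray,
    condition: str,
    config: SimConfig,
    seed,
    start_clock: str | None = None,
) -> tuple[np.ndarray, int]:
    """Per-sample EE (kcal/min) for the given activity draw.

    Returns ``(ee, n_truncated)`` where ``n_truncated`` counts negative
    noise draws clamped to zero.
    """
    if start_clock is None:
        start_clock = config.fasted_start if condition == "fasted" else config.fed_start
    rng = np.random.default_rng(seed)
    n = len(activity)
    a_bin = _bin_mean_per_sample(np.asarray(activity, dtype=float), config.bin_factor)
    ee = config.baseline_intercept + config.baseline_slope * np.sqrt(a_bin)
    if condition == "fed":
        offset = (
            parse_clock(start_clock) - parse_clock(config.protocol.meal_onset)
        ) % DAY_MIN
        if offset > config.duration_fed:  # start before the meal, not after it
            offset -= DAY_MIN
        t0 = offset + config.sampling_interval * np.arange(n)
        ee = ee + dit_kernel_interval_mean(t0, t0 + config.sampling_interval, config)
    if config.noise_sd > 0:
        ee = ee + rng.normal(0.0, config.noise_sd, size=n)
    n_truncated = int(np.sum(ee < 0))
    return np.maximum(ee, 0.0), n_truncated


def rer_trajectory(
    times: np.ndarray, condition: str, config: SimConfig, start_clock: str | None = None
) -> np.ndarray:
    """Deterministic RER per sample: fasting constant, postprandial excursion."""
    times = np.asarray(times, dtype=float)
    if condition == "fasted":
        return np.full_like(times, config.rer_fasted)
    if start_clock is None:
        start_clock = config.fed_start
    offset = (
        parse_clock(start_clock) - parse_clock(config.protocol.meal_onset)
    ) % DAY_MIN
    if offset > config.duration_fed:
        offset -= DAY_MIN
    t = times + offset
    shape = np.where(
        t < 0,
        0.0,
        np.where(
            t < config.rer_rise,
            t / config.rer_rise,
            np.exp(-np.maximum(t - config.rer_rise, 0.0) / config.rer_decay_tau),
        ),
    )
    return config.rer_fasted + (config.rer_fed_peak - config.rer_fasted) * shape


def invert_gas_exchange(ee, rer):
    """Solve the energy equation for (VO2, VCO2) in L/min at a given RER.

    With EE = 3.9 VO2 + 1.1 VCO2 and RER = VCO2/VO2:
    VO2 = EE / (3.9 + 1.1 RER), VCO2 = RER * VO2.
    """
    ee = np.asarray(ee, dtype=float)
    rer = np.asarray(rer, dtype=float)
    if np.any(ee < 0):
        raise CalorimetryError("EE must be non-negative")
    if np.any((rer <= 0) | (rer > 1.2)):
        raise CalorimetryError("RER must lie in (0, 1.2]")
    vo2 = ee / (EE_O2_COEF + EE_CO2_COEF * rer)
    vco2 = rer * vo2
    if vo2.ndim == 0:
        return float(vo2), float(vco2)
    return vo2, vco2


# ---------------------------------------------------------------------------
# whole-experiment simulation


def _make_trace(
    config: SimConfig,
    condition: str,
    ee: np.ndarray,
    rer: np.ndarray,
    activity: np.ndarray,
    start_clock: str,
    animal_id: str,
) -> CalorimetryTrace:
    vo2, vco2 = invert_gas_exchange(ee, rer)
    return CalorimetryTrace(
        time=config.sampling_interval * np.arange(len(ee)),
        vo2=vo2 * 1e3,  # store in mL/min, mouse-scale magnitudes
        vco2=vco2 * 1e3,
        activity=activity,
        condition=condition,
        animal_id=animal_id,
        clock_offset=start_clock,
        gas_unit="mL_per_min",
        sampling_interval=config.sampling_interval,
    )


def simulate_mouse(
    config: SimConfig, seed, animal_id: str = "sim"
) -> tuple[CalorimetryTrace, CalorimetryTrace, SimGroundTruth]:
    """One animal's paired fasted (11 h) and fed (22 h) traces plus truth."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_act_fast, s_ee_fast, s_act_fed, s_ee_fed = ss.spawn(4)

    n_fast = int(round(config.duration_fasted / config.sampling_interval))
    n_fed = int(round(config.duration_fed / config.sampling_interval))

    act_fast = generate_activity(config, "fasted", n_fast, s_act_fast)
    ee_fast, trunc_fast = generate_ee(act_fast, "fasted", config, s_ee_fast)
    rer_fast = rer_trajectory(
        config.sampling_interval * np.arange(n_fast), "fasted", config
    )
    fasted = _make_trace(
        config, "fasted", ee_fast, rer_fast, act_fast, config.fasted_start, animal_id
    )

    act_fed = generate_activity(config, "fed", n_fed, s_act_fed)
    ee_fed, trunc_fed = generate_ee(act_fed, "fed", config, s_ee_fed)
    times_fed = config.sampling_interval * np.arange(n_fed)
    rer_fed = rer_trajectory(times_fed, "fed", config)
    fed = _make_trace(
        config, "fed", ee_fed, rer_fed, act_fed, config.fed_start, animal_id
    )

    bin_width = config.bin_factor * config.sampling_interval
    offset = (
        parse_clock(config.fed_start) - parse_clock(config.protocol.meal_onset)
    ) % DAY_MIN
    if offset > config.duration_fed:
        offset -= DAY_MIN
    n_bins = n_fed // config.bin_factor
    bin_starts = offset + bin_width * np.arange(n_bins)
    truth = SimGroundTruth(
        intercept=config.baseline_intercept,
        slope=config.baseline_slope,
        transform="sqrt",
        dit_bin_rates=dit_kernel_interval_mean(
            bin_starts, bin_starts + bin_width, config
        ),
        injected_total_dit=float(
            dit_kernel_cumulative(offset + config.duration_fed, config)
            - dit_kernel_cumulative(offset, config)
        ),
        rer_fed=rer_fed,
        n_truncated_fasted=trunc_fast,
        n_truncated_fed=trunc_fed,
        animal_id=animal_id,
    )
    return fasted, fed, truth


def simulate_cohort(
    config: SimConfig,
    n_animals: int,
    base_seed,
    vary_animals: bool = True,
) -> list[tuple[CalorimetryTrace, CalorimetryTrace, SimGroundTruth]]:
    """Independent animals with deterministically derived per-animal seeds.

    When ``vary_animals`` is set, each animal's baseline intercept and slope
    are drawn from normal distributions around the configured values with
    fractional sds ``cohort_cv_intercept``/``cohort_cv_slope``.
    """
    if n_animals < 1:
        raise CalorimetryError("n_animals must be >= 1")
    ss = (
        base_seed
        if isinstance(base_seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_seed)
    )
    cohort = []
    for i, child in enumerate(ss.spawn(n_animals)):
        param_seed, sim_seed = child.spawn(2)
        cfg = config
        if vary_animals:
            prng = np.random.default_rng(param_seed)
            a = config.baseline_intercept * (
                1.0 + config.cohort_cv_intercept * prng.standard_normal()
            )
            b = config.baseline_slope * (
                1.0 + config.cohort_cv_slope * prng.standard_normal()
            )
            cfg = replace(
                config,
                baseline_intercept=max(a, 0.1 * config.baseline_intercept),
                baseline_slope=max(b, 0.1 * config.baseline_slope),
            )
        cohort.append(simulate_mouse(cfg, sim_seed, animal_id=f"m{i + 1:02d}"))
    return cohort
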