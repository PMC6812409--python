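"""DIT series, integrals, and summary ratios.

Diet-induced thermogenesis at each fed bin is the observed EE minus the
fasting model's prediction at the *same* activity level — the subtraction
is what removes the activity confound that plagues naive fed-minus-fasted
comparisons.  Totals are rectangle-rule integrals (each binned rate already
represents its interval's mean, so rectangles are the unbiased quadrature),
and the headline summaries are

    DIT/intake (%) = 100 * total DIT / calorie intake
    DIT/EE (%)     = 100 * total DIT / total EE (TEE)

Negative per-bin DIT values (noise pushing an observation below the fasting
line) are kept in the integrals — clipping them would bias totals upward —
and their count is reported so a run dominated by them is visible.

The fasting model is fitted on the late-night fasting window but applied
across the whole 22-h fed window; the circadian mismatch this implies is a
property of the method, documented rather than corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CalorimetryError, FeedingProtocol
from .fasting_model import FastingModel, predict_ee
from .preprocess import BinnedTrace

__all__ = [
    "DITSeries",
    "HourlySeries",
    "DITResult",
    "compute_dit_series",
    "aggregate_hourly",
    "total_auc",
    "summarize",
    "intake_per_bw",
    "species_dit_ratio",
]


@dataclass
class DITSeries:
    """Per-bin observed/predicted EE and their difference for one animal."""

    time_mid: np.ndarray
    ee_observed: np.ndarray  # kcal/min
    ee_predicted: np.ndarray  # kcal/min, activity-matched fasting prediction
    dit: np.ndarray  # kcal/min, observed - predicted
    activity: np.ndarray
    photoperiod: np.ndarray
    bin_width: float
    animal_id: str
    model: FastingModel
    clock_offset: str = "0000"

    @property
    def n_bins(self) -> int:
        return len(self.time_mid)


@dataclass
class HourlySeries:
    """1-h aggregates of a DIT series, in kcal/h."""

    hour_start: np.ndarray  # minutes since series start
    dit: np.ndarray  # kcal accumulated in that hour == kcal/h
    ee: np.ndarray
    partial_last_hour: bool  # True if the final hour was not fully covered


@dataclass
class DITResult:
    """Totals, ratios, and summaries for one animal's fed measurement."""

    animal_id: str
    total_dit: float  # kcal over the fed window
    total_ee: float  # kcal (TEE over the fed window)
    intake_kcal: float
    dit_over_intake: float  # percent
    dit_over_ee: float  # percent
    hourly_dit: np.ndarray
    hourly_ee: np.ndarray
    activity_dark: float  # mean counts/min, dark photoperiod
    activity_light: float
    n_negative_bins: int
    model: FastingModel
    protocol: FeedingProtocol

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "totals": {
                "total_dit_kcal": self.total_dit,
                "total_ee_kcal": self.total_ee,
                "intake_kcal": self.intake_kcal,
            },
            "ratios": {
                "dit_over_intake_pct": self.dit_over_intake,
                "dit_over_ee_pct": self.dit_over_ee,
            },
            "hourly": {
                "dit_kcal_per_h": [float(v) for v in self.hourly_dit],
                "ee_kcal_per_h": [float(v) for v in self.hourly_ee],
            },
            "activity": {
                "dark_counts_per_min": self.activity_dark,
                "light_counts_per_min": self.activity_light,
            },
            "n_negative_bins": self.n_negative_bins,
            "model": self.model.to_dict(),
            "protocol": self.protocol.to_dict(),
        }


def compute_dit_series(fed: BinnedTrace, model: FastingModel) -> DITSeries:
    """Subtract the activity-matched fasting prediction from fed EE, per bin.

    Negative differences are retained, not clipped.
    """
    if fed.condition != "fed":
        raise CalorimetryError(
            f"DIT requires a fed trace, got condition {fed.condition!r}"
        )
    if fed.n_bins == 0:
        raise CalorimetryError("fed trace has no bins")
    if model.animal_id != fed.animal_id:
        warnings.warn(
            f"fasting model fitted on {model.animal_id!r} applied to fed trace "
            f"of {fed.animal_id!r}",
            stacklevel=2,
        )
    predicted = predict_ee(model, fed.activity)
    observed = np.asarray(fed.ee, dtype=float)
    return DITSeries(
        time_mid=fed.time_mid,
        ee_observed=observed,
        ee_predicted=predicted,
        dit=observed - predicted,
        activity=fed.activity,
        photoperiod=fed.photoperiod,
        bin_width=fed.bin_width,
        animal_id=fed.animal_id,
        model=model,
        clock_offset=fed.clock_offset,
    )


def aggregate_hourly(series: DITSeries) -> HourlySeries:
    """Group bins into consecutive 1-h windows; report kcal per hour.

    Each hour's value is the sum of rate x bin width over the bins whose
    span falls in that hour.  A trailing hour not fully covered by bins is
    still reported but flagged.
    """
    if series.n_bins == 0:
        raise CalorimetryError("empty DIT series")
    start = series.time_mid[0] - series.bin_width / 2
    rel = series.time_mid - series.bin_width / 2 - start  # bin start offsets
    hour_idx = np.floor(rel / 60.0 + 1e-9).astype(int)
    n_hours = hour_idx[-1] + 1
    dit_h = np.zeros(n_hours)
    ee_h = np.zeros(n_hours)
    np.add.at(dit_h, hour_idx, series.dit * series.bin_width)
    np.add.at(ee_h, hour_idx, series.ee_observed * series.bin_width)
    covered_last = np.sum(hour_idx == n_hours - 1) * series.bin_width
    return HourlySeries(
        hour_start=start + 60.0 * np.arange(n_hours),
        dit=dit_h,
        ee=ee_h,
        partial_last_hour=bool(covered_last < 60.0 - 1e-9),
    )


def total_auc(series: DITSeries, channel: str = "dit") -> float:
    """Area under the per-bin curve: sum of rate x bin width, in kcal."""
    if series.n_bins == 0:
        raise CalorimetryError("empty DIT series")
    if channel == "dit":
        rates = series.dit
    elif channel == "ee":
        rates = series.ee_observed
    elif channel == "predicted":
        rates = series.ee_predicted
    else:
        raise CalorimetryError(f"unknown channel {channel!r}")
    return float(np.sum(rates) * series.bin_width)


def summarize(series: DITSeries, protocol: FeedingProtocol) -> DITResult:
    """Totals, percentage ratios, and photoperiod activity means."""
    if protocol.intake_kcal <= 0:
        raise CalorimetryError("intake_kcal must be positive")
    total_dit = total_auc(series, "dit")
    total_ee = total_auc(series, "ee")
    hourly = aggregate_hourly(series)
    dark = series.photoperiod == "dark"
    light = series.photoperiod == "light"
    return DITResult(
        animal_id=series.animal_id,
        total_dit=total_dit,
        total_ee=total_ee,
        intake_kcal=protocol.intake_kcal,
        dit_over_intake=100.0 * total_dit / protocol.intake_kcal,
        dit_over_ee=100.0 * total_dit / total_ee,
        hourly_dit=hourly.dit,
        hourly_ee=hourly.ee,
        activity_dark=float(series.activity[dark].mean()) if dark.any() else math.nan,
        activity_light=float(series.activity[light].mean()) if light.any() else math.nan,
        n_negative_bins=int(np.sum(series.dit < 0)),
        model=series.model,
        protocol=protocol,
    )


def intake_per_bw(intake_kcal: float, bw_g: float) -> float:
    """Daily energy intake per gram body weight, to 3 significant figures.

    Works for any species: pass intake in kcal/day and body weight in grams
    (a 38.8 g mouse eating 21.6 kcal/day gives 0.557 kcal/g BW; a 63 kg
    human at 2650 kcal/day gives 0.0421 kcal/g BW).
    """
    if bw_g <= 0:
        raise CalorimetryError("body weight must be positive")
    if intake_kcal <= 0:
        raise CalorimetryError("intake must be positive")
    value = intake_kcal / bw_g
    digits = -int(math.floor(math.log10(abs(value)))) + 2
    return round(value, digits)


def species_dit_ratio(mouse_per_bw: float, human_per_bw: float) -> float:
    """Fold difference of per-body-weight rates between two species."""
    if mouse_per_bw <= 0 or human_per_bw <= 0:
        raise CalorimetryError("per-BW rates must be positive")
    return mouse_per_bw / human_per_bw
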