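"""Descriptive timing analyses of account cohorts.

Four read-outs of posting behaviour that complement the inferential stack:

* periodogram power spectral density of the binned event-count series, to
  check for (absent) dominant frequencies in activity;
* per-account delay SD versus delay mean — heavy-tailed, bursty posting
  shows SD roughly proportional to the mean (signal-dependent noise);
* von Mises circular statistics of the local posting hour: mean direction,
  concentration kappa and an SD-equivalent dispersion;
* weekly / hourly activity matrices (accounts x weekday or hour counts).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import signal, stats

from .events import EventStream, clock_features, compute_delays

__all__ = [
    "PeriodogramResult",
    "CircularSummary",
    "ScalingFit",
    "ActivityMatrix",
    "event_rate_series",
    "periodogram",
    "fit_von_mises",
    "kappa_from_resultant",
    "mean_sd_scaling",
    "activity_matrix",
]


@dataclass
class PeriodogramResult:
    frequency: np.ndarray  # Hz, positive ascending
    psd: np.ndarray  # linear power per Hz

    @property
    def psd_db(self) -> np.ndarray:
        """Power in dB/Hz; empty bins (zero power) map to -inf."""
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.psd)


@dataclass
class CircularSummary:
    mean_hour: float  # [0, 24)
    kappa: float  # concentration, >= 0 (inf for a point mass)
    resultant_length: float  # [0, 1]
    dispersion: float  # SD-equivalent spread, hours analogue on the circle


@dataclass
class ScalingFit:
    pairs: pd.DataFrame  # columns account_id, mean_delay, sd_delay
    slope: float
    intercept: float
    r: float
    log_log: bool


@dataclass
class ActivityMatrix:
    axis: str  # "weekday" | "hour"
    counts: pd.DataFrame  # rows = accounts (ascending total), cols = 7 or 24

    @property
    def account_order(self) -> list[str]:
        return list(self.counts.index)


# ---------------------------------------------------------------------------

def event_rate_series(stream: EventStream, bin_width_s: float) -> np.ndarray:
    """Event counts in consecutive fixed-width bins spanning the stream."""
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    if len(stream) == 0:
        raise ValueError("stream has no events")
    t = stream.times_utc
    idx = ((t - t[0]) // int(bin_width_s)).astype(np.int64)
    return np.bincount(idx)


def periodogram(counts, bin_width_s: float) -> PeriodogramResult:
    """Mean-removed standard periodogram of a count series.

    Frequencies are in Hz (sampling rate 1/bin_width); power is one-sided
    density so that sum(psd) * df equals the series variance (Parseval).
    The zero-frequency bin is dropped.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 4:
        raise ValueError("need a series of length >= 4")
    freq, psd = signal.periodogram(
        counts,
        fs=1.0 / bin_width_s,
        window="boxcar",
        detrend="constant",
        scaling="density",
    )
    return PeriodogramResult(frequency=freq[1:], psd=psd[1:])


# ---------------------------------------------------------------------------
# circular statistics of posting hour

def kappa_from_resultant(r_bar: float) -> float:
    """Invert the mean resultant length to the von Mises concentration via
    the standard piecewise approximation (Fisher)."""
    if r_bar < 0.53:
        return 2 * r_bar + r_bar**3 + 5 * r_bar**5 / 6
    if r_bar < 0.85:
        return -0.4 + 1.39 * r_bar + 0.43 / (1 - r_bar)
    denom = r_bar**3 - 4 * r_bar**2 + 3 * r_bar
    return float("inf") if denom == 0 else 1.0 / denom


def fit_von_mises(hours, dispersion: str = "inv_sqrt_kappa") -> CircularSummary:
    """Fit a von Mises distribution to hour-of-day values (0-23 or fractional).

    Hours map to angles theta = 2*pi*h/24; the mean direction comes from the
    resultant vector and kappa from the resultant length. ``dispersion``
    selects the SD-equivalent conversion: ``inv_sqrt_kappa`` (1/sqrt(kappa),
    the large-kappa wrapped-normal SD) or ``circular_sd``
    (sqrt(-2 ln R), the circular standard deviation). Both are returned in
    radian-equivalent units scaled to hours (x 24 / 2 pi).
    """
    hours = np.asarray(hours, dtype=float)
    if hours.size < 2:
        raise ValueError("need at least 2 events")
    theta = 2.0 * np.pi * hours / 24.0
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    r_bar = float(np.hypot(c, s))
    if r_bar < 1e-12:
        raise ValueError("resultant length is zero; mean direction undefined")
    mean_angle = float(np.arctan2(s, c)) % (2.0 * np.pi)
    kappa = kappa_from_resultant(r_bar)
    if dispersion == "inv_sqrt_kappa":
        disp = 0.0 if np.isinf(kappa) else 1.0 / np.sqrt(kappa)
    elif dispersion == "circular_sd":
        disp = float(np.sqrt(max(0.0, -2.0 * np.log(r_bar))))
    else:
        raise ValueError(f"unknown dispersion convention {dispersion!r}")
    hours_per_radian = 24.0 / (2.0 * np.pi)
    return CircularSummary(
        mean_hour=mean_angle * hours_per_radian,
        kappa=kappa,
        resultant_length=r_bar,
        dispersion=disp * hours_per_radian,
    )


# ---------------------------------------------------------------------------

def mean_sd_scaling(cohort, log_log: bool = False) -> ScalingFit:
    """Per-account delay mean and SD, with a least-squares line through the
    scatter (optionally in log-log coordinates) and the Pearson r."""
    rows = []
    for stream in cohort:
        if len(stream) < 3:  # fewer than 2 delays: SD undefined
            warnings.warn(
                f"account {stream.account_id!r} has < 2 delays; skipped in scaling fit"
            )
            continue
        delays = compute_delays(stream).delays
        rows.append(
            {
                "account_id": stream.account_id,
                "mean_delay": float(delays.mean()),
                "sd_delay": float(delays.std(ddof=1)),
            }
        )
    if len(rows) < 2:
        raise ValueError("need at least 2 accounts with >= 2 delays each")
    pairs = pd.DataFrame(rows)
    x, y = pairs["mean_delay"].to_numpy(), pairs["sd_delay"].to_numpy()
    if log_log:
        x, y = np.log10(x), np.log10(y)
    if np.std(x) == 0:
        raise ValueError("degenerate fit: all accounts have the same mean delay")
    fit = stats.linregress(x, y)
    return ScalingFit(
        pairs=pairs,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        log_log=log_log,
    )


def activity_matrix(cohort, axis: str = "hour", top_n: int | None = None) -> ActivityMatrix:
    """Accounts x (weekday | hour) event-count matrix.

    Rows are sorted by ascending total event count; ``top_n`` keeps only the
    most active accounts (still sorted ascending).
    """
    if axis not in ("weekday", "hour"):
        raise ValueError("axis must be 'weekday' or 'hour'")
    n_cols = 7 if axis == "weekday" else 24
    offset = 1 if axis == "weekday" else 0  # ISO weekdays run 1-7
    rows = {}
    for stream in cohort:
        clock = clock_features(stream)
        values = clock.weekday if axis == "weekday" else clock.local_hour
        rows[stream.account_id] = np.bincount(values - offset, minlength=n_cols)
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.columns = (
        list(range(1, 8)) if axis == "weekday" else list(range(24))
    )
    totals = counts.sum(axis=1)
    counts = counts.loc[totals.sort_values(kind="stable").index]
    if top_n is not None:
        counts = counts.iloc[-top_n:]
    return ActivityMatrix(axis=axis, counts=counts)
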