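"""Empirical feature densities on fixed grids.

The classifier scores events against non-parametric class densities:

* inter-event delays are histogrammed on 100 logarithmically spaced bins
  spanning configurable decades (default 10^0 to 10^7 s) and normalised to
  integrate to one (probability per second);
* hours of day are 24-bin relative frequencies (probability per hourly bin);
* the joint of the two is either the product of the marginals (independence
  assumed) or a full 100 x 24 two-dimensional histogram.

Empty bins are raised to a small documented floor so that log-scores stay
finite when a query lands where a class has never been observed; the
pre-floor values are retained so normalisation remains checkable. Point
queries between bin centres are answered by a monotone shape-preserving
piecewise-cubic (PCHIP) interpolant, which cannot overshoot or go negative
the way an unconstrained cubic spline can on sparse histograms; queries
outside the binned support return the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "BinConfig",
    "LogBinnedDensity",
    "HourDensity",
    "JointDensity",
    "EmpiricalCDF",
    "fit_delay_density",
    "fit_hour_density",
    "fit_joint",
    "density_at",
    "build_cdf",
    "build_ccdf",
]

#: density floor for empty delay bins, probability per second
DELAY_FLOOR = 1e-12
#: mass floor for empty hour bins, probability per hourly bin
HOUR_FLOOR = 1e-6


@dataclass(frozen=True)
class BinConfig:
    """Log-spaced delay binning: ``n_bins`` bins between ``10**decade_min``
    and ``10**decade_max`` seconds."""

    decade_min: float = 0.0
    decade_max: float = 7.0
    n_bins: int = 100

    def edges(self) -> np.ndarray:
        return np.logspace(self.decade_min, self.decade_max, self.n_bins + 1)

    def centres(self) -> np.ndarray:
        e = self.edges()
        return np.sqrt(e[:-1] * e[1:])  # geometric centres


@dataclass
class LogBinnedDensity:
    """Delay histogram density on log-spaced bins (probability per second)."""

    bin_edges: np.ndarray  # n_bins + 1 strictly increasing positive seconds
    density: np.ndarray  # n_bins, post-floor
    floor: float
    n_samples: int
    raw_density: np.ndarray = field(repr=False, default=None)  # pre-floor

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.raw_density is None:
            self.raw_density = self.density.copy()
        self.raw_density = np.asarray(self.raw_density, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0) or self.bin_edges[0] <= 0:
            raise ValueError("bin edges must be positive and strictly increasing")
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("need one density value per bin")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        self._interp = None

    @property
    def centres(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def integral(self, pre_floor: bool = True) -> float:
        values = self.raw_density if pre_floor else self.density
        return float(np.sum(values * self.widths))

    def __call__(self, query) -> np.ndarray:
        return density_at(self, query)

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "density": self.density.tolist(),
            "raw_density": self.raw_density.tolist(),
            "floor": self.floor,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogBinnedDensity":
        return cls(
            bin_edges=np.asarray(d["bin_edges"]),
            density=np.asarray(d["density"]),
            floor=d["floor"],
            n_samples=d["n_samples"],
            raw_density=np.asarray(d["raw_density"]),
        )


@dataclass
class HourDensity:
    """24-bin hour-of-day mass function (sums to one)."""

    mass: np.ndarray
    n_samples: int
    floor: float = HOUR_FLOOR

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (24,):
            raise ValueError("hour density needs exactly 24 masses")
        if np.any(self.mass < 0):
            raise ValueError("masses must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("hour masses must sum to 1")

    def __call__(self, hours) -> np.ndarray:
        hours = np.asarray(hours, dtype=np.int64)
        if np.any((hours < 0) | (hours > 23)):
            raise ValueError("hours must lie in [0, 23]")
        return self.mass[hours]

    def to_dict(self) -> dict:
        return {"mass": self.mass.tolist(), "n_samples": self.n_samples, "floor": self.floor}

    @classmethod
    def from_dict(cls, d: dict) -> "HourDensity":
        return cls(mass=np.asarray(d["mass"]), n_samples=d["n_samples"], floor=d["floor"])


@dataclass
class JointDensity:
    """Joint (delay, hour) density: product of marginals, or a full 2-D
    histogram when independence is not assumed."""

    mode: str  # "independent" | "full2d"
    delay_marginal: LogBinnedDensity
    hour_marginal: HourDensity
    grid: np.ndarray | None = None  # (n_bins, 24) density per (second x hour-bin)
    floor: float = DELAY_FLOOR * HOUR_FLOOR

    def __post_init__(self) -> None:
        if self.mode not in ("independent", "full2d"):
            raise ValueError(f"unknown joint mode {self.mode!r}")
        if self.mode == "full2d":
            if self.grid is None:
                raise ValueError("full2d mode requires the fitted grid")
            self.grid = np.asarray(self.grid, dtype=float)
            expected = (len(self.delay_marginal.density), 24)
            if self.grid.shape != expected:
                raise ValueError(f"grid must have shape {expected}")

    def evaluate(self, delays, hours) -> np.ndarray:
        delays = np.atleast_1d(np.asarray(delays, dtype=float))
        hours = np.atleast_1d(np.asarray(hours, dtype=np.int64))
        if self.mode == "independent":
            return density_at(self.delay_marginal, delays) * self.hour_marginal(hours)
        edges = self.delay_marginal.bin_edges
        idx = np.searchsorted(edges, delays, side="right") - 1
        inside = (idx >= 0) & (idx < self.grid.shape[0])
        out = np.full(delays.shape, self.floor)
        ok = inside & (hours >= 0) & (hours <= 23)
        out[ok] = self.grid[idx[ok], hours[ok]]
        return out


@dataclass
class EmpiricalCDF:
    """Right-continuous empirical step function on sorted support points.

    ``kind="cdf"`` stores P(X <= x) (non-decreasing, 0 below the support);
    ``kind="ccdf"`` stores P(X > x) (non-increasing, 1 below the support).
    """

    support: np.ndarray
    value: np.ndarray
    kind: str = "cdf"

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.kind not in ("cdf", "ccdf"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        diffs = np.diff(self.value)
        if self.kind == "cdf" and np.any(diffs < 0):
            raise ValueError("CDF values must be non-decreasing")
        if self.kind == "ccdf" and np.any(diffs > 0):
            raise ValueError("CCDF values must be non-increasing")
        if len(self.value) and (self.value.min() < -1e-12 or self.value.max() > 1 + 1e-12):
            raise ValueError("values must lie in [0, 1]")

    @property
    def left_value(self) -> float:
        """Value taken below the smallest support point."""
        return 0.0 if self.kind == "cdf" else 1.0

    def __call__(self, query) -> np.ndarray:
        query = np.asarray(query, dtype=float)
        idx = np.searchsorted(self.support, query, side="right")
        padded = np.concatenate(([self.left_value], self.value))
        out = padded[idx]
        return float(out) if query.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting

def fit_delay_density(
    delays,
    bin_config: BinConfig = BinConfig(),
    floor: float = DELAY_FLOOR,
) -> LogBinnedDensity:
    """Histogram delays on log-spaced bins, normalised to integrate to one.

    Samples outside the binned decades are ignored for normalisation (there
    should be none under the default decades for second-floored delays from
    accounts active less than ~116 days between posts).
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("need at least one delay")
    if np.any(delays <= 0):
        raise ValueError("delays must be positive (floor upstream)")
    edges = bin_config.edges()
    raw, _ = np.histogram(delays, bins=edges, density=True)
    density = np.where(raw > 0, raw, floor)
    n_in = int(np.sum((delays >= edges[0]) & (delays <= edges[-1])))
    return LogBinnedDensity(
        bin_edges=edges,
        density=density,
        floor=floor,
        n_samples=n_in,
        raw_density=raw,
    )


def fit_hour_density(hours, floor: float = HOUR_FLOOR) -> HourDensity:
    """Relative hourly frequencies with an additive floor on empty bins,
    renormalised to sum to one."""
    hours = np.asarray(hours, dtype=np.int64)
    if hours.size == 0:
        raise ValueError("need at least one hour")
    if np.any((hours < 0) | (hours > 23)):
        raise ValueError("hours must lie in [0, 23]")
    counts = np.bincount(hours, minlength=24).astype(float)
    mass = counts / counts.sum()
    mass = np.where(mass > 0, mass, floor)
    mass = mass / mass.sum()
    return HourDensity(mass=mass, n_samples=int(counts.sum()), floor=floor)


def fit_joint(
    delay_d: LogBinnedDensity,
    hour_d: HourDensity,
    mode: str = "independent",
    paired_samples: tuple[Sequence[float], Sequence[int]] | None = None,
) -> JointDensity:
    """Combine marginals into a joint density.

    ``independent`` evaluates as the product of the two marginals. ``full2d``
    needs the paired (delay, hour) samples and fits a floored, normalised
    2-D histogram on the delay bins x 24 hour bins grid.
    """
    if mode == "independent":
        return JointDensity(mode=mode, delay_marginal=delay_d, hour_marginal=hour_d)
    if mode != "full2d":
        raise ValueError(f"unknown joint mode {mode!r}")
    if paired_samples is None:
        raise ValueError("full2d mode requires paired (delay, hour) samples")
    delays = np.asarray(paired_samples[0], dtype=float)
    hours = np.asarray(paired_samples[1], dtype=np.int64)
    if delays.shape != hours.shape or delays.size == 0:
        raise ValueError("paired samples must be equal-length and non-empty")
    edges = delay_d.bin_edges
    hist, _, _ = np.histogram2d(delays, hours, bins=[edges, np.arange(25) - 0.5])
    widths = np.diff(edges)[:, None]  # hour bin width is one bin
    total = hist.sum()
    if total == 0:
        raise ValueError("no paired samples fall inside the delay bins")
    grid = hist / (total * widths)
    floor = delay_d.floor * hour_d.floor
    grid = np.where(grid > 0, grid, floor)
    return JointDensity(
        mode="full2d",
        delay_marginal=delay_d,
        hour_marginal=hour_d,
        grid=grid,
        floor=floor,
    )


def density_at(density: LogBinnedDensity, query) -> np.ndarray:
    """Evaluate a delay density at arbitrary points.

    PCHIP interpolation through (bin centre, density) nodes in log-delay
    coordinates, clamped below at the floor; outside the centre range the
    floor is returned. Scalar in, scalar out.
    """
    if density._interp is None:
        density._interp = PchipInterpolator(
            np.log10(density.centres), density.density, extrapolate=False
        )
    query = np.asarray(query, dtype=float)
    scalar = query.ndim == 0
    q = np.atleast_1d(query)
    out = np.full(q.shape, density.floor)
    ok = q > 0
    if np.any(ok):
        vals = density._interp(np.log10(q[ok]))
        vals = np.where(np.isnan(vals), density.floor, np.maximum(vals, density.floor))
        out[ok] = vals
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# empirical CDFs

def build_cdf(delays) -> EmpiricalCDF:
    """Right-continuous empirical CDF on the sorted unique delay values."""
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("need at least one delay")
    support, counts = np.unique(delays, return_counts=True)
    value = np.cumsum(counts) / delays.size
    return EmpiricalCDF(support=support, value=value)


def build_ccdf(delays) -> EmpiricalCDF:
    """Complementary CDF P(X > x): 1 below the minimum, stepping down to 0
    at the maximum; complements :func:`build_cdf` pointwise."""
    cdf = build_cdf(delays)
    return EmpiricalCDF(support=cdf.support, value=1.0 - cdf.value, kind="ccdf")
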