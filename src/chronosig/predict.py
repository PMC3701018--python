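"""Class-level prediction of the next event's delay distribution.

The predictive model for an account class is simply the empirical CDF of
the class's pooled inter-event delays: F(t) is the probability that the
next event has occurred within t seconds of the previous one. Each observed
delay tau defines a step function — 0 before tau, 1 at and after it (the
observed cumulative indicator) — and the model is scored per event by the
coefficient of determination R^2 = 1 - SSres/SStot between the model CDF
and the step, evaluated on a comparison grid. R^2 is left unclamped:
negative values mean the CDF predicts the event time worse than a constant
at the step's mean, and they are meaningful (the uniform-random null model
scores far below zero on realistic delays).

Two model variants are provided: a single unconditional CDF per class, and
an hour-conditioned variant with 24 CDFs selected by the local hour of the
event preceding the delay (empty hours fall back to the unconditional CDF).

The default comparison grid is a fixed set of log-spaced points spanning
the delay-bin decades, shared by every model being compared. A fixed grid
keeps per-event R^2 values comparable across models: grids tied to each
model's own support points make the mean R^2 depend on the number of
support points (extreme delays contribute residual sums that scale with
grid size), which would confound single-vs-hourly and model-vs-null
comparisons. Any explicit grid can be passed instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import BinConfig, EmpiricalCDF, build_cdf

__all__ = [
    "DelayCDFModel",
    "HourConditionedModel",
    "StepFunction",
    "PredictionReport",
    "UndefinedR2Error",
    "default_eval_grid",
    "build_single_model",
    "build_hourly_model",
    "step_function",
    "r2_against_step",
    "evaluate_account",
    "uniform_null_model",
]

#: points in the default log-spaced comparison grid
DEFAULT_GRID_SIZE = 200


class UndefinedR2Error(ValueError):
    """All grid points lie on one side of the step: SStot is zero and R^2 is
    undefined. Widen the evaluation grid or skip the event."""


def default_eval_grid(
    bin_config: BinConfig = BinConfig(), n_points: int = DEFAULT_GRID_SIZE
) -> np.ndarray:
    """Log-spaced comparison grid over the delay-bin decades."""
    return np.logspace(bin_config.decade_min, bin_config.decade_max, n_points)


@dataclass(frozen=True)
class StepFunction:
    """Observed cumulative indicator of one delay: 0 before tau, 1 after."""

    tau: float

    def __post_init__(self) -> None:
        if not self.tau >= 1:
            raise ValueError("tau must be >= 1 s (delays are floored)")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = (t >= self.tau).astype(float)
        return float(out) if t.ndim == 0 else out


def step_function(tau: float) -> StepFunction:
    return StepFunction(tau)


@dataclass
class DelayCDFModel:
    """Empirical delay CDF of one account class."""

    label: str
    cdf: EmpiricalCDF

    def __call__(self, t) -> np.ndarray:
        return self.cdf(t)


@dataclass
class HourConditionedModel:
    """24 per-hour delay CDFs with an unconditional fallback."""

    label: str
    by_hour: dict[int, DelayCDFModel]
    fallback: DelayCDFModel

    def model_for_hour(self, hour: int) -> DelayCDFModel:
        if not 0 <= hour <= 23:
            raise ValueError("hour must lie in [0, 23]")
        return self.by_hour.get(int(hour), self.fallback)


@dataclass
class PredictionReport:
    """Per-event R^2 summary for one evaluated account (or pooled set)."""

    per_event_r2: np.ndarray
    n_events: int  # events with a defined R^2
    n_skipped: int  # events whose step fell outside the grid

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_event_r2)) if self.n_events else float("nan")

    @property
    def sd_r2(self) -> float:
        if self.n_events > 1:
            return float(np.std(self.per_event_r2, ddof=1))
        return 0.0

    def to_dict(self) -> dict:
        return {
            "mean_r2": self.mean_r2,
            "sd_r2": self.sd_r2,
            "n": self.n_events,
            "n_skipped": self.n_skipped,
        }


# ---------------------------------------------------------------------------
# model construction

def build_single_model(class_delays, label: str = "unlabelled") -> DelayCDFModel:
    """Unconditional model: empirical CDF of the pooled class delays."""
    delays = np.asarray(class_delays, dtype=float)
    if delays.size < 2:
        raise ValueError("need at least 2 delays to build a predictive model")
    return DelayCDFModel(label=label, cdf=build_cdf(delays))


def build_hourly_model(
    class_delays, preceding_hours, label: str = "unlabelled"
) -> HourConditionedModel:
    """Hour-conditioned model: one CDF per preceding local hour.

    Hours with no observed delay (or a single one) resolve to the
    unconditional fallback CDF.
    """
    delays = np.asarray(class_delays, dtype=float)
    hours = np.asarray(preceding_hours, dtype=np.int64)
    if delays.shape != hours.shape:
        raise ValueError("delays and preceding_hours must be the same length")
    if delays.size < 2:
        raise ValueError("need at least 2 delays overall")
    fallback = build_single_model(delays, label=label)
    by_hour = {}
    for h in range(24):
        sub = delays[hours == h]
        if sub.size >= 2:
            by_hour[h] = DelayCDFModel(label=label, cdf=build_cdf(sub))
    return HourConditionedModel(label=label, by_hour=by_hour, fallback=fallback)


def uniform_null_model(seed=None, n: int = 10_000) -> DelayCDFModel:
    """Null model: empirical CDF of n draws from Uniform(1, 1e6) seconds."""
    if n < 2:
        raise ValueError("need at least 2 draws")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.uniform(1.0, 1_000_000.0, size=n)
    return DelayCDFModel(label="null", cdf=build_cdf(draws))


# ---------------------------------------------------------------------------
# scoring

def r2_against_step(model_cdf, tau: float, eval_grid=None) -> float:
    """Coefficient of determination between a model CDF and the observed
    step at tau, on the evaluation grid.

    residuals = step - CDF at each grid point; SStot is taken about the mean
    of the step values. Raises :class:`UndefinedR2Error` when every grid
    point falls on one side of tau.
    """
    if eval_grid is None:
        eval_grid = default_eval_grid()
    grid = np.asarray(eval_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("evaluation grid must be non-empty")
    step = (grid >= tau).astype(float)
    m = step.sum()
    if m == 0 or m == grid.size:
        raise UndefinedR2Error(
            f"all {grid.size} grid points lie on one side of tau={tau}"
        )
    cdf_vals = model_cdf(grid) if callable(model_cdf) else np.asarray(model_cdf, float)
    ss_res = float(np.sum((step - cdf_vals) ** 2))
    ss_tot = float(np.sum((step - step.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _r2_batch(cdf_vals: np.ndarray, grid: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Vectorised per-tau R^2 on a shared grid via prefix sums.

    For k grid points below tau and m = G - k at/above it:
    SSres = sum_{j<k} F_j^2 + sum_{j>=k} (1 - F_j)^2 and SStot = m*k/G.
    Events with k == 0 or m == 0 come back NaN (undefined).
    """
    G = grid.size
    below_sq = np.concatenate(([0.0], np.cumsum(cdf_vals**2)))
    above_sq = np.concatenate(([0.0], np.cumsum(((1.0 - cdf_vals) ** 2)[::-1])))[::-1]
    k = np.searchsorted(grid, taus, side="left")
    m = G - k
    out = np.full(taus.shape, np.nan)
    ok = (k > 0) & (m > 0)
    ss_res = below_sq[k[ok]] + above_sq[k[ok]]
    ss_tot = m[ok] * k[ok] / G
    out[ok] = 1.0 - ss_res / ss_tot
    return out


def evaluate_account(
    model,
    account_delays,
    preceding_hours=None,
    eval_grid=None,
) -> PredictionReport:
    """Score each of an account's delays against a class model.

    ``model`` is a :class:`DelayCDFModel` or :class:`HourConditionedModel`;
    the latter needs ``preceding_hours`` to select the per-hour CDF for each
    delay. Events whose step function has no crossing inside the grid are
    skipped and counted in ``n_skipped``.
    """
    taus = np.asarray(account_delays, dtype=float)
    if taus.size == 0:
        raise ValueError("account has no delays to evaluate")
    if eval_grid is None:
        eval_grid = default_eval_grid()
    grid = np.sort(np.asarray(eval_grid, dtype=float))
    if isinstance(model, HourConditionedModel):
        if preceding_hours is None:
            raise ValueError("hour-conditioned model needs preceding_hours")
        hours = np.asarray(preceding_hours, dtype=np.int64)
        if hours.shape != taus.shape:
            raise ValueError("delays and preceding_hours must be the same length")
        r2 = np.full(taus.shape, np.nan)
        for h in np.unique(hours):
            sub_model = model.model_for_hour(int(h))
            mask = hours == h
            r2[mask] = _r2_batch(sub_model(grid), grid, taus[mask])
    else:
        r2 = _r2_batch(model(grid), grid, taus)
    defined = np.isfinite(r2)
    return PredictionReport(
        per_event_r2=r2[defined],
        n_events=int(defined.sum()),
        n_skipped=int((~defined).sum()),
    )
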