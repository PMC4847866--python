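"""Ornstein-Uhlenbeck home-range movement model.

A fish with a stable home range is modelled as a biased random walk: pure
diffusion (white Gaussian noise of intensity ``epsilon`` per coordinate,
m^2/min) plus a linear restoring force of strength ``k`` (1/min) toward the
home-range center.  At stationarity each coordinate is Gaussian around the
center with variance ``epsilon / (2 k)``, so the distance from the center is
Rayleigh and the disc containing the animal 95% of the time has radius

    radius = sqrt(-epsilon * ln(0.05) / k)

The exact discrete-time transition over a step of ``dt`` minutes is an AR(1):

    r[n+1] = center + exp(-k dt) * (r[n] - center) + R[n]

with independent zero-mean Gaussian innovations per coordinate of s.d.

    sigma(dt) = sqrt(epsilon * (1 - exp(-2 k dt)) / (2 k))

Activity is diurnal: the animal moves only during a fixed block of daylight
minutes each day and holds position overnight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "LN20",
    "OUParams",
    "DielSchedule",
    "Trajectory",
    "radius_from_k_eps",
    "eps_from_radius_k",
    "step_sd",
    "stationary_sd",
    "transition_mean",
    "simulate_path",
]

#: -ln(1 - 0.95); links (k, epsilon) to the 95% occupancy radius.
LN20 = -math.log(0.05)

#: Night-gap policies for chaining consecutive active days.
NIGHT_GAP_POLICIES = ("contiguous", "elapsed")


def radius_from_k_eps(k: float, epsilon: float) -> float:
    """Radius of the 95% home-range disc for exploration rate ``k`` (1/min)
    and noise intensity ``epsilon`` (m^2/min).

    Increasing in epsilon, decreasing in k.  Undefined for ``k <= 0``: pure
    diffusion has no stationary distribution, hence no bounded home range.
    """
    if k <= 0:
        raise ValueError(f"radius undefined for k <= 0 (got k={k})")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0 (got {epsilon})")
    return math.sqrt(epsilon * LN20 / k)


def eps_from_radius_k(radius: float, k: float) -> float:
    """Noise intensity (m^2/min) giving a 95% home-range disc of ``radius``
    meters at exploration rate ``k``.  Algebraic inverse of
    :func:`radius_from_k_eps`.
    """
    if k <= 0:
        raise ValueError(f"epsilon undefined for k <= 0 (got k={k})")
    if radius < 0:
        raise ValueError(f"radius must be >= 0 (got {radius})")
    return radius * radius * k / LN20


def step_sd(epsilon: float, k: float, dt: float) -> float:
    """Per-coordinate innovation s.d. (meters) of the discrete OU transition
    over ``dt`` minutes.

    Continuous at ``k = 0`` where it takes the Brownian limit
    ``sqrt(epsilon * dt)``; bounded above by the stationary s.d.
    ``sqrt(epsilon / (2 k))`` for ``k > 0``.
    """
    if epsilon < 0 or k < 0 or dt <= 0:
        raise ValueError(
            f"require epsilon >= 0, k >= 0, dt > 0 (got {epsilon}, {k}, {dt})"
        )
    x = 2.0 * k * dt
    # -expm1(-x)/x -> 1 as x -> 0: exact Brownian limit without cancellation.
    return math.sqrt(epsilon * dt * (-math.expm1(-x) / x)) if x > 0 else math.sqrt(
        epsilon * dt
    )


def stationary_sd(epsilon: float, k: float) -> float:
    """Per-coordinate s.d. of the stationary OU distribution, sqrt(eps/(2k))."""
    if k <= 0:
        raise ValueError("stationary distribution requires k > 0")
    return math.sqrt(epsilon / (2.0 * k))


@dataclass(frozen=True)
class OUParams:
    """Movement parameters of the home-range model.

    Attributes
    ----------
    center_x, center_y : float
        Home-range center, planar meters (easting / northing).
    k : float
        Exploration rate, 1/min; strength of the attraction to the center.
    epsilon : float
        Noise intensity, m^2/min per coordinate.
    """

    center_x: float
    center_y: float
    k: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0 (got {self.k})")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0 (got {self.epsilon})")
        for name in ("center_x", "center_y"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_radius(
        cls, center_x: float, center_y: float, k: float, radius: float
    ) -> "OUParams":
        """Build parameters from the field's reporting parameterization
        (k, 95% radius) instead of (k, epsilon)."""
        return cls(center_x, center_y, k, eps_from_radius_k(radius, k))

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y])

    @property
    def radius(self) -> float:
        """95% home-range radius in meters (derived from k and epsilon)."""
        return radius_from_k_eps(self.k, self.epsilon)


@dataclass(frozen=True)
class DielSchedule:
    """Diurnal activity calendar: ``days`` tracking days with
    ``active_minutes_per_day`` minutes of movement in each (default 840,
    i.e. 14 daylight hours)."""

    days: int
    active_minutes_per_day: int = 840
    start_date: str = "2011-08-01"

    def __post_init__(self) -> None:
        if self.days <= 0 or self.active_minutes_per_day <= 0:
            raise ValueError("days and active_minutes_per_day must be positive")

    @property
    def total_minutes(self) -> int:
        return self.days * self.active_minutes_per_day

    def day_of_minute(self, minute: np.ndarray | int):
        """Day index of an active-minute index: floor(m / active_minutes_per_day)."""
        return np.asarray(minute) // self.active_minutes_per_day


@dataclass(frozen=True)
class Trajectory:
    """A simulated (or reconstructed) path at 1-minute resolution."""

    positions: np.ndarray  # (n, 2) planar meters
    day_index: np.ndarray  # (n,) int
    params_used: OUParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if len(self.day_index) != len(pos):
            raise ValueError("day_index length must match positions")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "day_index", np.asarray(self.day_index, dtype=int))

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute_index": np.arange(len(self)),
                "day_index": self.day_index,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        )


def transition_mean(
    pos: np.ndarray, params: OUParams, dt: float
) -> np.ndarray:
    """Conditional mean of the next position after ``dt`` minutes:
    ``center + exp(-k dt) * (pos - center)``, componentwise.

    ``pos`` may be a single (2,) point or an (n, 2) batch.
    """
    pos = np.asarray(pos, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("pos must be finite")
    a = math.exp(-params.k * dt)
    return params.center + a * (pos - params.center)


def _boundary_dts(schedule: DielSchedule, night_gap: str) -> float:
    """Transition time (minutes) between the last active minute of one day
    and the first of the next."""
    if night_gap == "contiguous":
        return 1.0
    if night_gap == "elapsed":
        return 1.0 + (1440.0 - schedule.active_minutes_per_day)
    raise ValueError(f"night_gap must be one of {NIGHT_GAP_POLICIES}")


def simulate_path(
    params: OUParams,
    schedule: DielSchedule,
    seed: int | np.random.Generator,
    night_gap: str = "contiguous",
) -> Trajectory:
    """Simulate a daylight-only OU path at 1-minute resolution.

    The initial position is drawn from the stationary distribution (Gaussian
    around the center, per-coordinate s.d. sqrt(eps/(2k))); each subsequent
    position follows the exact discrete transition with dt = 1 min.
    Consecutive days chain through the last position of the previous day:
    under ``night_gap='contiguous'`` the overnight transition is an ordinary
    1-minute step (the animal is assumed buried and motionless at night);
    under ``'elapsed'`` the overnight transition spans the full wall-clock
    gap, letting the process relax toward the center overnight.

    Innovations are drawn x-then-y per step in step order from a single
    generator, so a fixed integer seed reproduces the path bit-for-bit.
    """
    if params.k <= 0:
        raise ValueError("simulate_path requires k > 0 (stationary start)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.total_minutes
    sd0 = stationary_sd(params.epsilon, params.k)
    center = params.center

    u0 = rng.normal(0.0, sd0, size=2)  # offset from center at minute 0
    z = rng.standard_normal(size=(n - 1, 2))  # x-then-y per step (row-major)

    a1 = math.exp(-params.k)  # dt = 1 min
    s1 = step_sd(params.epsilon, params.k, 1.0)
    offsets = np.empty((n, 2))
    offsets[0] = u0

    if night_gap == "contiguous" or schedule.days == 1:
        # Single AR(1) recursion across all minutes: u[i] = a1 u[i-1] + s1 z[i]
        for c in range(2):
            y, _ = lfilter([1.0], [1.0, -a1], s1 * z[:, c], zi=[a1 * u0[c]])
            offsets[1:, c] = y
        if night_gap not in NIGHT_GAP_POLICIES:
            raise ValueError(f"night_gap must be one of {NIGHT_GAP_POLICIES}")
    else:
        dtb = _boundary_dts(schedule, night_gap)
        ab = math.exp(-params.k * dtb)
        sb = step_sd(params.epsilon, params.k, dtb)
        m = schedule.active_minutes_per_day
        u_prev = u0.copy()
        for d in range(schedule.days):
            lo = d * m
            if d > 0:
                # overnight transition into the first minute of day d
                offsets[lo] = ab * u_prev + sb * z[lo - 1]
            start = offsets[lo]
            zd = z[lo : lo + m - 1]
            for c in range(2):
                y, _ = lfilter([1.0], [1.0, -a1], s1 * zd[:, c], zi=[a1 * start[c]])
                offsets[lo + 1 : lo + m, c] = y
            u_prev = offsets[lo + m - 1]

    positions = center + offsets
    day_index = np.repeat(np.arange(schedule.days), schedule.active_minutes_per_day)
    seed_val = seed if isinstance(seed, int) else None
    return Trajectory(positions, day_index, params_used=params, seed=seed_val)
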