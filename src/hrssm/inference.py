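"""Bayesian estimation of home-range parameters from pooled detection counts.

The state-space model joins the discrete OU transition (process model, at
the pooling time-step) with binomial detection counts per receiver
(observation model): with latent position X_n during step n,

    X_n | X_{n-1} ~ N2(center + e^{-k dt}(X_{n-1} - center), sigma(dt)^2 I)
    ND_{n,j}      ~ Binomial(emissions_per_step, invlogit(alpha_day + beta_day d_{n,j}))

where d_{n,j} is the distance from X_n to receiver j.  The first latent
position carries the stationary density.  The latent position is held
constant within a step — exact when the fish is still, and an approximation
whose breakdown at long steps (fast fish moving appreciably within a step)
is precisely the bias mode the validation experiments probe.

Sampling is Metropolis-within-Gibbs: random-walk updates for the four
movement parameters (center_x, center_y on the natural scale; k and radius
on the log scale), and single-site random-walk updates for the latent
positions, vectorized over alternating even/odd sites (conditionally
independent given their neighbours).  Proposal scales adapt during burn-in
only.  epsilon is a deterministic transform of (radius, k) per draw.
Convergence is monitored with the Gelman-Rubin potential scale reduction
factor; < 1.1 is taken as converged.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .observation import DetectionCalibration, DetectionMatrix, ReceiverArray, _calib_by_day
from .ou import LN20, OUParams, eps_from_radius_k

__all__ = [
    "NormalPrior",
    "UniformPrior",
    "Priors",
    "MCMCConfig",
    "PosteriorResult",
    "process_loglik",
    "observation_loglik",
    "fit_ssm",
    "gelman_rubin",
    "reconstruct_trajectory",
]

_LOGIT_CLAMP = 36.0
PARAM_NAMES = ("center_x", "center_y", "k", "radius")


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalPrior:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be > 0")

    def logpdf(self, x: float) -> float:
        return -0.5 * ((x - self.mean) / self.sd) ** 2

    @staticmethod
    def from_precision(mean: float, tau: float) -> "NormalPrior":
        """BUGS-style parameterization: tau (tolerance) is 1/variance."""
        return NormalPrior(mean, 1.0 / math.sqrt(tau))


@dataclass(frozen=True)
class UniformPrior:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("need upper > lower")

    def logpdf(self, x: float) -> float:
        return 0.0 if self.lower <= x <= self.upper else -math.inf


@dataclass(frozen=True)
class Priors:
    """Prior distributions for the four movement parameters.

    Defaults are nearly flat relative to a coastal receiver array: k uniform
    on (0, 1) per minute, radius Normal(0, 10^4 m) truncated at zero, center
    coordinates Normal(0, 10^6 m).  The radius prior is truncated at zero
    (a negative radius is meaningless); its normal form lets informative
    between-fish knowledge be expressed as (mean, sd).
    """

    k: UniformPrior = field(default_factory=lambda: UniformPrior(0.0, 1.0))
    radius: NormalPrior | UniformPrior = field(
        default_factory=lambda: NormalPrior(0.0, 1.0e4)
    )
    center_x: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 1.0e6))
    center_y: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 1.0e6))

    def log_radius(self, r: float) -> float:
        if r <= 0:
            return -math.inf
        return self.radius.logpdf(r)

    def log_k(self, k: float) -> float:
        if k <= 0:
            return -math.inf
        return self.k.logpdf(k)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  The full profile follows standard practice for this
    model class: 3 chains, 10,000 burn-in iterations, keep 1 in 10 of the
    following 10,000 (3,000 retained draws in total).  ``scaled_down`` is a
    short profile for desk-scale replication studies."""

    n_chains: int = 3
    n_burnin: int = 10_000
    n_samples: int = 10_000  # post-burn-in iterations per chain
    thin: int = 10
    seed: int = 0
    adapt_interval: int = 50
    target_accept_scalar: float = 0.44
    target_accept_latent: float = 0.30

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_burnin, self.n_samples, self.thin) <= 0:
            raise ValueError("chain settings must be positive")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")

    @property
    def n_kept_per_chain(self) -> int:
        return self.n_samples // self.thin

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_chains=3, n_burnin=2_000, n_samples=2_000, thin=5, seed=seed)


# --------------------------------------------------------------------------
# log-densities
# --------------------------------------------------------------------------

def _step_dts(n_steps: int, step_minutes: float, day_index: np.ndarray,
              active_minutes_per_day: int = 840, night_gap: str = "contiguous") -> np.ndarray:
    """Transition durations dt[1..n-1]; dt[0] is unused (stationary start).

    Under ``contiguous`` every transition lasts one step; under ``elapsed``
    transitions crossing a day boundary additionally span the inactive night.
    """
    dt = np.full(n_steps, float(step_minutes))
    if night_gap == "elapsed":
        boundary = np.flatnonzero(np.diff(day_index) > 0) + 1
        dt[boundary] += 1440.0 - active_minutes_per_day
    elif night_gap != "contiguous":
        raise ValueError("night_gap must be 'contiguous' or 'elapsed'")
    return dt


def _proc_ll_terms(X: np.ndarray, cx: float, cy: float, k: float, eps: float,
                   dt: np.ndarray) -> float:
    """Process log-density of a latent path (sum over transitions plus the
    stationary density of the first state)."""
    if k <= 0 or eps <= 0:
        return -math.inf
    var0 = eps / (2.0 * k)
    a = np.exp(-k * dt[1:])
    s2 = var0 * (1.0 - a * a)
    ctr = np.array([cx, cy])
    resid = X[1:] - (ctr + a[:, None] * (X[:-1] - ctr))
    ll = -np.sum(np.log(2.0 * math.pi * s2) + (resid * resid).sum(axis=1) / (2.0 * s2))
    d0 = X[0] - ctr
    ll += -math.log(2.0 * math.pi * var0) - (d0 @ d0) / (2.0 * var0)
    return float(ll)


def process_loglik(
    latent: np.ndarray,
    params: OUParams,
    step_minutes: float,
    day_index: np.ndarray | None = None,
    night_gap: str = "contiguous",
    active_minutes_per_day: int = 840,
) -> float:
    """Log-density of a latent position path under the OU transition at
    dt = step_minutes, including the stationary density of the first state."""
    X = np.asarray(latent, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or len(X) < 2:
        raise ValueError("latent must be (n>=2, 2)")
    if not np.all(np.isfinite(X)):
        raise ValueError("latent positions must be finite")
    day = np.zeros(len(X), dtype=int) if day_index is None else np.asarray(day_index)
    dt = _step_dts(len(X), step_minutes, day, active_minutes_per_day, night_gap)
    return _proc_ll_terms(X, params.center_x, params.center_y, params.k,
                          params.epsilon, dt)


def observation_loglik(
    counts_row: np.ndarray,
    position: np.ndarray,
    calib: DetectionCalibration,
    array: ReceiverArray,
    emissions_per_step: int,
) -> float:
    """Binomial log-likelihood of one step's counts across receivers given
    the latent position (full log-pmf, binomial coefficients included)."""
    c = np.asarray(counts_row, dtype=float)
    if np.any(c > emissions_per_step) or np.any(c < 0):
        raise ValueError("counts must lie in [0, emissions_per_step]")
    d = array.distances(np.asarray(position, dtype=float))[0]
    eta = np.clip(calib.alpha + calib.beta * d, -_LOGIT_CLAMP, _LOGIT_CLAMP)
    m = float(emissions_per_step)
    ll = c * eta - m * np.logaddexp(0.0, eta)
    ll += gammaln(m + 1.0) - gammaln(c + 1.0) - gammaln(m - c + 1.0)
    return float(ll.sum())


def gelman_rubin(draws: np.ndarray) -> float:
    """Potential scale reduction factor from an (n_chains, n_draws) array.

    Classic between/within-chain variance ratio:
    sqrt(((n-1)/n W + B/n) / W) with B the between-chain variance of the
    chain means (times n) and W the mean within-chain variance.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need (chains >= 2, draws >= 2)")
    m, n = x.shape
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else math.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(math.sqrt(var_hat / W))


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """MCMC draws and summaries for one fitted fish/dataset."""

    draws: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    latent_draws: np.ndarray | None  # (n_chains, n_kept, n_steps, 2)
    rhat: dict[str, float]
    config: MCMCConfig
    priors: Priors
    seed: int
    data_hash: str
    acceptance: dict[str, float] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(v < 1.1 for v in self.rhat.values())

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()

    def bci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        x = self.pooled(name)
        return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))

    def mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.draws:
            x = self.pooled(name)
            lo, hi = self.bci(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(x.mean()),
                    "median": float(np.median(x)),
                    "bci_2.5": lo,
                    "bci_97.5": hi,
                    "rhat": self.rhat.get(name, math.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def draws_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self.draws.items():
            c, n = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), n),
                        "iteration": np.tile(np.arange(n), c),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------

def _obs_ll_block(X: np.ndarray, counts: np.ndarray, alpha: np.ndarray,
                  beta: np.ndarray, rec_xy: np.ndarray, m: float) -> np.ndarray:
    """Per-step observation log-likelihood (constants dropped) for positions
    X (b, 2) against counts (b, R) with per-step calibration (b,)."""
    dx = X[:, 0, None] - rec_xy[None, :, 0]
    dy = X[:, 1, None] - rec_xy[None, :, 1]
    d = np.sqrt(dx * dx + dy * dy)
    eta = np.clip(alpha[:, None] + beta[:, None] * d, -_LOGIT_CLAMP, _LOGIT_CLAMP)
    return (counts * eta - m * np.logaddexp(0.0, eta)).sum(axis=1)


def _init_state(counts: np.ndarray, rec_xy: np.ndarray, rng: np.random.Generator):
    """Deterministic data-driven initialization plus per-chain jitter:
    detection-weighted centroids for the center and latents, k = 0.01/min,
    radius = twice the spread of the step centroids."""
    tot = counts.sum(axis=1)
    overall = counts.sum(axis=0)
    if overall.sum() > 0:
        global_cent = (overall[:, None] * rec_xy).sum(axis=0) / overall.sum()
    else:
        global_cent = rec_xy.mean(axis=0)
    cent = np.tile(global_cent, (len(counts), 1))
    nz = tot > 0
    if nz.any():
        cent[nz] = (counts[nz, :, None] * rec_xy[None]).sum(axis=1) / tot[nz, None]
    spread = math.sqrt(((cent - cent.mean(axis=0)) ** 2).sum(axis=1).mean())
    radius0 = max(2.0 * spread, 50.0)
    # overdisperse chains for an honest convergence diagnostic
    center = global_cent + rng.normal(0.0, 30.0, size=2)
    k0 = 0.01 * math.exp(rng.normal(0.0, 0.5))
    radius0 = radius0 * math.exp(rng.normal(0.0, 0.3))
    X0 = cent + rng.normal(0.0, 10.0, size=cent.shape)
    return center, min(max(k0, 1e-5), 0.99), radius0, X0


def _run_chain(counts, alpha_step, beta_step, rec_xy, m, dt, priors, config,
               rng, fixed_latents=None):
    n_steps = len(counts)
    if fixed_latents is not None:
        X = np.array(fixed_latents, dtype=float)
        center, k, radius, _ = _init_state(counts, rec_xy, rng)
    else:
        center, k, radius, X = _init_state(counts, rec_xy, rng)
    cx, cy = float(center[0]), float(center[1])

    obs_ll = _obs_ll_block(X, counts, alpha_step, beta_step, rec_xy, m)

    even = np.arange(0, n_steps, 2)
    odd = np.arange(1, n_steps, 2)

    # proposal scales: center (m), log-k, log-radius, ridge (log-k with
    # epsilon held fixed), latent (m)
    scales = {"center_x": 20.0, "center_y": 20.0, "k": 0.4, "radius": 0.15,
              "ridge": 0.6}
    latent_scale = 25.0
    update_names = (*PARAM_NAMES, "ridge")
    acc = {p: 0 for p in update_names}
    tries = {p: 0 for p in update_names}
    acc_lat = 0
    tries_lat = 0
    acc_total = {p: 0 for p in update_names}
    tries_total = {p: 0 for p in update_names}
    acc_lat_total = 0
    tries_lat_total = 0

    def proc_ll(cx_, cy_, k_, r_):
        return _proc_ll_terms(X, cx_, cy_, k_, eps_from_radius_k(r_, k_), dt)

    cur_proc = proc_ll(cx, cy, k, radius)
    cur_logprior = (priors.center_x.logpdf(cx) + priors.center_y.logpdf(cy)
                    + priors.log_k(k) + priors.log_radius(radius))

    n_total = config.n_burnin + config.n_samples
    n_kept = config.n_kept_per_chain
    kept = {p: np.empty(n_kept) for p in PARAM_NAMES}
    kept["epsilon"] = np.empty(n_kept)
    kept_latent = (None if fixed_latents is not None
                   else np.empty((n_kept, n_steps, 2)))
    kk = 0

    for it in range(n_total):
        in_burnin = it < config.n_burnin

        # ---- movement parameters ----
        for name in update_names:
            tries[name] += 1
            tries_total[name] += 1
            if name == "ridge":
                # rescale k holding epsilon = radius^2 k / ln20 fixed: moves
                # along the weakly identified (k -> 0, radius -> inf) ridge.
                delta = scales[name] * rng.standard_normal()
                kp = k * math.exp(delta)
                rp = radius * math.exp(-delta / 2.0)
                if not (priors.k.lower < kp < priors.k.upper):
                    continue
                if isinstance(priors.radius, UniformPrior) and not (
                    priors.radius.lower <= rp <= priors.radius.upper
                ):
                    continue
                new_proc = proc_ll(cx, cy, kp, rp)
                new_lp = (priors.center_x.logpdf(cx) + priors.center_y.logpdf(cy)
                          + priors.log_k(kp) + priors.log_radius(rp))
                # det of the (k, radius) -> (kp, rp) map is e^{delta/2}
                log_ratio = new_proc + new_lp - cur_proc - cur_logprior + delta / 2.0
                if math.log(rng.random()) < log_ratio:
                    k, radius = kp, rp
                    cur_proc, cur_logprior = new_proc, new_lp
                    acc[name] += 1
                    acc_total[name] += 1
                continue
            if name == "center_x":
                prop = cx + scales[name] * rng.standard_normal()
                new_proc = proc_ll(prop, cy, k, radius)
                new_lp = (priors.center_x.logpdf(prop) + priors.center_y.logpdf(cy)
                          + priors.log_k(k) + priors.log_radius(radius))
                log_ratio = new_proc + new_lp - cur_proc - cur_logprior
            elif name == "center_y":
                prop = cy + scales[name] * rng.standard_normal()
                new_proc = proc_ll(cx, prop, k, radius)
                new_lp = (priors.center_x.logpdf(cx) + priors.center_y.logpdf(prop)
                          + priors.log_k(k) + priors.log_radius(radius))
                log_ratio = new_proc + new_lp - cur_proc - cur_logprior
            elif name == "k":
                prop = k * math.exp(scales[name] * rng.standard_normal())
                if not (priors.k.lower < prop < priors.k.upper):
                    continue
                new_proc = proc_ll(cx, cy, prop, radius)
                new_lp = (priors.center_x.logpdf(cx) + priors.center_y.logpdf(cy)
                          + priors.log_k(prop) + priors.log_radius(radius))
                log_ratio = (new_proc + new_lp - cur_proc - cur_logprior
                             + math.log(prop) - math.log(k))  # log-scale Jacobian
            else:  # radius
                prop = radius * math.exp(scales[name] * rng.standard_normal())
                if isinstance(priors.radius, UniformPrior) and not (
                    priors.radius.lower <= prop <= priors.radius.upper
                ):
                    continue
                new_proc = proc_ll(cx, cy, k, prop)
                new_lp = (priors.center_x.logpdf(cx) + priors.center_y.logpdf(cy)
                          + priors.log_k(k) + priors.log_radius(prop))
                log_ratio = (new_proc + new_lp - cur_proc - cur_logprior
                             + math.log(prop) - math.log(radius))
            if math.log(rng.random()) < log_ratio:
                if name == "center_x":
                    cx = prop
                elif name == "center_y":
                    cy = prop
                elif name == "k":
                    k = prop
                else:
                    radius = prop
                cur_proc, cur_logprior = new_proc, new_lp
                acc[name] += 1
                acc_total[name] += 1

        # ---- latent positions (even/odd blocks) ----
        if fixed_latents is None:
            eps = eps_from_radius_k(radius, k)
            var0 = eps / (2.0 * k)
            a_all = np.exp(-k * dt)
            s2_all = var0 * (1.0 - a_all * a_all)
            ctr = np.array([cx, cy])
            for idx in (even, odd):
                b = len(idx)
                tries_lat += b
                tries_lat_total += b
                Xp = X[idx] + latent_scale * rng.standard_normal((b, 2))
                d_obs = (_obs_ll_block(Xp, counts[idx], alpha_step[idx],
                                       beta_step[idx], rec_xy, m)
                         - obs_ll[idx])
                # incoming transition (or stationary density for step 0)
                dlt = np.zeros(b)
                first = idx[0] == 0
                inner = idx[1:] if first else idx
                sl = slice(1, None) if first else slice(None)
                if len(inner):
                    mu = ctr + a_all[inner, None] * (X[inner - 1] - ctr)
                    dlt[sl] += (((X[inner] - mu) ** 2).sum(axis=1)
                                - ((Xp[sl] - mu) ** 2).sum(axis=1)) / (2.0 * s2_all[inner])
                if first:
                    dlt[0] += (((X[0] - ctr) ** 2).sum() - ((Xp[0] - ctr) ** 2).sum()) / (
                        2.0 * var0
                    )
                # outgoing transition
                has_next = idx < n_steps - 1
                nxt = idx[has_next] + 1
                mu_old = ctr + a_all[nxt, None] * (X[nxt - 1] - ctr)
                mu_new = ctr + a_all[nxt, None] * (Xp[has_next] - ctr)
                dlt[has_next] += (((X[nxt] - mu_old) ** 2).sum(axis=1)
                                  - ((X[nxt] - mu_new) ** 2).sum(axis=1)) / (2.0 * s2_all[nxt])
                log_ratio = d_obs + dlt
                accept = np.log(rng.random(b)) < log_ratio
                if accept.any():
                    w = idx[accept]
                    X[w] = Xp[accept]
                    obs_ll[w] = obs_ll[w] + d_obs[accept]
                    acc_lat += int(accept.sum())
                    acc_lat_total += int(accept.sum())
            cur_proc = proc_ll(cx, cy, k, radius)

        # ---- adaptation (burn-in only) ----
        if in_burnin and (it + 1) % config.adapt_interval == 0:
            for name in update_names:
                if tries[name]:
                    rate = acc[name] / tries[name]
                    scales[name] *= math.exp(
                        np.clip(rate - config.target_accept_scalar, -0.5, 0.5)
                    )
                acc[name] = tries[name] = 0
            if tries_lat:
                rate = acc_lat / tries_lat
                latent_scale *= math.exp(
                    np.clip(rate - config.target_accept_latent, -0.5, 0.5)
                )
                acc_lat = tries_lat = 0

        # ---- collection ----
        if not in_burnin:
            j = it - config.n_burnin
            if (j + 1) % config.thin == 0 and kk < n_kept:
                kept["center_x"][kk] = cx
                kept["center_y"][kk] = cy
                kept["k"][kk] = k
                kept["radius"][kk] = radius
                kept["epsilon"][kk] = eps_from_radius_k(radius, k)
                if kept_latent is not None:
                    kept_latent[kk] = X
                kk += 1

    acc_rates = {p: (acc_total[p] / tries_total[p] if tries_total[p] else math.nan)
                 for p in update_names}
    if tries_lat_total:
        acc_rates["latent"] = acc_lat_total / tries_lat_total
    return kept, kept_latent, acc_rates


def fit_ssm(
    data: DetectionMatrix,
    array: ReceiverArray,
    calib,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
    night_gap: str = "contiguous",
    active_minutes_per_day: int = 840,
    fixed_latents: np.ndarray | None = None,
) -> PosteriorResult:
    """Fit the state-space model by MCMC.

    Runs ``config.n_chains`` independent Metropolis-within-Gibbs chains
    targeting the joint posterior of (center_x, center_y, k, radius) and the
    latent per-step positions; epsilon is derived per draw.  Burn-in and
    thinning follow ``config``; summaries and the Gelman-Rubin statistic are
    computed on the retained draws.  A result with any rhat >= 1.1 is
    returned but flagged (``converged`` False, plus a recorded warning).

    ``fixed_latents`` pins the latent path (no latent updates) — useful for
    validating the movement-parameter conditional against direct likelihood
    maximization.
    """
    priors = priors or Priors()
    config = config or MCMCConfig()
    if data.n_receivers != len(array):
        raise ValueError("detection matrix and receiver array disagree on receiver count")
    by_day = _calib_by_day(calib)
    missing = [int(d) for d in np.unique(data.day_index) if int(d) not in by_day]
    if missing:
        raise ValueError(f"no calibration for day(s) {missing}")

    counts = data.counts.astype(float)
    warnings_: list[str] = []
    if counts.sum() == 0:
        msg = "all-zero detection matrix: parameters are only weakly identifiable"
        warnings.warn(msg, stacklevel=2)
        warnings_.append(msg)
    alpha_step = np.array([by_day[int(d)].alpha for d in data.day_index])
    beta_step = np.array([by_day[int(d)].beta for d in data.day_index])
    dt = _step_dts(data.n_steps, data.step_minutes, data.day_index,
                   active_minutes_per_day, night_gap)
    m = float(data.emissions_per_step)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    n_kept = config.n_kept_per_chain
    draws = {p: np.empty((config.n_chains, n_kept))
             for p in (*PARAM_NAMES, "epsilon")}
    latent = (None if fixed_latents is not None
              else np.empty((config.n_chains, n_kept, data.n_steps, 2)))
    acc_all: dict[str, float] = {}
    for c, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        kept, kept_latent, acc_rates = _run_chain(
            counts, alpha_step, beta_step, array.xy, m, dt, priors, config, rng,
            fixed_latents=fixed_latents,
        )
        for p in draws:
            draws[p][c] = kept[p]
        if latent is not None:
            latent[c] = kept_latent
        for key, v in acc_rates.items():
            acc_all[f"chain{c}_{key}"] = v

    rhat = {p: gelman_rubin(draws[p]) for p in draws}
    if any(v >= 1.1 for v in rhat.values()):
        bad = {p: round(v, 3) for p, v in rhat.items() if v >= 1.1}
        msg = f"chains not converged (rhat >= 1.1): {bad}"
        warnings.warn(msg, stacklevel=2)
        warnings_.append(msg)

    h = hashlib.sha256(np.ascontiguousarray(data.counts).tobytes()).hexdigest()[:16]
    return PosteriorResult(
        draws=draws,
        latent_draws=latent,
        rhat=rhat,
        config=config,
        priors=priors,
        seed=config.seed,
        data_hash=h,
        acceptance=acc_all,
        warnings_=warnings_,
    )


def reconstruct_trajectory(
    result: PosteriorResult,
    n_draws: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean latent path plus ``n_draws`` paths resampled from the
    stored latent draws (for uncertainty display/export).

    Returns ``(mean_path, sampled_paths)`` with shapes (n_steps, 2) and
    (n_draws, n_steps, 2).
    """
    if result.latent_draws is None:
        raise ValueError("no latent draws stored on this result")
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    lat = result.latent_draws
    pooled = lat.reshape(-1, lat.shape[2], lat.shape[3])
    mean_path = pooled.mean(axis=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_draws == 0:
        return mean_path, pooled[:0]
    pick = rng.integers(0, len(pooled), size=n_draws)
    return mean_path, pooled[pick]
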