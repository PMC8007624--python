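"""Synthetic benchmark generators.

Four families of inputs, each with a known ground truth:

* two diffusively coupled logistic maps -- the bio-inspired predator-prey
  benchmark with tunable directed couplings ``beta_xy`` (Y onto X) and
  ``beta_yx`` (X onto Y);
* an S-species community emulating a biweekly coastal fish census
  (shared seasonal forcing, a planted strongly-interacting core, chaotic
  intrinsic dynamics, zero-inflated rare species);
* a bivariate Gaussian VAR(1), for which transfer entropy has a closed
  form (it coincides with Granger causality for Gaussian processes);
* an explicit-lag coupled pair, for delay-recovery tests.

All stochastic generators take one integer seed and are bitwise
reproducible; the deterministic map takes none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DivergenceError, NonStationaryError
from .timeseries import GroundTruth, TimeSeriesSet

__all__ = [
    "CoupledLogisticParams",
    "CommunityModelParams",
    "VARParams",
    "simulate_coupled_logistic",
    "simulate_community",
    "maizuru_like_params",
    "simulate_gaussian_var",
    "simulate_lagged_coupling",
    "phase_space_scan",
]

#: admissible state region for the coupled logistic map; iterates outside
#: indicate the divergent regime and abort the run.
_STATE_LO, _STATE_HI = -0.5, 1.5


@dataclass
class CoupledLogisticParams:
    """Parameters of the two-species coupled logistic map.

    The update is

        X(t+1) = X(t) [r_x - r_x X(t) - beta_xy Y(t)]
        Y(t+1) = Y(t) [r_y - r_y Y(t) - beta_yx X(t)]

    ``beta_xy`` is the strength of Y's effect on X and ``beta_yx`` the
    strength of X's effect on Y, both in [0, 1]. Defaults (growth rates
    3.8 and 3.5, initial states 0.4 and 0.2) put both species in the
    chaotic regime.
    """

    beta_xy: float = 0.0
    beta_yx: float = 0.0
    r_x: float = 3.8
    r_y: float = 3.5
    x0: float = 0.4
    y0: float = 0.2
    n_steps: int = 1000
    transient: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta_xy <= 1.0 and 0.0 <= self.beta_yx <= 1.0):
            raise ValueError("couplings beta_xy, beta_yx must lie in [0, 1]")
        if not (0.0 < self.x0 < 1.0 and 0.0 < self.y0 < 1.0):
            raise ValueError(
                "initial states must lie in (0, 1); 0 is an absorbing fixed point"
            )
        if self.n_steps <= self.transient:
            raise ValueError("n_steps must exceed transient")
        if self.transient < 0:
            raise ValueError("transient must be non-negative")


def simulate_coupled_logistic(
    params: CoupledLogisticParams, floor_at_zero: bool = False
) -> TimeSeriesSet:
    """Iterate the coupled logistic map; returns series named "X" and "Y".

    Deterministic: equal parameters give bitwise-identical output. The
    initial states count as the first time point, so ``n_steps`` retained
    points (after discarding ``transient``) are returned.

    Parameters
    ----------
    floor_at_zero
        If True, negative iterates are clamped to 0 instead of treated as
        divergence. Off by default: the published map is run as-is and a
        trajectory leaving [-0.5, 1.5] raises :class:`DivergenceError`.
    """
    p = params
    total = p.n_steps + p.transient
    x = np.empty(total)
    y = np.empty(total)
    x[0], y[0] = p.x0, p.y0
    for t in range(total - 1):
        xn = x[t] * (p.r_x - p.r_x * x[t] - p.beta_xy * y[t])
        yn = y[t] * (p.r_y - p.r_y * y[t] - p.beta_yx * x[t])
        if floor_at_zero:
            xn = max(xn, 0.0)
            yn = max(yn, 0.0)
        if not (math.isfinite(xn) and math.isfinite(yn)):
            raise DivergenceError(f"non-finite iterate at step {t + 1}")
        if not (_STATE_LO <= xn <= _STATE_HI and _STATE_LO <= yn <= _STATE_HI):
            raise DivergenceError(
                f"iterate left [{_STATE_LO}, {_STATE_HI}] at step {t + 1}: "
                f"x={xn:.4g}, y={yn:.4g}"
            )
        if xn == 0.0 and yn == 0.0:
            raise DivergenceError(f"both species absorbed at 0 at step {t + 1}")
        x[t + 1], y[t + 1] = xn, yn
    return TimeSeriesSet(
        np.column_stack([x[p.transient:], y[p.transient:]]), ["X", "Y"]
    )


@dataclass
class CommunityModelParams:
    """Parameters of the S-species synthetic community.

    ``B[i, j]`` is the directed coupling of species i onto species j
    (diagonal ignored). Each species follows a clipped multiplicative
    logistic update -- the two-species map generalized to S species.
    Seasonality enters as a sinusoidal modulation of the growth rates,
    shared in phase across the whole community (the environment drives
    every species' demography through the same annual cycle); the series
    are observed through multiplicative lognormal noise. Species listed
    in ``rare_species_mask`` (0-based indices) are additionally thinned
    by Bernoulli dropout and scaled down, emulating zero-inflated rare
    taxa.
    """

    S: int
    B: np.ndarray
    r: np.ndarray
    seasonal_amplitude: float = 0.03
    seasonal_period: float = 26.0  # samples per year at biweekly sampling
    noise_sd: float = 0.01
    rare_species_mask: tuple[int, ...] = ()
    rare_dropout: float = 0.3
    rare_scale: float = 0.05
    rare_switch: float = 0.05  # per-step probability of absent<->present switch
    n_steps: int = 285
    seed: int = 0
    interacting_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.S < 2:
            raise ValueError("need at least 2 species")
        if self.B.shape != (self.S, self.S):
            raise ValueError(f"B must be {self.S}x{self.S}, got {self.B.shape}")
        if self.r.shape != (self.S,):
            raise ValueError(f"r must have length {self.S}")
        if not all(0 <= i < self.S for i in self.rare_species_mask):
            raise ValueError("rare_species_mask indices must lie in [0, S)")


def maizuru_like_params(seed: int = 0, S: int = 15, n_steps: int = 285) -> CommunityModelParams:
    """Default community emulating the Maizuru-Bay-style biweekly census.

    15 species, 285 time points. A strongly-coupled core of six species
    (the census' handful of dominant, strongly interacting taxa) sits in
    a wider web of weak couplings -- as in real communities, weak
    interactors greatly outnumber strong ones -- leaving two species
    truly uncoupled. Three species are zero-inflated rare taxa with
    persistent absence runs; the annual cycle forces every growth rate.
    All draws come from the one seed, so the ground truth is
    reproducible.
    """
    rng = np.random.default_rng(seed)
    B = np.zeros((S, S))
    core = list(range(3, 9))[: max(2, min(6, S - 2))]  # species 4..9, 1-based
    # a directed ring through the core: sparse coupling keeps each species
    # chaotic (dense reciprocal webs entrain the core onto near-periodic
    # orbits and erase the very signal the benchmark plants)
    ring = core + [core[0]]
    for i, j in zip(ring[:-1], ring[1:]):
        B[i, j] = rng.uniform(0.45, 0.6)
    # weak chain through most of the periphery; the last two stay uncoupled
    periphery = [i for i in range(S) if i not in core]
    weak = periphery[: max(0, len(periphery) - 2)]
    for i, j in zip(weak[:-1], weak[1:]):
        B[i, j] = rng.uniform(0.08, 0.15)
    r = rng.uniform(3.6, 3.9, size=S)
    rare_pool = [i for i in range(S) if i not in core]
    rare = tuple(int(i) for i in rng.choice(rare_pool, size=3, replace=False))
    return CommunityModelParams(
        S=S, B=B, r=r, rare_species_mask=rare, n_steps=n_steps, seed=seed
    )


def simulate_community(
    params: CommunityModelParams,
) -> tuple[TimeSeriesSet, GroundTruth]:
    """Simulate the community; returns the observed table and its ground truth.

    The latent state of each species is kept in [1e-6, 1] by clipping,
    which bounds the otherwise divergent multi-species map while
    preserving chaotic intrinsic dynamics. The shared annual sinusoid
    modulates every growth rate; observation is latent state times
    lognormal noise; rare species are scaled down and zeroed out by
    Bernoulli dropout.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    S, n = p.S, p.n_steps
    x = np.empty((n, S))
    x[0] = rng.uniform(0.2, 0.8, size=S)
    Bt = p.B.T  # row j: couplings onto species j
    for t in range(n - 1):
        rt = p.r * (
            1.0 + p.seasonal_amplitude * np.sin(2.0 * np.pi * t / p.seasonal_period)
        )
        nxt = x[t] * (rt - rt * x[t] - Bt @ x[t])
        if not np.all(np.isfinite(nxt)):
            raise DivergenceError(f"non-finite community state at step {t + 1}")
        x[t + 1] = np.clip(nxt, 1e-6, 1.0)

    obs = x.copy()
    if p.noise_sd > 0:
        obs = obs * rng.lognormal(0.0, p.noise_sd, size=(n, S))
    for i in p.rare_species_mask:
        # occupancy is a persistent two-state chain (mean run 1/rare_switch
        # samples), so rare taxa disappear for whole stretches of the record
        # rather than flickering; within presence runs an extra Bernoulli
        # dropout keeps the counts sporadic.
        present = np.empty(n, dtype=bool)
        present[0] = rng.random() < 0.5
        flips = rng.random(n - 1) < p.rare_switch
        for t in range(1, n):
            present[t] = present[t - 1] ^ flips[t - 1]
        keep = present & (rng.random(n) >= p.rare_dropout)
        obs[:, i] = obs[:, i] * keep * p.rare_scale

    names = [f"sp{i + 1}" for i in range(S)]
    mag = np.abs(p.B)
    np.fill_diagonal(mag, 0.0)
    interacting = [
        names[i]
        for i in range(S)
        if mag[i].max(initial=0.0) >= p.interacting_threshold
        or mag[:, i].max(initial=0.0) >= p.interacting_threshold
    ]
    ts = TimeSeriesSet(obs, names, dt_label="2 weeks")
    return ts, GroundTruth(p.B.copy(), interacting, p.interacting_threshold)


@dataclass
class VARParams:
    """Bivariate Gaussian first-order vector autoregression z_t = A z_{t-1} + e_t."""

    A: np.ndarray
    noise_cov: np.ndarray = field(default_factory=lambda: np.eye(2))
    n: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.A.shape != (2, 2) or self.noise_cov.shape != (2, 2):
            raise ValueError("A and noise_cov must be 2x2")
        if np.max(np.abs(np.linalg.eigvals(self.A))) >= 1.0:
            raise NonStationaryError("spectral radius of A must be < 1")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise_cov must be positive-definite")


def simulate_gaussian_var(params: VARParams) -> TimeSeriesSet:
    """Simulate the VAR(1); returns series "X" (index 0) and "Y" (index 1).

    The chain starts at the origin; its empirical lag-0 covariance
    converges to the stationary solution of Sigma = A Sigma A' + Q.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    chol = np.linalg.cholesky(p.noise_cov)
    eps = rng.standard_normal((p.n, 2)) @ chol.T
    z = np.empty((p.n, 2))
    z[0] = eps[0]
    A = p.A
    for t in range(1, p.n):
        z[t] = A @ z[t - 1] + eps[t]
    return TimeSeriesSet(z, ["X", "Y"])


def _quadratic_map(x: np.ndarray) -> np.ndarray:
    """Default nonlinear read-out for the lagged pair: the logistic hump."""
    return x * (1.0 - x)


def simulate_lagged_coupling(
    u0: int,
    n: int = 1000,
    noise_sd: float = 0.0,
    seed: int = 0,
    g=None,
    driver: str = "iid",
) -> tuple[TimeSeriesSet, int]:
    """Driver X and response Y(t) = g(X(t - u0)) + noise, with known lag.

    ``driver`` is ``"iid"`` (uniform noise, the default) or
    ``"logistic"`` (chaotic map, r=3.9). ``g`` defaults to the quadratic
    hump x(1-x) so the coupling is nonlinear; pass any vectorized
    callable (e.g. the identity) to change it. Returns the series and
    the planted lag.

    Beware the chaotic driver with the default read-out: g is then one
    step of the driver's own map up to scale, so the information-optimal
    lag is genuinely u0 - 1, not u0 -- a deterministic driver blurs "the"
    lag. The i.i.d. driver makes the planted lag uniquely identifiable.
    """
    if u0 <= 0:
        raise ValueError("planted lag u0 must be positive")
    if n <= u0 + 10:
        raise ValueError("n must exceed u0 + 10")
    rng = np.random.default_rng(seed)
    if driver == "iid":
        x = rng.uniform(0.0, 1.0, size=n)
    elif driver == "logistic":
        x = np.empty(n)
        x[0] = rng.uniform(0.2, 0.8)
        for t in range(n - 1):
            x[t + 1] = 3.9 * x[t] * (1.0 - x[t])
    else:
        raise ValueError(f"unknown driver {driver!r}")
    if g is None:
        g = _quadratic_map
    y = np.empty(n)
    y[:u0] = g(x[:u0])  # warm-up: undriven values, keeps lengths aligned
    y[u0:] = g(x[:-u0])
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return TimeSeriesSet(np.column_stack([x, y]), ["X", "Y"]), u0


_SCAN_METRICS = ("corr", "mi", "rho_x_to_y", "rho_y_to_x", "te_x_to_y", "te_y_to_x")


def phase_space_scan(
    beta_xy_grid,
    beta_yx_grid,
    metric: str,
    n_steps: int = 800,
    config=None,
    normalize: bool = False,
) -> np.ndarray:
    """Map one pairwise estimator over a grid of coupling strengths.

    For each (beta_xy, beta_yx) cell the coupled logistic map is simulated
    for ``n_steps`` and the requested metric evaluated; divergent cells
    are recorded as NaN, not fatal. Output shape is
    (len(beta_xy_grid), len(beta_yx_grid)). With ``normalize`` the finite
    entries are min-max rescaled to [0, 1].
    """
    from . import ccm as _ccm
    from . import estimators as _est

    metric = metric.lower()
    if metric not in _SCAN_METRICS:
        raise ValueError(f"metric must be one of {_SCAN_METRICS}")
    if config is None:
        config = _est.EstimatorConfig()
    out = np.full((len(beta_xy_grid), len(beta_yx_grid)), np.nan)
    for a, bxy in enumerate(beta_xy_grid):
        for b, byx in enumerate(beta_yx_grid):
            try:
                ts = simulate_coupled_logistic(
                    CoupledLogisticParams(beta_xy=bxy, beta_yx=byx, n_steps=n_steps)
                )
                x, y = ts.series("X"), ts.series("Y")
                if metric == "corr":
                    val = _est.pearson_corr(x, y)
                elif metric == "mi":
                    val = _est.mutual_information(x, y, u=0, config=config)
                elif metric == "te_x_to_y":
                    val = _est.transfer_entropy(x, y, config)
                elif metric == "te_y_to_x":
                    val = _est.transfer_entropy(y, x, config)
                elif metric == "rho_x_to_y":
                    val = _ccm.cross_map_skill(x, y, direction="x_to_y").rho
                else:
                    val = _ccm.cross_map_skill(x, y, direction="y_to_x").rho
                out[a, b] = val
            except DivergenceError:
                continue
    if normalize:
        finite = np.isfinite(out)
        if finite.any():
            lo, hi = out[finite].min(), out[finite].max()
            if hi > lo:
                out[finite] = (out[finite] - lo) / (hi - lo)
            else:
                out[finite] = 0.0
    return out
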