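"""Pairwise interaction matrices, dynamical networks, and alpha-diversity.

An interaction matrix holds one directed score per ordered species pair
(i, j): transfer entropy, CCM cross-map skill, mutual information or
linear correlation of species i toward species j. Matrices are min-max
normalized to [0, 1] (negatives floored at 0) for presentation and for
the diversity machinery.

*Effective* alpha-diversity at threshold theta counts the species that
retain at least one incident directed link of normalized strength >=
theta -- the model-inferred interacting species -- per time window;
*taxonomic* alpha is the observed species richness of the window. The
interaction threshold is chosen to maximize the agreement (correlation or
mutual information) between the two series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import ccm as _ccm
from . import estimators as _est
from .exceptions import InsufficientDataError, OifError, ZeroVarianceError
from .timeseries import TimeSeriesSet

__all__ = [
    "InteractionMatrix",
    "DynamicalNetworks",
    "DiversitySeries",
    "ThresholdSearchResult",
    "infer_interaction_matrix",
    "normalize_matrix",
    "dynamical_networks",
    "taxonomic_alpha",
    "effective_alpha",
    "diversity_series",
    "optimize_threshold",
]

METHODS = ("corr", "mi", "te", "ccm_rho")


@dataclass
class InteractionMatrix:
    """S x S directed pairwise scores; entry (i, j) is the score of i -> j.

    The diagonal is fixed at 0 and excluded from normalization and from
    diversity counts. ``delay_used`` records the source-target delay per
    pair (or one global value) for the delay-aware methods.
    """

    values: np.ndarray
    method: str
    species_names: list[str]
    normalized: bool = False
    delay_used: np.ndarray | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        S = len(self.species_names)
        if self.values.shape != (S, S):
            raise ValueError(f"matrix must be {S}x{S}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        np.fill_diagonal(self.values, 0.0)

    @property
    def S(self) -> int:
        return len(self.species_names)

    def offdiag(self) -> np.ndarray:
        """Off-diagonal entries as a flat array."""
        mask = ~np.eye(self.S, dtype=bool)
        return self.values[mask]


@dataclass
class DynamicalNetworks:
    """Interaction matrices inferred over a sequence of time windows.

    ``windows`` holds (start, stop) half-open row ranges; ``matrices`` the
    per-window :class:`InteractionMatrix`, or None where inference failed.
    """

    windows: list[tuple[int, int]]
    matrices: list[InteractionMatrix | None]
    g: int
    window_mode: str
    method: str


@dataclass
class DiversitySeries:
    """Per-window effective and taxonomic alpha-diversity."""

    times: np.ndarray
    alpha_eff: np.ndarray
    alpha_tax: np.ndarray
    theta: float
    g: int
    window_mode: str


@dataclass
class ThresholdSearchResult:
    """The threshold maximizing agreement between effective and taxonomic alpha."""

    theta_star: float
    criterion: str
    score_curve: np.ndarray
    theta_grid: np.ndarray


def _pair_score(
    x: np.ndarray, y: np.ndarray, method: str, config: _est.EstimatorConfig, u: int, emb
) -> float:
    if method == "corr":
        return _est.pearson_corr(x, y)
    if method == "mi":
        return _est.mutual_information(x, y, u=u, config=config)
    if method == "te":
        cfg = _replace_u(config, u)
        return _est.transfer_entropy(x, y, cfg)
    # ccm_rho: evidence that the source causes the target
    return _ccm.cross_map_skill(x, y, "x_to_y", E=emb.E, tau=emb.tau, theiler=emb.theiler).rho


def _replace_u(config: _est.EstimatorConfig, u: int) -> _est.EstimatorConfig:
    import dataclasses

    return dataclasses.replace(config, u=int(u))


def infer_interaction_matrix(
    ts: TimeSeriesSet,
    method: str = "te",
    config: _est.EstimatorConfig | None = None,
    delay_policy: str = "fixed",
    u_range=range(1, 11),
    embedding: _ccm.EmbeddingConfig | None = None,
) -> InteractionMatrix:
    """Fill all ordered species pairs with the chosen estimator.

    ``delay_policy`` (delay-aware methods "te" and "mi" only):

    * ``"fixed"``   -- use ``config.u`` for every pair;
    * ``"per_pair"`` -- MI-optimal delay per ordered pair;
    * ``"global_opt"`` -- one delay for all pairs, the u maximizing the
      mean MI profile across pairs (the community-wide optimum).

    Pairs involving a zero-variance series score 0 with a warning (such
    species carry too little uncertainty to transfer information), not an
    error.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if delay_policy not in ("fixed", "per_pair", "global_opt"):
        raise ValueError("delay_policy must be fixed | per_pair | global_opt")
    if ts.n_vars < 2:
        raise ValueError("need at least 2 species")
    config = config or _est.EstimatorConfig()
    embedding = embedding or _ccm.EmbeddingConfig()
    S = ts.n_vars
    vals = np.zeros((S, S))
    delays = np.full((S, S), int(config.u), dtype=int)
    u_list = [int(u) for u in u_range]

    global_u = config.u
    if delay_policy == "global_opt" and method in ("te", "mi"):
        profiles = []
        for i in range(S):
            for j in range(S):
                if i == j:
                    continue
                try:
                    res = _est.optimal_delay(ts.values[:, i], ts.values[:, j], u_list, config)
                    profiles.append(res.mi_profile)
                except (ZeroVarianceError, InsufficientDataError):
                    continue
        if not profiles:
            raise ZeroVarianceError("no species pair admits a delay search")
        mean_profile = np.nanmean(np.vstack(profiles), axis=0)
        global_u = u_list[int(np.nanargmax(mean_profile))]

    for i in range(S):
        for j in range(S):
            if i == j:
                continue
            x, y = ts.values[:, i], ts.values[:, j]
            u = global_u
            try:
                if delay_policy == "per_pair" and method in ("te", "mi"):
                    u = _est.optimal_delay(x, y, u_list, config).u_star
                vals[i, j] = _pair_score(x, y, method, config, u, embedding)
                delays[i, j] = u
            except (ZeroVarianceError, InsufficientDataError) as err:
                warnings.warn(
                    f"pair {ts.names[i]}->{ts.names[j]} scored 0: {err}", stacklevel=2
                )
                vals[i, j] = 0.0
    delay_used: np.ndarray | int | None
    if method in ("te", "mi"):
        delay_used = delays if delay_policy == "per_pair" else int(global_u)
    else:
        delay_used = None
    return InteractionMatrix(vals, method, list(ts.names), normalized=False, delay_used=delay_used)


def normalize_matrix(m: InteractionMatrix) -> InteractionMatrix:
    """Min-max rescale off-diagonal entries to [0, 1], flooring negatives at 0.

    NaN entries (failed windows/pairs) are ignored by the rescaling and
    preserved. An all-equal matrix maps to all-zeros with a warning.
    """
    vals = m.values.copy()
    mask = ~np.eye(m.S, dtype=bool)
    off = vals[mask]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise OifError("cannot normalize an all-missing matrix")
    off = np.where(np.isfinite(off), np.maximum(off, 0.0), off)
    lo = np.nanmin(np.where(np.isfinite(off), off, np.nan))
    hi = np.nanmax(np.where(np.isfinite(off), off, np.nan))
    if hi > lo:
        off = (off - lo) / (hi - lo)
    else:
        warnings.warn("all off-diagonal entries equal; normalized matrix is all zeros")
        off = np.where(np.isfinite(off), 0.0, off)
    vals[mask] = off
    return InteractionMatrix(
        vals, m.method, list(m.species_names), normalized=True, delay_used=m.delay_used
    )


def dynamical_networks(
    ts: TimeSeriesSet,
    method: str = "te",
    config: _est.EstimatorConfig | None = None,
    g: int = 30,
    window_mode: str = "expanding",
    step: int = 1,
    **infer_kwargs,
) -> DynamicalNetworks:
    """Infer one interaction matrix per time window at resolution g.

    ``expanding`` (default): windows [0, t) for t = g, g+step, ..., n --
    the network estimated "until the selected time" with incremental
    data. ``sliding``: fixed-length windows [t-g, t). A window where
    inference fails yields a None entry, not a crash. ``g`` is the
    minimum number of points for robust pdf inference (default 30).
    """
    if window_mode not in ("expanding", "sliding"):
        raise ValueError("window_mode must be 'expanding' or 'sliding'")
    n = ts.length
    if n < g:
        raise InsufficientDataError(f"series length {n} below resolution g={g}")
    ends = list(range(g, n + 1, step))
    if ends[-1] != n:
        ends.append(n)
    windows = [(0 if window_mode == "expanding" else t - g, t) for t in ends]
    matrices: list[InteractionMatrix | None] = []
    for start, stop in windows:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                matrices.append(
                    infer_interaction_matrix(
                        ts.window(start, stop), method, config, **infer_kwargs
                    )
                )
            except OifError:
                matrices.append(None)
    return DynamicalNetworks(windows, matrices, g, window_mode, method)


def taxonomic_alpha(ts: TimeSeriesSet, window: tuple[int, int] | None = None) -> int:
    """Observed species richness: species with any strictly positive abundance."""
    sub = ts if window is None else ts.window(*window)
    return int(np.sum(np.any(sub.values > 0, axis=0)))


def effective_alpha(m: InteractionMatrix, theta: float, rule: str = "either") -> int:
    """Count model-inferred interacting species at threshold theta.

    A species counts if it has at least one incident directed link
    (incoming, outgoing, or either, per ``rule``) with normalized value
    >= theta; zero-valued entries are absent links and never count, so at
    theta=0 the count is the number of species with any nonzero link.
    """
    if not m.normalized:
        raise ValueError("effective_alpha requires a normalized matrix")
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    if rule not in ("either", "in", "out"):
        raise ValueError("rule must be either | in | out")
    vals = m.values
    link = np.isfinite(vals) & (vals > 0.0) & (vals >= theta)
    np.fill_diagonal(link, False)
    has_out = link.any(axis=1)
    has_in = link.any(axis=0)
    if rule == "out":
        keep = has_out
    elif rule == "in":
        keep = has_in
    else:
        keep = has_out | has_in
    return int(keep.sum())


def diversity_series(
    dyn: DynamicalNetworks, ts: TimeSeriesSet, theta: float, rule: str = "either"
) -> DiversitySeries:
    """Effective and taxonomic alpha per window of a dynamical network.

    Windows whose matrix is missing are dropped. Each window's matrix is
    normalized before thresholding.
    """
    times, a_eff, a_tax = [], [], []
    for (start, stop), m in zip(dyn.windows, dyn.matrices):
        if m is None:
            continue
        mn = m if m.normalized else normalize_matrix(m)
        times.append(stop)
        a_eff.append(effective_alpha(mn, theta, rule))
        a_tax.append(taxonomic_alpha(ts, (start, stop)))
    return DiversitySeries(
        np.array(times), np.array(a_eff), np.array(a_tax), theta, dyn.g, dyn.window_mode
    )


def optimize_threshold(
    dyn: DynamicalNetworks,
    ts: TimeSeriesSet,
    theta_grid,
    criterion: str = "corr",
    rule: str = "either",
) -> ThresholdSearchResult:
    """Pick the threshold whose effective-alpha series best tracks taxonomic alpha.

    The candidate grid must include 0.2 and 0.3 (the reference operating
    points for cross-map skill and transfer entropy). For each theta the
    effective-alpha series is scored against the taxonomic series at zero
    lag by Pearson correlation or plug-in MI on the integer counts; a
    constant effective series scores -inf (corr) or 0 (MI). Smallest
    theta wins ties.
    """
    if criterion not in ("corr", "mi"):
        raise ValueError("criterion must be 'corr' or 'mi'")
    grid = np.asarray(sorted(float(t) for t in theta_grid))
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise ValueError("theta_grid must lie within [0, 1]")
    for required in (0.2, 0.3):
        if not np.any(np.isclose(grid, required)):
            raise ValueError(f"theta_grid must include {required}")
    n_windows = sum(m is not None for m in dyn.matrices)
    if n_windows < 5:
        raise InsufficientDataError("need at least 5 windows with matrices")

    # normalize once, count per theta
    norm = [normalize_matrix(m) if (m is not None and not m.normalized) else m for m in dyn.matrices]
    a_tax = np.array(
        [taxonomic_alpha(ts, w) for w, m in zip(dyn.windows, norm) if m is not None]
    )
    scores = np.empty(grid.size)
    mi_cfg = _est.EstimatorConfig(
        r=1.0, standardize=False, mi_correction="none", log_base=2.0
    )
    for idx, theta in enumerate(grid):
        a_eff = np.array(
            [effective_alpha(m, float(theta), rule) for m in norm if m is not None]
        )
        try:
            if criterion == "corr":
                scores[idx] = _est.pearson_corr(a_eff.astype(float), a_tax.astype(float))
            else:
                scores[idx] = _est.mutual_information(
                    a_eff.astype(float), a_tax.astype(float), u=0, config=mi_cfg
                )
        except (ZeroVarianceError, InsufficientDataError):
            scores[idx] = -np.inf if criterion == "corr" else 0.0
    best = int(np.argmax(scores))  # argmax takes the first (smallest theta) on ties
    return ThresholdSearchResult(float(grid[best]), criterion, scores, grid)
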