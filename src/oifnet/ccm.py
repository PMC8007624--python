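"""Convergent cross mapping (CCM).

State-space reconstruction by time-delay embedding (Takens), simplex
projection with E+1 exponentially distance-weighted nearest neighbors,
cross-map skill rho as the Pearson correlation between cross-estimated
and observed values, and convergence profiles over library length L.

Direction convention: evidence that X causes Y is the skill with which X
can be estimated from Y's shadow manifold (the caused variable's
reconstruction encodes the causer). ``cross_map_skill(x, y, "x_to_y")``
therefore embeds y and cross-estimates x.

The predictee's own time index is always excluded from the neighbor pool
(a zero-distance self-match would make any in-library cross-map trivially
perfect); a Theiler window ``theiler`` additionally excludes neighbors
within that many samples of the prediction time. Everything here is
deterministic: libraries are the first L embedded points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import SeriesTooShortError, ZeroVarianceError
from .estimators import pearson_corr

__all__ = [
    "EmbeddingConfig",
    "ShadowManifold",
    "CrossMapResult",
    "embed",
    "simplex_cross_map",
    "cross_map_skill",
    "convergence_profile",
    "select_embedding_dim",
]


@dataclass
class EmbeddingConfig:
    """Embedding dimension E, lag tau, Theiler exclusion, library length L.

    A series of length n yields n - (E-1)*tau embedded vectors; ``L=None``
    means "use all of them". Simplex projection uses E+1 neighbors, the
    minimum bounding simplex in E dimensions.
    """

    E: int = 2
    tau: int = 1
    theiler: int = 0
    L: int | None = None

    def __post_init__(self) -> None:
        if self.E < 1 or self.tau < 1 or self.theiler < 0:
            raise ValueError("require E >= 1, tau >= 1, theiler >= 0")


@dataclass
class ShadowManifold:
    """Lagged-coordinate reconstruction of one series.

    Point i is (x(t_i), x(t_i - tau), ..., x(t_i - (E-1) tau)) and
    ``time_index[i] = t_i`` (0-based, strictly increasing).
    """

    points: np.ndarray
    time_index: np.ndarray
    source_name: str = ""
    tau: int = 1

    @property
    def E(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class CrossMapResult:
    """Cross-map skill and the aligned prediction/observation pair."""

    rho: float
    predicted: np.ndarray
    observed: np.ndarray
    direction: str
    L: int


def embed(x: np.ndarray, E: int, tau: int = 1, name: str = "") -> ShadowManifold:
    """Time-delay embedding of a series into E dimensions with lag tau."""
    x = np.asarray(x, dtype=float)
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be >= 1")
    n = x.size
    span = (E - 1) * tau
    if n < span + 1:
        raise SeriesTooShortError(
            f"series of length {n} too short for E={E}, tau={tau}"
        )
    t = np.arange(span, n)
    points = np.column_stack([x[t - j * tau] for j in range(E)])
    return ShadowManifold(points, t, name, tau)


def _simplex_weights(d: np.ndarray) -> np.ndarray:
    """Exponential distance weights w_i = exp(-d_i / d_1), normalized.

    If the nearest distance is zero, the zero-distance neighbors share
    the weight equally (the defined limit of the exponential rule).
    """
    d1 = d[0]
    if d1 == 0.0:
        w = (d == 0.0).astype(float)
    else:
        w = np.exp(-d / d1)
    return w / w.sum()


def simplex_cross_map(
    source_manifold: ShadowManifold,
    target: np.ndarray,
    L: int | None = None,
    theiler: int = 0,
) -> CrossMapResult:
    """Cross-estimate ``target`` from a shadow manifold by simplex projection.

    For each embedded point, the E+1 nearest library points (Euclidean
    distance; library = the first L points; neighbors within ``theiler``
    samples of the prediction time, and the point itself, excluded) vote
    for the target's contemporaneous value with exponential distance
    weights. Skill is the Pearson correlation between the cross-estimated
    and observed target values.
    """
    target = np.asarray(target, dtype=float)
    M = source_manifold
    n_pts = len(M)
    E = M.E
    if L is None:
        L = n_pts
    if L < E + 2:
        raise SeriesTooShortError(f"library L={L} too small; need at least E+2={E + 2}")
    if L > n_pts:
        raise SeriesTooShortError(f"library L={L} exceeds {n_pts} embedded points")
    if target.size <= int(M.time_index[-1]):
        raise ValueError("target series shorter than the manifold's time span")

    lib_pts = M.points[:L]
    lib_t = M.time_index[:L]
    dist = cdist(M.points, lib_pts)
    # temporal exclusion: self plus the Theiler radius
    gap = np.abs(M.time_index[:, None] - lib_t[None, :])
    dist[gap <= theiler] = np.inf

    k = E + 1
    preds = np.empty(n_pts)
    for i in range(n_pts):
        row = dist[i]
        idx = np.argpartition(row, k - 1)[:k]
        idx = idx[np.argsort(row[idx], kind="stable")]
        d = row[idx]
        if not np.all(np.isfinite(d)):
            raise SeriesTooShortError(
                "fewer than E+1 admissible neighbors; reduce theiler or grow L"
            )
        w = _simplex_weights(d)
        preds[i] = w @ target[lib_t[idx]]
    obs = target[M.time_index]
    rho = pearson_corr(preds, obs)
    return CrossMapResult(rho, preds, obs, direction="", L=L)


def cross_map_skill(
    x: np.ndarray,
    y: np.ndarray,
    direction: str,
    E: int | None = None,
    tau: int = 1,
    L: int | None = None,
    theiler: int = 0,
    E_range=range(1, 11),
) -> CrossMapResult:
    """CCM skill for one causal direction.

    ``direction="x_to_y"`` scores the evidence that X causes Y: it embeds
    y and cross-estimates x from M_Y. With ``E=None`` the embedding
    dimension is chosen by univariate simplex self-prediction of the
    embedded (manifold) series over ``E_range``.
    """
    if direction not in ("x_to_y", "y_to_x"):
        raise ValueError("direction must be 'x_to_y' or 'y_to_x'")
    manifold_src, tgt = (y, x) if direction == "x_to_y" else (x, y)
    if E is None:
        E = select_embedding_dim(np.asarray(manifold_src, float), E_range, tau)
    M = embed(np.asarray(manifold_src, float), E, tau)
    res = simplex_cross_map(M, np.asarray(tgt, float), L=L, theiler=theiler)
    res.direction = direction
    return res


def convergence_profile(
    x: np.ndarray,
    y: np.ndarray,
    config: EmbeddingConfig,
    L_grid,
) -> dict[str, np.ndarray]:
    """Cross-map skill as a function of library length, both directions.

    Libraries are the first L embedded points (deterministic). Returns
    ``{"x_to_y": rho_per_L, "y_to_x": rho_per_L}`` aligned with L_grid.
    Convergence -- rho rising to a stable value as L grows -- is the CCM
    signature of causation.
    """
    L_list = [int(L) for L in L_grid]
    if min(L_list) < 30:
        raise ValueError("library lengths below 30 points are unreliable")
    out = {}
    for direction in ("x_to_y", "y_to_x"):
        rhos = np.empty(len(L_list))
        for i, L in enumerate(L_list):
            rhos[i] = cross_map_skill(
                x, y, direction, E=config.E, tau=config.tau, L=L, theiler=config.theiler
            ).rho
        out[direction] = rhos
    return out


def select_embedding_dim(x: np.ndarray, E_range=range(1, 11), tau: int = 1) -> int:
    """Choose E by univariate simplex self-prediction (one step ahead).

    For each candidate E the series is embedded, each point's next value
    x(t+1) is forecast from its E+1 nearest neighbors (self excluded),
    and the skill is the correlation between forecasts and outcomes. The
    smallest E attaining the maximum skill wins; candidates that cannot
    be embedded raise, per the series-too-short contract, only if no
    candidate fits.
    """
    x = np.asarray(x, dtype=float)
    E_list = sorted(int(E) for E in E_range)
    if not E_list:
        raise ValueError("E_range must be non-empty")
    best_E, best_skill = None, -np.inf
    last_err: Exception | None = None
    for E in E_list:
        try:
            M = embed(x, E, tau)
            usable = M.time_index < x.size - 1  # need x(t+1) to exist
            pts = M.points[usable]
            t_idx = M.time_index[usable]
            if len(pts) < E + 2:
                raise SeriesTooShortError("too few points for self-prediction")
            dist = cdist(pts, pts)
            np.fill_diagonal(dist, np.inf)
            k = E + 1
            preds = np.empty(len(pts))
            for i in range(len(pts)):
                idx = np.argpartition(dist[i], k - 1)[:k]
                idx = idx[np.argsort(dist[i][idx], kind="stable")]
                w = _simplex_weights(dist[i][idx])
                preds[i] = w @ x[t_idx[idx] + 1]
            skill = pearson_corr(preds, x[t_idx + 1])
        except (SeriesTooShortError, ZeroVarianceError) as err:  # degenerate E: skip
            last_err = err
            continue
        if skill > best_skill:
            best_E, best_skill = E, skill
    if best_E is None:
        raise last_err if last_err is not None else SeriesTooShortError(
            "no candidate embedding dimension fits the series"
        )
    return best_E
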