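"""Ulam-type discretization of the switched dynamics into a finite Markov chain.

The cover domain [0, 1]^n is partitioned into hypercube cells of width
``delta``; cells whose center has total cover > 1 are rejected as unphysical.
Each accepted cell is a chain state with a fire probability evaluated at its
center.  Two conditional transition matrices capture the deterministic no-fire
and fire maps (entry (i, j) = proportion of cell i mapping into cell j); by
total probability the chain's transition matrix is their state-dependent
mixture

    T[i, .] = (1 - p_i) T_nf[i, .] + p_i T_f[i, .]

whose stationary distribution w (w T = w) approximates the long-run occupancy
of tree-cover states — the quantity whose shape (unimodal vs bimodal) the
model is built to explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model_core import (
    ConfigurationError,
    ModelConfig,
    SimplexError,
    effective_update_matrix,
    fire_probability,
    effective_cover,
)
from .statistics import CoverHistogram

__all__ = [
    "StateGrid",
    "DiscretizedChain",
    "ErgodicityReport",
    "NonUniqueStationaryWarning",
    "build_grid",
    "build_conditional_transitions",
    "mix_transitions",
    "stationary_distribution",
    "ergodicity_check",
    "cover_distribution",
    "discretize",
]


class NonUniqueStationaryWarning(UserWarning):
    """The chain has several closed classes; the stationary vector is not unique."""


@dataclass(frozen=True, eq=False)
class StateGrid:
    """Accepted hypercube cells of a uniform partition of the cover simplex.

    Cells are ordered lexicographically by multi-index; ``centers[i]`` is the
    coordinate vector of the center of state i.
    """

    n: int
    delta: float
    k: int
    indices: np.ndarray
    centers: np.ndarray

    @property
    def N(self) -> int:
        return self.centers.shape[0]

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Map points in [0, 1]^n to accepted-state row numbers.

        Cells are half-open [l, l+delta) with the last cell closed.  Points
        landing in a rejected cell (possible near the simplex face) are
        assigned to the nearest accepted cell center.
        """
        pts = np.atleast_2d(points)
        idx = np.clip(np.floor(pts / self.delta).astype(int), 0, self.k - 1)
        flat = np.ravel_multi_index(idx.T, (self.k,) * self.n)
        rows = self._row_of_flat[flat]
        missing = rows < 0
        if np.any(missing):
            _, nearest = self._tree.query(pts[missing])
            rows[missing] = nearest
        return rows

    def __post_init__(self) -> None:
        flat = np.ravel_multi_index(self.indices.T, (self.k,) * self.n)
        row_of_flat = np.full(self.k**self.n, -1, dtype=int)
        row_of_flat[flat] = np.arange(self.N)
        object.__setattr__(self, "_row_of_flat", row_of_flat)
        object.__setattr__(self, "_tree", cKDTree(self.centers))


def build_grid(n: int, delta: float) -> StateGrid:
    """Enumerate the accepted cells of an n-dimensional partition of width delta.

    ``1/delta`` must be an integer; acceptance is by the center test
    (sum of center coordinates <= 1), consistent with evaluating the fire
    probability at cell centers.
    """
    if n < 1:
        raise ConfigurationError(f"dimension must be >= 1, got {n}")
    k = round(1.0 / delta)
    if k < 1 or abs(k * delta - 1.0) > 1e-9:
        raise ConfigurationError(f"bin width {delta} does not divide [0, 1] evenly")
    axes = [np.arange(k)] * n
    mesh = np.meshgrid(*axes, indexing="ij")
    indices = np.stack([m.ravel() for m in mesh], axis=1)  # lexicographic
    centers = (indices + 0.5) * delta
    keep = centers.sum(axis=1) <= 1.0 + 1e-12
    return StateGrid(n=n, delta=delta, k=k, indices=indices[keep], centers=centers[keep])


def _affine_map(config: ModelConfig, fired: bool) -> tuple[np.ndarray, np.ndarray]:
    """The one-year map x -> M x + b under a constant fire status."""
    M = effective_update_matrix(config, fired)
    b = np.zeros(config.n)
    b[0] = config.recruitment.a
    return M, b


def _exact_transitions_1d(grid: StateGrid, c: float, d: float) -> sp.csr_matrix:
    """Exact cell-to-cell transitions of the monotone scalar map x -> c x + d.

    The image of each cell is an interval; row entries are the normalized
    overlap lengths with destination cells.
    """
    k, delta = grid.k, grid.delta
    rows, cols, vals = [], [], []
    for i in range(k):
        lo = c * (i * delta) + d
        hi = c * ((i + 1) * delta) + d
        if hi - lo < 1e-15:  # map collapses the cell to a point
            j = int(grid.locate(np.array([[min(max(lo, 0.0), 1.0)]]))[0])
            rows.append(i)
            cols.append(j)
            vals.append(1.0)
            continue
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise SimplexError(f"cell {i} maps outside [0, 1]: [{lo}, {hi}]")
        j_lo = min(int(lo / delta), k - 1)
        j_hi = min(int((hi - 1e-15) / delta), k - 1)
        length = hi - lo
        for j in range(j_lo, j_hi + 1):
            overlap = min(hi, (j + 1) * delta) - max(lo, j * delta)
            if overlap > 0:
                rows.append(i)
                cols.append(j)
                vals.append(overlap / length)
    return sp.csr_matrix((vals, (rows, cols)), shape=(k, k))


def _sampled_transitions(
    grid: StateGrid, M: np.ndarray, b: np.ndarray, samples_per_axis: int
) -> sp.csr_matrix:
    """Ulam transitions estimated from a regular sub-grid of points per cell."""
    m = samples_per_axis
    offs = (np.arange(m) + 0.5) / m * grid.delta
    mesh = np.meshgrid(*([offs] * grid.n), indexing="ij")
    offsets = np.stack([o.ravel() for o in mesh], axis=1)  # (m^n, n)
    n_pts = offsets.shape[0]
    rows, cols, vals = [], [], []
    weight = 1.0 / n_pts
    for i in range(grid.N):
        base = grid.indices[i] * grid.delta
        pts = base + offsets
        imgs = pts @ M.T + b
        if imgs.min() < -1e-9 or imgs.max() > 1 + 1e-9:
            raise SimplexError(f"cell {i} maps materially outside [0, 1]^n")
        dest = grid.locate(np.clip(imgs, 0.0, 1.0))
        js, counts = np.unique(dest, return_counts=True)
        rows.extend([i] * js.size)
        cols.extend(js.tolist())
        vals.extend((counts * weight).tolist())
    return sp.csr_matrix((vals, (rows, cols)), shape=(grid.N, grid.N))


def build_conditional_transitions(
    grid: StateGrid, config: ModelConfig, samples_per_axis: int = 5
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Row-stochastic transition matrices of the no-fire and fire maps.

    For n=1 the affine maps are monotone, so transitions are computed exactly
    from interval overlaps; for n>1 they are estimated by mapping a regular
    sub-grid of ``samples_per_axis**n`` points per cell.
    """
    out = []
    for fired in (False, True):
        M, b = _affine_map(config, fired)
        if grid.n == 1:
            out.append(_exact_transitions_1d(grid, float(M[0, 0]), float(b[0])))
        else:
            out.append(_sampled_transitions(grid, M, b, samples_per_axis))
    return out[0], out[1]


def mix_transitions(T_nf, T_f, p_state) -> sp.csr_matrix:
    """State-dependent mixture T[i,.] = (1-p_i) T_nf[i,.] + p_i T_f[i,.]."""
    p = np.asarray(p_state, dtype=float).ravel()
    T_nf = sp.csr_matrix(T_nf)
    T_f = sp.csr_matrix(T_f)
    if T_nf.shape != T_f.shape or T_nf.shape[0] != p.size:
        raise ValueError("transition matrices and p_state must be conformable")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_state entries must lie in [0, 1]")
    D_nf = sp.diags(1.0 - p)
    D_f = sp.diags(p)
    return (D_nf @ T_nf + D_f @ T_f).tocsr()


def _direct_solve(T: np.ndarray) -> np.ndarray:
    """Solve w (T - I) = 0 with the last equation replaced by normalization."""
    N = T.shape[0]
    A = T.T - np.eye(N)
    A[-1, :] = 1.0
    b = np.zeros(N)
    b[-1] = 1.0
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        w, *_ = np.linalg.lstsq(A, b, rcond=None)
    w = np.clip(w, 0.0, None)
    return w / w.sum()


def stationary_distribution(
    T,
    tol: float = 1e-13,
    maxiter: int = 1_000_000,
    method: str = "power",
) -> np.ndarray:
    """Stationary vector w of a row-stochastic matrix (w T = w, w >= 0, sum 1).

    Power iteration from the uniform vector, with a direct linear solve as
    fallback and as the ``method="direct"`` route.  If the chain has several
    closed classes the stationary vector is not unique: a
    :class:`NonUniqueStationaryWarning` is issued and the limit from the
    uniform start is returned.
    """
    T = sp.csr_matrix(T)
    N = T.shape[0]
    rows = np.asarray(T.sum(axis=1)).ravel()
    if np.any(np.abs(rows - 1.0) > 1e-8):
        raise ValueError("T is not row-stochastic")
    report = ergodicity_check(T)
    if report.closed_classes > 1:
        warnings.warn(
            f"chain has {report.closed_classes} closed classes; "
            "stationary distribution is not unique (returning uniform-start limit)",
            NonUniqueStationaryWarning,
        )
    if method == "direct":
        return _direct_solve(T.toarray())
    TT = T.T.tocsr()
    w = np.full(N, 1.0 / N)
    for it in range(maxiter):
        w_new = TT @ w
        s = w_new.sum()
        if s <= 0:
            raise RuntimeError("power iteration lost all mass (invalid T)")
        w_new /= s
        diff = np.abs(w_new - w).sum()
        w = w_new
        if diff < tol:
            break
    else:
        w = _direct_solve(T.toarray())
    resid = np.abs(TT @ w - w).sum()
    if resid > 1e-10:
        w = _direct_solve(T.toarray())
        resid = np.abs(TT @ w - w).sum()
        if resid > 1e-10:
            raise RuntimeError(
                f"stationary solver failed to converge (residual {resid:.3g})"
            )
    return w


@dataclass(frozen=True)
class ErgodicityReport:
    irreducible: bool
    aperiodic: bool
    closed_classes: int
    period: int


def _class_period(T: sp.csr_matrix, nodes: np.ndarray) -> int:
    """Period of a communicating class: gcd of cycle lengths via BFS levels."""
    sub = T[nodes][:, nodes].tocsr()
    if np.any(sub.diagonal() > 0):
        return 1
    m = nodes.size
    level = np.full(m, -1, dtype=int)
    level[0] = 0
    queue = [0]
    g = 0
    indptr, indices = sub.indptr, sub.indices
    while queue:
        u = queue.pop()
        for v in indices[indptr[u] : indptr[u + 1]]:
            if level[v] < 0:
                level[v] = level[u] + 1
                queue.append(v)
            else:
                g = np.gcd(g, level[u] + 1 - level[v])
    return int(abs(g)) if g != 0 else 1


def ergodicity_check(T) -> ErgodicityReport:
    """Irreducibility and aperiodicity of the positive-entry digraph of T."""
    T = sp.csr_matrix(T)
    n_comp, labels = connected_components(T > 0, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        nodes = np.nonzero(labels == c)[0]
        targets = labels[T[nodes].tocoo().col]
        if np.all(targets == c):
            closed.append(nodes)
    irreducible = n_comp == 1
    # period of the recurrent behaviour: examined on the closed class(es)
    periods = [_class_period(T, nodes) for nodes in closed]
    period = int(np.gcd.reduce(periods)) if periods else 1
    return ErgodicityReport(
        irreducible=irreducible,
        aperiodic=all(p == 1 for p in periods),
        closed_classes=len(closed),
        period=period,
    )


@dataclass(frozen=True, eq=False)
class DiscretizedChain:
    """Grid, fire probabilities, conditional/mixed transitions and stationary w.

    ``state_covers[i]`` is the vegetation cover of state i's center — the sum
    over the fire model's cover mask (all classes when no mask is set).
    """

    grid: StateGrid
    p_state: np.ndarray
    state_covers: np.ndarray
    T_nf: sp.csr_matrix
    T_f: sp.csr_matrix
    T: sp.csr_matrix
    w: np.ndarray


def discretize(
    config: ModelConfig, delta: float = 0.01, samples_per_axis: int = 5
) -> DiscretizedChain:
    """Build the full discretized chain of a model configuration.

    Deterministic (seed-independent): the chain depends only on the maps, the
    fire-probability feedback and the grid resolution.
    """
    grid = build_grid(config.n, delta)
    covers = np.array(
        [effective_cover(center, config.fire) for center in grid.centers]
    )
    p_state = fire_probability(covers, config.fire)
    T_nf, T_f = build_conditional_transitions(grid, config, samples_per_axis)
    T = mix_transitions(T_nf, T_f, p_state)
    w = stationary_distribution(T)
    return DiscretizedChain(
        grid=grid, p_state=p_state, state_covers=covers, T_nf=T_nf, T_f=T_f, T=T, w=w
    )


def cover_distribution(chain: DiscretizedChain, bin_width: float = 0.1) -> CoverHistogram:
    """Aggregate the stationary mass by vegetation cover of the state centers.

    Warns (without losing mass) when the bin width is not a multiple of the
    grid resolution, in which case cells straddle bin boundaries.
    """
    ratio = bin_width / chain.grid.delta
    if abs(ratio - round(ratio)) > 1e-9:
        warnings.warn(
            f"bin width {bin_width} is not a multiple of grid delta "
            f"{chain.grid.delta}; rebinning by cell centers",
            UserWarning,
        )
    return CoverHistogram.from_values(chain.state_covers, bin_width, weights=chain.w)
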