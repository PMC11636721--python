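"""Linear operators with exact adjoints.

Everything the solver touches is expressed through :class:`LinearMap`: the
tomographic forward projector, the discrete image gradient used by the TV
penalty, row-blocks of a partitioned measurement operator, and the random
row-subsampling views used to cheapen the dual-residual estimate.  Adjoint
exactness matters here: primal-dual convergence theory assumes ``A*`` is the
true Hilbert adjoint of ``A``, so every shipped map is either matrix-backed
(adjoint = transpose) or hand-paired with its exact discrete adjoint.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LinearMap",
    "MatrixMap",
    "BlockRowMap",
    "RowSubsetView",
    "NormEstimate",
    "apply",
    "adjoint",
    "estimate_norm",
    "make_grad2d",
    "make_parallel_projector",
    "row_subset",
]


class LinearMap:
    """A bounded linear operator between two (finite) real vector spaces.

    Parameters
    ----------
    domain_shape, range_shape
        Array shapes of inputs and outputs.  Shapes are frozen at
        construction.
    """

    def __init__(self, domain_shape: tuple[int, ...], range_shape: tuple[int, ...]):
        self._domain_shape = tuple(int(s) for s in domain_shape)
        self._range_shape = tuple(int(s) for s in range_shape)

    @property
    def domain_shape(self) -> tuple[int, ...]:
        return self._domain_shape

    @property
    def range_shape(self) -> tuple[int, ...]:
        return self._range_shape

    @property
    def domain_size(self) -> int:
        return int(np.prod(self._domain_shape))

    @property
    def range_size(self) -> int:
        return int(np.prod(self._range_shape))

    # subclasses implement these two
    def _apply(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _adjoint(self, y: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Return ``A x``."""
        x = np.asarray(x, dtype=float)
        if x.shape != self._domain_shape:
            raise ValueError(
                f"apply: expected domain shape {self._domain_shape}, got {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("apply: input contains non-finite entries")
        return self._apply(x)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """Return ``A* y``."""
        y = np.asarray(y, dtype=float)
        if y.shape != self._range_shape:
            raise ValueError(
                f"adjoint: expected range shape {self._range_shape}, got {y.shape}"
            )
        return self._adjoint(y)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.apply(x)


class MatrixMap(LinearMap):
    """Operator backed by an explicit (dense or sparse) matrix.

    ``domain_shape``/``range_shape`` may be multi-dimensional; inputs are
    flattened in C order before the matrix-vector product.
    """

    def __init__(
        self,
        matrix,
        domain_shape: tuple[int, ...] | None = None,
        range_shape: tuple[int, ...] | None = None,
    ):
        if sp.issparse(matrix):
            matrix = matrix.tocsr()
        else:
            matrix = np.asarray(matrix, dtype=float)
            if matrix.ndim != 2:
                raise ValueError("MatrixMap requires a 2-D matrix")
        m, d = matrix.shape
        if domain_shape is None:
            domain_shape = (d,)
        if range_shape is None:
            range_shape = (m,)
        if int(np.prod(domain_shape)) != d or int(np.prod(range_shape)) != m:
            raise ValueError("matrix shape inconsistent with domain/range shapes")
        super().__init__(domain_shape, range_shape)
        self.matrix = matrix

    def _apply(self, x: np.ndarray) -> np.ndarray:
        out = self.matrix @ x.ravel()
        return np.asarray(out).reshape(self.range_shape)

    def _adjoint(self, y: np.ndarray) -> np.ndarray:
        out = self.matrix.T @ y.ravel()
        return np.asarray(out).reshape(self.domain_shape)


class BlockRowMap(LinearMap):
    """Row-stacked operator ``A x = (A_1 x, ..., A_n x)``.

    All blocks share the domain; the range is the flat concatenation of the
    (flattened) block ranges.  ``block_slices`` gives each block's slice into
    the stacked range vector.
    """

    def __init__(self, blocks: Sequence[LinearMap]):
        blocks = list(blocks)
        if len(blocks) < 1:
            raise ValueError("BlockRowMap needs at least one block")
        dom = blocks[0].domain_shape
        for b in blocks:
            if b.domain_shape != dom:
                raise ValueError("all blocks must share the domain shape")
        total = sum(b.range_size for b in blocks)
        super().__init__(dom, (total,))
        self.blocks = blocks
        offsets = np.cumsum([0] + [b.range_size for b in blocks])
        self.block_slices = [
            slice(int(offsets[i]), int(offsets[i + 1])) for i in range(len(blocks))
        ]

    def _apply(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([b._apply(x).ravel() for b in self.blocks])

    def _adjoint(self, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.domain_shape)
        for b, sl in zip(self.blocks, self.block_slices):
            out += b._adjoint(y[sl].reshape(b.range_shape))
        return out


class RowSubsetView(LinearMap):
    """Restriction of a flat-range operator to a subset of its rows.

    For matrix-backed parents the view is materialized by row slicing, so
    ``view.apply(x)`` is bit-identical to ``parent.apply(x)[rows]`` and the
    adjoint scatters into the parent domain exactly.  Nested views remain
    matrix-backed.
    """

    def __init__(self, parent: LinearMap, rows: Sequence[int]):
        if len(parent.range_shape) != 1:
            raise ValueError("RowSubsetView requires a parent with flat range")
        rows = np.asarray(rows, dtype=int)
        if rows.size == 0:
            raise ValueError("row subset must be non-empty")
        if np.any(rows < 0) or np.any(rows >= parent.range_size):
            raise ValueError("row index out of range")
        if np.any(np.diff(rows) <= 0):
            raise ValueError("rows must be sorted and unique")
        super().__init__(parent.domain_shape, (rows.size,))
        self.parent = parent
        self.rows = rows
        self.matrix = None
        # sparse row slicing keeps per-row accumulation order, so the view
        # is bit-identical to select-after-apply; dense BLAS does not make
        # that guarantee, so dense parents take the generic path below
        if sp.issparse(getattr(parent, "matrix", None)):
            self.matrix = parent.matrix[rows]

    def _apply(self, x: np.ndarray) -> np.ndarray:
        if self.matrix is not None:
            return np.asarray(self.matrix @ x.ravel()).ravel()
        return self.parent._apply(x)[self.rows]

    def _adjoint(self, y: np.ndarray) -> np.ndarray:
        if self.matrix is not None:
            return np.asarray(self.matrix.T @ y).reshape(self.domain_shape)
        padded = np.zeros(self.parent.range_shape)
        padded[self.rows] = y
        return self.parent._adjoint(padded)


def apply(map_: LinearMap, x: np.ndarray) -> np.ndarray:
    """Functional alias for ``map_.apply(x)``."""
    return map_.apply(x)


def adjoint(map_: LinearMap, y: np.ndarray) -> np.ndarray:
    """Functional alias for ``map_.adjoint(y)``."""
    return map_.adjoint(y)


def row_subset(map_: LinearMap, rows: Sequence[int]) -> RowSubsetView:
    """Restrict ``map_`` to the given sorted, unique rows of its range."""
    return RowSubsetView(map_, rows)


class NormEstimate(float):
    """A float operator-norm estimate carrying a power-iteration status flag."""

    converged: bool
    n_iterations: int

    def __new__(cls, value: float, converged: bool, n_iterations: int):
        obj = super().__new__(cls, value)
        obj.converged = bool(converged)
        obj.n_iterations = int(n_iterations)
        return obj


def estimate_norm(
    map_: LinearMap,
    tol: float = 1e-7,
    max_iter: int = 5000,
    seed: int = 0,
) -> NormEstimate:
    """Estimate the spectral norm ``||A||`` by power iteration on ``A* A``.

    Deterministic given ``seed``.  Non-convergence within ``max_iter`` is
    reported through the ``converged`` attribute of the returned value, not
    raised: the solver's safety margin ``beta < 1`` is meant to absorb small
    estimation error.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(map_.domain_shape)
    nx = np.linalg.norm(x)
    if nx == 0:  # pragma: no cover - zero-probability event
        x = np.ones(map_.domain_shape)
        nx = np.linalg.norm(x)
    x /= nx
    est = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = map_._adjoint(map_._apply(x))
        nw = np.linalg.norm(w)
        if nw == 0:
            return NormEstimate(0.0, True, it)
        new_est = float(np.sqrt(nw))  # ||A*A x|| -> lambda_max, norm = sqrt
        x = w / nw
        if est > 0 and abs(new_est - est) <= tol * new_est:
            est = new_est
            converged = True
            break
        est = new_est
    return NormEstimate(est, converged, it)


class Grad2D(LinearMap):
    """Forward-difference image gradient with replicate (Neumann) boundary.

    Maps an ``(h, w)`` image to a 2-channel field ``(2, h, w)``: channel 0
    holds differences along axis 0 (rows), channel 1 along axis 1 (columns);
    the last row/column of each channel is zero.  ``||D||^2 <= 8``.
    """

    def __init__(self, height: int, width: int):
        if height < 1 or width < 1:
            raise ValueError("grad2d dimensions must be positive")
        super().__init__((height, width), (2, height, width))

    def _apply(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros(self.range_shape)
        out[0, :-1, :] = x[1:, :] - x[:-1, :]
        out[1, :, :-1] = x[:, 1:] - x[:, :-1]
        return out

    def _adjoint(self, y: np.ndarray) -> np.ndarray:
        # negative discrete divergence, the exact transpose of _apply
        out = np.zeros(self.domain_shape)
        a = y[0]
        out[1:, :] += a[:-1, :]
        out[:-1, :] -= a[:-1, :]
        b = y[1]
        out[:, 1:] += b[:, :-1]
        out[:, :-1] -= b[:, :-1]
        return out


def make_grad2d(height: int, width: int) -> Grad2D:
    """Build the 2-D forward-difference gradient operator."""
    return Grad2D(height, width)


_MAX_EXPLICIT_SIDE = 512


def _siddon_ray(n: int, ox: float, oy: float, dx: float, dy: float):
    """Exact pixel intersection lengths of one ray with an n x n unit grid.

    The grid occupies ``[-n/2, n/2]^2``; the ray is ``(ox, oy) + s (dx, dy)``
    with ``(dx, dy)`` a unit vector.  Returns (pixel_flat_indices, lengths).
    """
    half = n / 2.0
    eps = 1e-12
    # slab entry/exit parameters
    s_min, s_max = -np.inf, np.inf
    for o, d in ((ox, dx), (oy, dy)):
        if abs(d) < eps:
            if o <= -half or o >= half:
                return np.empty(0, dtype=int), np.empty(0)
        else:
            s0 = (-half - o) / d
            s1 = (half - o) / d
            s_min = max(s_min, min(s0, s1))
            s_max = min(s_max, max(s0, s1))
    if s_max - s_min <= eps:
        return np.empty(0, dtype=int), np.empty(0)
    crossings = [np.array([s_min, s_max])]
    grid = np.arange(n + 1) - half
    if abs(dx) >= eps:
        sx = (grid - ox) / dx
        crossings.append(sx[(sx > s_min) & (sx < s_max)])
    if abs(dy) >= eps:
        sy = (grid - oy) / dy
        crossings.append(sy[(sy > s_min) & (sy < s_max)])
    s = np.unique(np.concatenate(crossings))
    lengths = np.diff(s)
    mid = 0.5 * (s[:-1] + s[1:])
    mx = ox + mid * dx
    my = oy + mid * dy
    cols = np.clip(np.floor(mx + half).astype(int), 0, n - 1)
    rows = np.clip(np.floor(my + half).astype(int), 0, n - 1)
    keep = lengths > eps
    return (rows[keep] * n + cols[keep]), lengths[keep]


class ParallelProjector(MatrixMap):
    """Parallel-beam tomographic projector as an explicit sparse matrix.

    Rays are traced through a unit-pixel grid centered at the origin with the
    Siddon exact-intersection method; the sinogram is ordered angle-major
    (all detector bins of the first angle, then the second, ...).  The
    explicit matrix gives an exact adjoint (its transpose) and supports exact
    row restriction via :class:`RowSubsetView`.
    """

    def __init__(self, n_pixels: int, angles_deg: Sequence[float], n_detectors: int | None = None):
        if n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")
        if n_pixels > _MAX_EXPLICIT_SIDE:
            raise ValueError(
                f"explicit projector limited to side <= {_MAX_EXPLICIT_SIDE}; "
                "use a smaller grid"
            )
        angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        if angles_deg.size < 1:
            raise ValueError("at least one angle is required")
        if n_detectors is None:
            n_detectors = int(np.ceil(np.sqrt(2.0) * n_pixels))
        if n_detectors < 1:
            raise ValueError("n_detectors must be >= 1")
        span = np.sqrt(2.0) * n_pixels
        spacing = span / n_detectors
        t = (np.arange(n_detectors) - (n_detectors - 1) / 2.0) * spacing
        rows_idx, cols_idx, vals = [], [], []
        for a, theta in enumerate(np.deg2rad(angles_deg)):
            dx, dy = np.cos(theta), np.sin(theta)
            ux, uy = -np.sin(theta), np.cos(theta)
            for c in range(n_detectors):
                pix, lens = _siddon_ray(n_pixels, t[c] * ux, t[c] * uy, dx, dy)
                ray = a * n_detectors + c
                rows_idx.append(np.full(pix.size, ray))
                cols_idx.append(pix)
                vals.append(lens)
        m = angles_deg.size * n_detectors
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(m, n_pixels * n_pixels),
        ).tocsr()
        super().__init__(mat, domain_shape=(n_pixels, n_pixels), range_shape=(m,))
        self.n_pixels = n_pixels
        self.angles_deg = angles_deg
        self.n_detectors = n_detectors
        self.detector_spacing = spacing


def make_parallel_projector(
    n_pixels: int, angles: Sequence[float], n_detectors: int | None = None
) -> ParallelProjector:
    """Build a Siddon parallel-beam projector for an ``n x n`` image."""
    return ParallelProjector(n_pixels, angles, n_detectors)
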