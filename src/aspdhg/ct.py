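"""Synthetic CT test-bed: phantoms, sinograms, minibatch partition, problem assembly.

Emulates the three classic degraded-acquisition regimes at desk scale:

* ``sparse_view`` — few projection angles over the half circle;
* ``limited_angle`` — angles restricted to [0, 150] degrees;
* ``low_dose`` — many angles but photon-starved measurements: Beer-Lambert
  counts ``Poisson(N0 exp(-mu))`` per ray, log-transformed back to noisy
  line integrals (counts clamped at 1 so the log stays finite).

The reconstruction problem is the TV-regularized least-squares objective

    min_x  0.5 ||A x - b||_2^2 + lam ||D x||_1

assembled as a saddle-point problem whose dual blocks are (i) the
interleaved row-blocks of the projector, each with data term
``f_i = 0.5 ||. - b_i||^2``, and (ii) one extra block for the TV operator
``D`` with ``f = lam ||.||_1`` (anisotropic by default, isotropic on
request).  ``g`` is zero.  Measurement rows are grouped interleaved —
block i owns every n-th row starting at i — so every minibatch sees all
angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .operators import (
    BlockRowMap,
    LinearMap,
    estimate_norm,
    make_grad2d,
    make_parallel_projector,
    row_subset,
)
from .proximal import L1Norm, L21Norm, L2Squared, NonNegative, Zero
from .solver import Block, SaddleProblem

__all__ = [
    "PhantomSpec",
    "ScanGeometry",
    "PartitionedSinogram",
    "default_phantom_spec",
    "make_phantom",
    "default_geometry",
    "simulate_sinogram",
    "interleave_partition",
    "assemble_tv_problem",
    "make_ct_problem",
    "TUNED_RATIO",
    "ratio_sweep",
]

# Desk-scale well-tuned starting step-size ratios (tau/sigma) per modality:
# the value the residual-balancing scheme is observed to settle at on the
# default 64x64 problems, which is also the operational definition of a
# well-chosen fixed ratio.  The unit-pixel desk-scale operators have norms
# far from those of full-scale fanbeam CT, so these land at different
# magnitudes than full-scale values; the sweep spans four orders of
# magnitude down from the tuned value, where fixed steps become badly chosen.
TUNED_RATIO = {"sparse_view": 1e-2, "limited_angle": 5e-4, "low_dose": 2e-4}


def ratio_sweep(tuned: float) -> list[float]:
    """Starting-ratio sweep spanning 4 orders of magnitude around ``tuned``."""
    return [tuned * 1e1, tuned, tuned * 1e-2, tuned * 1e-4]


@dataclass
class PhantomSpec:
    """Ellipse-superposition phantom on an ``n x n`` grid.

    Each ellipse is ``(cx, cy, ax, ay, rot_deg, intensity)`` in the
    normalized square ``[-1, 1]^2``; a pixel's value is the sum of the
    intensities of all ellipses containing its center.
    """

    n: int
    ellipses: list[tuple[float, float, float, float, float, float]] = field(
        default_factory=list
    )

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("phantom grid side must be >= 8")
        for e in self.ellipses:
            if len(e) != 6 or not all(np.isfinite(e)):
                raise ValueError("each ellipse is (cx, cy, ax, ay, rot_deg, intensity)")


# A modest head-like phantom in the ellipse-superposition tradition: skull
# rim, brain interior, two low-contrast lateral cavities, two small bright
# lesions.  Intensities are additive.
_DEFAULT_ELLIPSES = [
    (0.0, 0.0, 0.72, 0.92, 0.0, 2.0),
    (0.0, -0.02, 0.66, 0.86, 0.0, -1.0),
    (0.25, 0.0, 0.14, 0.35, -15.0, -0.3),
    (-0.25, 0.0, 0.14, 0.35, 15.0, -0.3),
    (0.0, 0.40, 0.12, 0.12, 0.0, 0.4),
    (0.0, -0.45, 0.05, 0.05, 0.0, 0.5),
]


def default_phantom_spec(n: int = 64) -> PhantomSpec:
    """The built-in head-like ellipse phantom."""
    return PhantomSpec(n=n, ellipses=list(_DEFAULT_ELLIPSES))


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the ellipse phantom: deterministic center-membership sum."""
    n = spec.n
    coords = (np.arange(n) + 0.5) * 2.0 / n - 1.0
    X, Y = np.meshgrid(coords, coords[::-1])  # row 0 at the top
    img = np.zeros((n, n))
    for cx, cy, ax, ay, rot, val in spec.ellipses:
        th = np.deg2rad(rot)
        xr = (X - cx) * np.cos(th) + (Y - cy) * np.sin(th)
        yr = -(X - cx) * np.sin(th) + (Y - cy) * np.cos(th)
        img += val * ((xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0)
    return img


@dataclass
class ScanGeometry:
    """Acquisition description for one of the three degraded modalities."""

    modality: str
    n_angles: int
    angle_range: tuple[float, float] = (0.0, 180.0)
    n_detectors: int | None = None
    N0: float = 1e4

    def __post_init__(self):
        if self.modality not in ("sparse_view", "limited_angle", "low_dose"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        lo, hi = self.angle_range
        if self.modality == "limited_angle" and not (0.0 <= lo and hi <= 150.0):
            raise ValueError("limited-angle range must lie within [0, 150] degrees")
        if self.N0 <= 0:
            raise ValueError("incident photon count N0 must be positive")

    @property
    def angles(self) -> np.ndarray:
        lo, hi = self.angle_range
        return lo + (hi - lo) * np.arange(self.n_angles) / self.n_angles


def default_geometry(modality: str, n_pixels: int = 64) -> ScanGeometry:
    """Desk-scale defaults: 12 angles (sparse), [0,150] x 50 (limited),
    90 noisy angles at N0 = 1e4 (low dose)."""
    if modality == "sparse_view":
        return ScanGeometry("sparse_view", n_angles=12)
    if modality == "limited_angle":
        return ScanGeometry("limited_angle", n_angles=50, angle_range=(0.0, 150.0))
    if modality == "low_dose":
        return ScanGeometry("low_dose", n_angles=90, N0=1e4)
    raise ValueError(f"unknown modality {modality!r}")


def simulate_sinogram(
    image: np.ndarray,
    projector: LinearMap,
    geometry: ScanGeometry,
    rng: np.random.Generator | None = None,
    target_attenuation: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate measurements ``(b, b_clean)`` for the given modality.

    The clean sinogram is the exact forward projection.  In the low-dose
    modality the line integrals are rescaled so the maximum equals
    ``target_attenuation`` (a realistic peak optical depth), per-ray photon
    counts are drawn as ``Poisson(N0 exp(-mu))``, clamped at one count, and
    log-transformed back to the original scale.  The other modalities are
    noise-free; their degradation lives in the geometry.
    """
    clean = projector.apply(image)
    if geometry.modality != "low_dose":
        return clean.copy(), clean
    if rng is None:
        rng = np.random.default_rng(0)
    peak = float(np.max(clean))
    scale = target_attenuation / peak if peak > 0 else 1.0
    expected = geometry.N0 * np.exp(-clean * scale)
    counts = rng.poisson(expected).astype(float)
    noisy = -np.log(np.maximum(counts, 1.0) / geometry.N0) / scale
    return noisy, clean


def interleave_partition(n_rows: int, n_blocks: int) -> list[np.ndarray]:
    """Block i owns rows ``{i, i + n, i + 2n, ...}``; sizes differ by <= 1."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n_blocks > n_rows:
        raise ValueError("cannot split into more blocks than rows")
    return [np.arange(i, n_rows, n_blocks) for i in range(n_blocks)]


@dataclass
class PartitionedSinogram:
    """Row index sets and data vectors of the interleaved minibatches."""

    row_sets: list[np.ndarray]
    data: list[np.ndarray]

    def __post_init__(self):
        if len(self.row_sets) != len(self.data):
            raise ValueError("row sets and data blocks must align")
        all_rows = np.concatenate(self.row_sets)
        if np.unique(all_rows).size != all_rows.size:
            raise ValueError("row sets must be disjoint")

    @property
    def n_blocks(self) -> int:
        return len(self.row_sets)

    def full_sinogram(self) -> np.ndarray:
        """Reassemble the full measurement vector from the blocks."""
        n = sum(r.size for r in self.row_sets)
        out = np.empty(n)
        for rows, b in zip(self.row_sets, self.data):
            out[rows] = b
        return out


def partition_sinogram(b: np.ndarray, n_blocks: int) -> PartitionedSinogram:
    """Interleave-partition a flat sinogram into ``n_blocks`` minibatches."""
    rows = interleave_partition(b.size, n_blocks)
    return PartitionedSinogram(rows, [b[r].copy() for r in rows])


def assemble_tv_problem(
    shape: tuple[int, int],
    projector: LinearMap,
    parts: PartitionedSinogram,
    lam: float,
    tv_flavor: str = "aniso",
    sampling: str = "uniform",
    nonneg: bool = False,
    norm_seed: int = 0,
) -> SaddleProblem:
    """Build the TV-regularized CT saddle-point problem.

    Data blocks are row-subset views of the projector with quadratic data
    terms; when ``lam > 0`` one extra dual block carries the image-gradient
    operator with the (an)isotropic TV conjugate prox.  Sampling is uniform
    over all blocks by default, or proportional to row counts (data blocks)
    with the TV block treated as an average-sized one.  Per-block operator
    norms are power-iteration estimates, seeded for determinism.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if parts.n_blocks < 1:
        raise ValueError("empty partition")
    if tv_flavor not in ("aniso", "iso"):
        raise ValueError("tv_flavor must be 'aniso' or 'iso'")
    ops = [row_subset(projector, rows) for rows in parts.row_sets]
    blocks = []
    for j, (op, b_j) in enumerate(zip(ops, parts.data)):
        L = float(estimate_norm(op, seed=norm_seed + j))
        f = L2Squared(b_j)
        blocks.append(Block(op=op, conj_prox=f.conj_prox, p=0.0, L=L, b=b_j, name=f"data{j}"))
    if lam > 0:
        D = make_grad2d(*shape)
        L_D = float(estimate_norm(D, seed=norm_seed + len(ops)))
        ftv = L1Norm(lam) if tv_flavor == "aniso" else L21Norm(lam)
        blocks.append(Block(op=D, conj_prox=ftv.conj_prox, p=0.0, L=L_D, b=None, name="tv"))
    n = len(blocks)
    if sampling == "uniform":
        probs = np.full(n, 1.0 / n)
    elif sampling == "size_weighted":
        sizes = np.array(
            [blk.b.size if blk.b is not None else 0 for blk in blocks], dtype=float
        )
        mean_data = sizes[sizes > 0].mean()
        sizes[sizes == 0] = mean_data
        probs = sizes / sizes.sum()
    else:
        raise ValueError("sampling must be 'uniform' or 'size_weighted'")
    for blk, p in zip(blocks, probs):
        blk.p = float(p)
    g = NonNegative() if nonneg else Zero()
    return SaddleProblem(g=g, blocks=blocks, domain_shape=tuple(shape))


# Desk-scale default TV weights per modality: small enough that the data
# term dominates at the reference solution for clean geometries, larger for
# the noisy low-dose regime where TV must actually denoise.
_DEFAULT_LAMBDA = {"sparse_view": 0.02, "limited_angle": 0.02, "low_dose": 0.2}


def make_ct_problem(
    modality: str,
    n_pixels: int = 64,
    n_blocks: int = 10,
    lam: float | None = None,
    tv_flavor: str = "aniso",
    noise_seed: int = 0,
    geometry: ScanGeometry | None = None,
):
    """One-call construction of a full synthetic CT benchmark instance.

    Returns ``(problem, info)`` where ``info`` carries the phantom, the
    projector, clean and measured sinograms, the TV operator/weight and a
    ready-to-log ``objective`` callable.
    """
    if geometry is None:
        geometry = default_geometry(modality, n_pixels)
    if lam is None:
        lam = _DEFAULT_LAMBDA[modality]
    phantom = make_phantom(default_phantom_spec(n_pixels))
    projector = make_parallel_projector(n_pixels, geometry.angles, geometry.n_detectors)
    rng = np.random.default_rng(noise_seed)
    b, b_clean = simulate_sinogram(phantom, projector, geometry, rng=rng)
    parts = partition_sinogram(b, n_blocks)
    problem = assemble_tv_problem((n_pixels, n_pixels), projector, parts, lam, tv_flavor)

    D = make_grad2d(n_pixels, n_pixels)
    tv = L1Norm(lam) if tv_flavor == "aniso" else L21Norm(lam)

    def objective(x: np.ndarray) -> float:
        r = projector.apply(x) - b
        return 0.5 * float(np.sum(r**2)) + tv(D.apply(x))

    info = {
        "phantom": phantom,
        "projector": projector,
        "geometry": geometry,
        "sinogram": b,
        "sinogram_clean": b_clean,
        "partition": parts,
        "lam": lam,
        "tv_flavor": tv_flavor,
        "D": D,
        "objective": objective,
    }
    return problem, info
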