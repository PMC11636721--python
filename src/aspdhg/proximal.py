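"""Proximable convex functions and their conjugate proximal maps.

The saddle-point solver only ever touches a function through two contracts:
``prox(v, t) = argmin_z 0.5||z - v||^2 + t h(z)`` and the conjugate prox
``prox_{t h*}``, which is derived from the primal prox through the Moreau
identity ``prox_{t h*}(v) = v - t prox_{h/t}(v/t)`` when no closed form is
supplied.  The shipped functions cover the TV-regularized least-squares
objective: the zero function (no explicit primal term), a nonnegativity
constraint, quadratic data misfit terms ``0.5||z - b||^2``, and the
anisotropic / isotropic TV penalties.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Proximable",
    "Zero",
    "NonNegative",
    "L2Squared",
    "L1Norm",
    "L21Norm",
    "prox_zero",
    "prox_nonneg",
    "prox_l2sq_conj",
    "prox_l1_conj",
    "prox_l21_conj",
]


class Proximable:
    """Convex function with an evaluation and a proximal contract."""

    def __call__(self, v: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError

    def prox(self, v: np.ndarray, t: float) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def conj_prox(self, v: np.ndarray, t: float) -> np.ndarray:
        """Prox of the Fenchel conjugate, via the Moreau identity."""
        if t <= 0:
            raise ValueError("prox step must be positive")
        return v - t * self.prox(v / t, 1.0 / t)


class Zero(Proximable):
    """The zero function; its prox is the identity."""

    def __call__(self, v):
        return 0.0

    def prox(self, v, t):
        if t <= 0:
            raise ValueError("prox step must be positive")
        return np.asarray(v, dtype=float)


class NonNegative(Proximable):
    """Indicator of the nonnegative orthant; prox is the projection."""

    def __call__(self, v):
        return 0.0 if np.all(np.asarray(v) >= 0) else np.inf

    def prox(self, v, t):
        if t <= 0:
            raise ValueError("prox step must be positive")
        return np.maximum(np.asarray(v, dtype=float), 0.0)


class L2Squared(Proximable):
    """``f(z) = 0.5 ||z - b||^2`` with closed-form primal and conjugate prox."""

    def __init__(self, b: np.ndarray):
        self.b = np.asarray(b, dtype=float)

    def __call__(self, v):
        return 0.5 * float(np.sum((np.asarray(v) - self.b) ** 2))

    def prox(self, v, t):
        if t <= 0:
            raise ValueError("prox step must be positive")
        return (np.asarray(v, dtype=float) + t * self.b) / (1.0 + t)

    def conj_prox(self, v, t):
        return prox_l2sq_conj(v, t, self.b)


class L1Norm(Proximable):
    """``f(z) = lam ||z||_1``; prox is soft-thresholding, conjugate prox a box clip."""

    def __init__(self, lam: float):
        if lam < 0:
            raise ValueError("lam must be nonnegative")
        self.lam = float(lam)

    def __call__(self, v):
        return self.lam * float(np.sum(np.abs(v)))

    def prox(self, v, t):
        if t <= 0:
            raise ValueError("prox step must be positive")
        v = np.asarray(v, dtype=float)
        return np.sign(v) * np.maximum(np.abs(v) - t * self.lam, 0.0)

    def conj_prox(self, v, t):
        return prox_l1_conj(v, t, self.lam)


class L21Norm(Proximable):
    """Isotropic TV magnitude ``lam * sum_p ||(field_0p, field_1p)||_2``.

    Acts on 2-channel fields of shape ``(2, h, w)``; the conjugate prox is a
    per-pixel projection onto the Euclidean ball of radius ``lam``.
    """

    def __init__(self, lam: float):
        if lam < 0:
            raise ValueError("lam must be nonnegative")
        self.lam = float(lam)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.lam * float(np.sum(np.sqrt(np.sum(v**2, axis=0))))

    def prox(self, v, t):
        if t <= 0:
            raise ValueError("prox step must be positive")
        v = np.asarray(v, dtype=float)
        norms = np.sqrt(np.sum(v**2, axis=0))
        shrink = np.maximum(norms - t * self.lam, 0.0) / np.maximum(norms, 1e-300)
        return v * shrink[None]

    def conj_prox(self, v, t):
        return prox_l21_conj(v, t, self.lam)


def prox_zero(v: np.ndarray, t: float) -> np.ndarray:
    """Prox of the zero function: the identity."""
    if t <= 0:
        raise ValueError("prox step must be positive")
    return np.asarray(v, dtype=float)


def prox_nonneg(v: np.ndarray, t: float) -> np.ndarray:
    """Prox of the nonnegative-orthant indicator: componentwise ``max(v, 0)``."""
    if t <= 0:
        raise ValueError("prox step must be positive")
    return np.maximum(np.asarray(v, dtype=float), 0.0)


def prox_l2sq_conj(y: np.ndarray, t: float, b: np.ndarray) -> np.ndarray:
    """Conjugate prox of ``f(z) = 0.5||z - b||^2``: ``(y - t b) / (1 + t)``."""
    if t <= 0:
        raise ValueError("prox step must be positive")
    y = np.asarray(y, dtype=float)
    b = np.asarray(b, dtype=float)
    if y.shape != b.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs b {b.shape}")
    return (y - t * b) / (1.0 + t)


def prox_l1_conj(y: np.ndarray, t: float, lam: float) -> np.ndarray:
    """Conjugate prox of ``lam ||.||_1``: clip to ``[-lam, lam]`` (t-free)."""
    if t <= 0:
        raise ValueError("prox step must be positive")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    return np.clip(np.asarray(y, dtype=float), -lam, lam)


def prox_l21_conj(y: np.ndarray, t: float, lam: float) -> np.ndarray:
    """Conjugate prox of the isotropic TV term: per-pixel ball projection.

    ``y`` is a 2-channel field; each pixel's 2-vector is projected onto the
    Euclidean ball of radius ``lam``.
    """
    if t <= 0:
        raise ValueError("prox step must be positive")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    y = np.asarray(y, dtype=float)
    norms = np.sqrt(np.sum(y**2, axis=0))
    scale = np.where(norms > lam, lam / np.maximum(norms, 1e-300), 1.0)
    return y * scale[None]
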