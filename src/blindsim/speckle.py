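"""Synthetic speckle illumination fields.

A speckle field is modelled as the intensity of a sum of plane waves with
random phases, random amplitudes, and wavevectors drawn uniformly from a disc
``|k| <= k_cut`` in the spatial-frequency plane:

    E(r) = sum_j a_j exp(i (k_j . r + phi_j)),      I(r) = |E(r)|^2

with ``phi_j`` uniform on ``[0, 2pi)`` and ``a_j`` i.i.d. Rayleigh with unit
mean — the circular-Gaussian statistics of fully developed speckle.  The
cutoff ``k_cut`` controls the mean grain size ``d_sp``, defined throughout
this package as the FWHM of the intensity autocorrelation peak.

For a uniform disc of wavevectors the ensemble field correlation is the Airy
amplitude ``2 J1(k_cut r) / (k_cut r)`` and the intensity autocorrelation
contrast is its square, so ``d_sp = 2 v_half / k_cut`` where ``v_half`` is the
half-maximum point of ``[2 J1(v)/v]^2``.  That constant is found once by a
numerical root-find (no closed form is needed beyond the Bessel profile).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import j1

__all__ = [
    "SpeckleParams",
    "SpeckleField",
    "SpeckleStack",
    "airy_halfwidth_constant",
    "kcut_for_grain_size",
    "generate_speckle",
    "speckle_stack",
]


@lru_cache(maxsize=1)
def airy_halfwidth_constant() -> float:
    """The v > 0 solving ``[2 J1(v)/v]^2 = 1/2`` (about 1.6163)."""

    def f(v: float) -> float:
        return (2.0 * j1(v) / v) ** 2 - 0.5

    return float(brentq(f, 0.5, 3.0, xtol=1e-12))


def kcut_for_grain_size(d_sp: float) -> float:
    """Spatial-frequency cutoff (rad/px) giving autocorrelation FWHM d_sp."""
    if d_sp <= 0:
        raise ValueError("d_sp must be positive")
    return 2.0 * airy_halfwidth_constant() / d_sp


@dataclass(frozen=True)
class SpeckleParams:
    """Speckle generator parameters.

    ``d_sp`` is the grain size in pixels (FWHM of the intensity
    autocorrelation); ``n_waves`` the number of plane-wave components
    (>= 100 for the fully developed regime; smaller values are allowed for
    degenerate checks such as the single-wave flat field); ``normalization``
    the target mean intensity.
    """

    d_sp: float
    n_waves: int = 256
    seed: int = 0
    normalization: float = 1.0

    def __post_init__(self) -> None:
        if self.d_sp <= 0:
            raise ValueError("d_sp must be positive")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if self.normalization <= 0:
            raise ValueError("normalization target must be positive")


@dataclass(frozen=True)
class SpeckleField:
    """One speckle intensity realization ``I(r)`` with its parameters."""

    pixels: np.ndarray
    params: SpeckleParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SpeckleStack:
    """N independent speckle fields stacked along the first axis."""

    frames: np.ndarray  # (N, H, W)
    params: SpeckleParams

    @property
    def n(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def _field_from_rng(
    params: SpeckleParams, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    if min(h, w) < 4 * params.d_sp:
        raise ValueError(
            f"field {shape} too small for grain size {params.d_sp} px "
            "(need at least 4 grains per side)"
        )
    k_cut = kcut_for_grain_size(params.d_sp)
    n = params.n_waves
    # uniform over the disc |k| <= k_cut
    radius = k_cut * np.sqrt(rng.uniform(0.0, 1.0, n))
    angle = rng.uniform(0.0, 2.0 * np.pi, n)
    kx = radius * np.cos(angle)
    ky = radius * np.sin(angle)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    # Rayleigh with unit mean: sigma = 1/sqrt(pi/2)
    amp = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=n)

    ys = np.arange(h)
    xs = np.arange(w)
    # E = (U * c).T @ V with separable per-wave phase factors
    u = np.exp(1j * np.outer(ky, ys))  # (n, H)
    v = np.exp(1j * np.outer(kx, xs))  # (n, W)
    c = amp * np.exp(1j * phi)
    field = (u * c[:, None]).T @ v  # (H, W)
    intensity = np.abs(field) ** 2
    mean = intensity.mean()
    if mean > 0:
        intensity *= params.normalization / mean
    return intensity


def generate_speckle(
    params: SpeckleParams, shape: tuple[int, int]
) -> SpeckleField:
    """One speckle intensity field of the requested shape.

    Deterministic given ``params.seed``; the intensity is rescaled so its
    spatial mean equals ``params.normalization`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    return SpeckleField(pixels=_field_from_rng(params, shape, rng), params=params)


def speckle_stack(
    params: SpeckleParams, n: int, shape: tuple[int, int]
) -> SpeckleStack:
    """N independent speckle realizations from seed-derived sub-streams."""
    if n <= 0:
        raise ValueError(f"frame count must be positive, got {n}")
    children = np.random.SeedSequence(params.seed).spawn(n)
    frames = np.empty((n, shape[0], shape[1]), dtype=np.float64)
    for i, child in enumerate(children):
        frames[i] = _field_from_rng(params, shape, np.random.default_rng(child))
    return SpeckleStack(frames=frames, params=params)
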