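"""Ground-truth fluorophore-density phantoms.

Two families of targets are generated here:

* the Siemens star ``rho(r, theta) = 1 + cos(n_lobes * theta)`` — the standard
  radial resolution target whose local spatial period grows linearly with
  radius, so the radius at which the spokes become distinguishable encodes the
  resolution of an imaging pipeline;
* synthetic cell-like maps (random smooth filaments with a Gaussian
  cross-section plus soma-like blobs) used as training material for the
  CNN deconvolver.

Geometry convention: row-major arrays, origin at the top-left corner, pixel
centers at integer ``(row, col)`` coordinates.  The polar angle ``theta`` is
measured counter-clockwise from the +x (column) axis, i.e.
``theta = atan2(center_row - row, col - center_col)``.  Lengths are tracked in
units of the collection PSF width ``d_PSF`` through ``pixel_pitch``
(d_PSF per pixel), so statements like "field of view is 13 x d_PSF" are
checkable on the object itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DensityMap",
    "CellSceneParams",
    "make_siemens_star",
    "make_cell_like_gt",
    "extract_patches",
]


@dataclass(frozen=True)
class DensityMap:
    """A 2-D non-negative fluorophore density map.

    Parameters
    ----------
    pixels
        Non-negative, finite 2-D array.
    pixel_pitch
        Physical length of one pixel, in units of ``d_PSF``.
    center
        Sub-pixel ``(row, col)`` coordinates of the pattern center, for
        phantoms that have one.
    origin
        ``(row, col)`` offset of this map inside a parent image (set by
        :func:`extract_patches`).
    """

    pixels: np.ndarray
    pixel_pitch: float
    center: tuple[float, float] | None = None
    origin: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"density map must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("density map contains NaN or Inf")
        if px.min() < 0:
            raise ValueError("density map contains negative values")
        if not (self.pixel_pitch > 0):
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def d_psf_px(self) -> float:
        """The PSF FWHM expressed in pixels on this map's grid."""
        return 1.0 / self.pixel_pitch

    def with_pixels(self, pixels: np.ndarray) -> "DensityMap":
        return replace(self, pixels=pixels)


def make_siemens_star(
    size_px: int = 128,
    fov_in_dpsf: float = 13.0,
    n_lobes: int = 20,
) -> DensityMap:
    """Siemens-star resolution target ``rho = 1 + cos(n_lobes * theta)``.

    The star is centered at the geometric image center (half-pixel
    convention, ``(size-1)/2``).  Within a radius of one pixel of the center
    the angle is numerically meaningless; those pixels take the azimuthal
    mean value 1 (a removable singularity).

    Values lie in ``[0, 2]``; the angular pattern has exactly ``n_lobes``
    periods per full turn, so the local spatial period at radius ``R`` is
    ``2*pi*R / n_lobes``.
    """
    if size_px < 32:
        raise ValueError(f"size_px must be >= 32, got {size_px}")
    if n_lobes <= 0:
        raise ValueError(f"n_lobes must be positive, got {n_lobes}")
    if fov_in_dpsf <= 0:
        raise ValueError(f"fov_in_dpsf must be positive, got {fov_in_dpsf}")

    cy = (size_px - 1) / 2.0
    cx = (size_px - 1) / 2.0
    rows, cols = np.mgrid[0:size_px, 0:size_px]
    dy = cy - rows  # +y up so theta runs counter-clockwise from +x
    dx = cols - cx
    theta = np.arctan2(dy, dx)
    rho = 1.0 + np.cos(n_lobes * theta)
    r = np.hypot(dx, dy)
    rho[r < 1.0] = 1.0
    return DensityMap(
        pixels=rho,
        pixel_pitch=fov_in_dpsf / size_px,
        center=(cy, cx),
    )


@dataclass(frozen=True)
class CellSceneParams:
    """Controls for the synthetic cell-like scene generator.

    Defaults give sparse scenes (well under half the pixels above 10% of the
    maximum) whose filaments are thinner than ``d_PSF`` in places, so
    super-resolving them is meaningful.  ``filament_sigma_px`` is the Gaussian
    cross-section of a filament and ``blob_sigma_px`` the width of a
    soma-like blob, both in pixels.
    """

    n_filaments: int = 6
    n_blobs: int = 3
    filament_sigma_px: float = 1.5
    blob_sigma_px: float = 6.0
    step_px: float = 2.0
    curvature: float = 0.35
    steps_per_filament: int = 200
    filament_intensity: tuple[float, float] = (0.5, 1.0)
    blob_intensity: tuple[float, float] = (0.3, 0.8)
    background: float = 0.0


def make_cell_like_gt(
    shape: tuple[int, int],
    params: CellSceneParams | None = None,
    seed: int = 0,
) -> DensityMap:
    """Random cell-like density map: smooth filaments plus blobs.

    Filaments are directed random walks (heading perturbed by a Gaussian
    ``curvature`` increment each step) deposited on the grid and smoothed to
    a Gaussian cross-section; blobs are isotropic Gaussian peaks.
    Deterministic given ``seed``.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 8 or w < 8:
        raise ValueError(f"scene shape too small: {shape}")
    if params is None:
        # default structure counts are a density (referenced to a 256x256
        # scene), so larger fields of view keep the same filament coverage
        area_scale = (h * w) / 256.0**2
        params = CellSceneParams(
            n_filaments=max(3, round(6 * area_scale)),
            n_blobs=max(2, round(3 * area_scale)),
        )
    p = params
    rng = np.random.default_rng(seed)

    canvas = np.zeros((h, w), dtype=np.float64)

    for _ in range(p.n_filaments):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        heading = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(*p.filament_intensity)
        for _ in range(p.steps_per_filament):
            heading += rng.normal(0.0, p.curvature)
            y += p.step_px * np.sin(heading)
            x += p.step_px * np.cos(heading)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < h and 0 <= ix < w:
                canvas[iy, ix] += amp
    if p.n_filaments > 0:
        canvas = gaussian_filter(canvas, p.filament_sigma_px, mode="constant")

    blobs = np.zeros((h, w), dtype=np.float64)
    for _ in range(p.n_blobs):
        cy = rng.uniform(0.1 * h, 0.9 * h)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        amp = rng.uniform(*p.blob_intensity)
        rows, cols = np.mgrid[0:h, 0:w]
        blobs += amp * np.exp(
            -((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * p.blob_sigma_px**2)
        )

    scene = canvas + blobs + p.background
    np.clip(scene, 0.0, None, out=scene)
    # default grid: 8 px per d_PSF, matching the forward model default
    return DensityMap(pixels=scene, pixel_pitch=1.0 / 8.0)


def extract_patches(
    image: DensityMap,
    n_patches: int,
    patch_fov_in_dpsf: float = 11.0,
    seed: int = 0,
) -> list[DensityMap]:
    """Cut ``n_patches`` square patches at uniformly random positions.

    The patch side in pixels is ``round(patch_fov_in_dpsf / pixel_pitch)``.
    Within one call no two patches share the same top-left offset, so each
    patch coordinate is used at most once per dataset.  Deterministic given
    ``seed``; each returned :class:`DensityMap` records its offset in
    ``origin``.
    """
    if n_patches < 0:
        raise ValueError("n_patches must be >= 0")
    side = int(round(patch_fov_in_dpsf / image.pixel_pitch))
    h, w = image.shape
    if side > h or side > w:
        raise ValueError(
            f"patch side {side} px exceeds image shape {image.shape}"
        )
    if n_patches == 0:
        return []
    max_y = h - side
    max_x = w - side
    n_positions = (max_y + 1) * (max_x + 1)
    if n_patches > n_positions:
        raise ValueError(
            f"cannot draw {n_patches} distinct patches from "
            f"{n_positions} available positions"
        )
    rng = np.random.default_rng(seed)
    # sample distinct flat offsets without materializing the full grid
    chosen: set[int] = set()
    offsets: list[int] = []
    while len(offsets) < n_patches:
        cand = int(rng.integers(0, n_positions))
        if cand not in chosen:
            chosen.add(cand)
            offsets.append(cand)
    patches = []
    for flat in offsets:
        oy, ox = divmod(flat, max_x + 1)
        patches.append(
            DensityMap(
                pixels=image.pixels[oy : oy + side, ox : ox + side].copy(),
                pixel_pitch=image.pixel_pitch,
                origin=(oy, ox),
            )
        )
    return patches
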