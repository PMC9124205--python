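"""Lucy–Richardson deconvolution baseline.

The classical single-image maximum-likelihood deconvolution for Poisson
imaging, applied here to the pixelwise mean of the low-resolution stack (the
wide-field-equivalent image).  The multiplicative update

    e_{t+1} = e_t * [ (image / (e_t * h + eps)) * h_flipped ]

starts from ``e_0 = image``, preserves non-negativity at every step and
conserves total flux under the reflective boundary rule used throughout the
package.  No damping, acceleration or blind-PSF estimation is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import FrameStack, PSFModel, blur_image
from .phantoms import DensityMap

__all__ = ["LRParams", "lucy_richardson", "lucy_richardson_stack_mean"]


@dataclass(frozen=True)
class LRParams:
    """Richardson–Lucy settings: iteration count and division stabilizer."""

    n_iter: int = 50
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def lucy_richardson(
    image: np.ndarray | DensityMap,
    psf: PSFModel,
    params: LRParams | None = None,
) -> DensityMap:
    """Richardson–Lucy deconvolution of one non-negative image."""
    pitch = image.pixel_pitch if isinstance(image, DensityMap) else 1.0 / psf.d_psf
    img = image.pixels if isinstance(image, DensityMap) else np.asarray(image, dtype=np.float64)
    if img.min() < 0:
        raise ValueError("Richardson-Lucy requires a non-negative image")
    p = params or LRParams()
    kernel = psf.kernel
    kernel_flipped = kernel[::-1, ::-1]
    # PSFModel.kernel is radially symmetric so the flip is a formality,
    # kept for correctness with any symmetric-enough kernel
    flip_psf = PSFModel(kind=psf.kind, d_psf=psf.d_psf, kernel=kernel_flipped, support=psf.support)
    estimate = img.copy()
    for _ in range(p.n_iter):
        reblurred = blur_image(estimate, psf)
        ratio = img / (reblurred + p.epsilon)
        estimate = estimate * blur_image(ratio, flip_psf)
        np.clip(estimate, 0.0, None, out=estimate)
    return DensityMap(pixels=estimate, pixel_pitch=pitch)


def lucy_richardson_stack_mean(
    lr_stack: FrameStack,
    psf: PSFModel,
    params: LRParams | None = None,
    pixel_pitch: float | None = None,
) -> DensityMap:
    """Deconvolve the pixelwise mean of a low-resolution stack.

    This is the comparison convention used in the benchmarks: the mean over
    speckle illuminations is the wide-field image a classical single-image
    deconvolver would see.
    """
    mean = lr_stack.mean_frame()
    out = lucy_richardson(mean, psf, params)
    if pixel_pitch is not None:
        out = DensityMap(pixels=out.pixels, pixel_pitch=pixel_pitch)
    return out
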