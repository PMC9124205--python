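"""Stack and configuration I/O.

Frame stacks travel as multi-page 32-bit float grayscale TIFF (page order =
frame order; a 1-frame stack stays 3-D).  Integer TIFFs are converted to
float on read with the scale recorded in the stack provenance.  Benchmark
configurations round-trip through a flat ``key = value`` text format with no
includes; sidecar metadata for phantoms uses the same format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Any

import numpy as np
import tifffile

from .forward import FrameRole, FrameStack
from .phantoms import DensityMap

__all__ = [
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "write_keyvalues",
    "read_keyvalues",
    "BenchmarkConfig",
]


def write_stack(stack: FrameStack, path: str) -> None:
    """Write a frame stack as a multi-page float32 TIFF."""
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")


def read_stack(path: str, role: FrameRole | str = FrameRole.LOWRES) -> FrameStack:
    """Read a multi-page grayscale TIFF as a frame stack.

    8/16-bit integer pages are converted to float and divided by the dtype
    maximum (scale recorded in provenance).  Color or mixed-shape pages are
    rejected with the offending page named.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise ValueError(f"{path}: page {i} is not grayscale (shape {page.shape})")
        if page.shape != shape0:
            raise ValueError(
                f"{path}: page {i} shape {page.shape} differs from page 0 {shape0}"
            )
    arr = np.stack(pages)
    prov: dict[str, Any] = {"path": os.fspath(path)}
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / scale
        prov["int_scale"] = scale
    else:
        arr = arr.astype(np.float64)
    if isinstance(role, str):
        role = FrameRole(role)
    return FrameStack(frames=arr, role=role, provenance=prov)


def write_image(image: DensityMap | np.ndarray, path: str, pixel_pitch: float | None = None,
                extra_meta: dict[str, Any] | None = None) -> None:
    """Write one image as single-page float32 TIFF plus a ``.meta`` sidecar."""
    if isinstance(image, DensityMap):
        pixels = image.pixels
        pitch = image.pixel_pitch
    else:
        pixels = np.asarray(image)
        pitch = pixel_pitch if pixel_pitch is not None else 1.0
    tifffile.imwrite(path, pixels.astype(np.float32), photometric="minisblack")
    meta = {"pixel_pitch": pitch}
    if extra_meta:
        meta.update(extra_meta)
    write_keyvalues(meta, str(path) + ".meta")


def read_image(path: str) -> DensityMap:
    """Read a single-page TIFF (with optional ``.meta`` sidecar) as a map."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single grayscale page, got {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    pitch = 1.0
    meta_path = str(path) + ".meta"
    if os.path.exists(meta_path):
        meta = read_keyvalues(meta_path)
        pitch = float(meta.get("pixel_pitch", 1.0))
    return DensityMap(pixels=np.asarray(arr, dtype=np.float64), pixel_pitch=pitch)


# ---------------------------------------------------------------------------
# key-value config files


def _format_value(v: Any) -> str:
    if isinstance(v, (list, tuple)):
        return ",".join(_format_value(x) for x in v)
    if isinstance(v, bool):
        return "true" if v else "false"
    if v is None:
        return ""
    return str(v)


def write_keyvalues(mapping: dict[str, Any], path: str) -> None:
    with open(path, "w") as fh:
        for key, value in mapping.items():
            fh.write(f"{key} = {_format_value(value)}\n")


def _parse_scalar(text: str) -> Any:
    t = text.strip()
    if t == "":
        return None
    if t.lower() in ("true", "false"):
        return t.lower() == "true"
    try:
        return int(t)
    except ValueError:
        pass
    try:
        return float(t)
    except ValueError:
        pass
    return t


def read_keyvalues(path: str) -> dict[str, Any]:
    """Parse a flat ``key = value`` file (``#`` comments, commas = lists)."""
    out: dict[str, Any] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            value = value.strip()
            if "," in value:
                out[key.strip()] = [_parse_scalar(v) for v in value.split(",")]
            else:
                out[key.strip()] = _parse_scalar(value)
    return out


# ---------------------------------------------------------------------------
# benchmark configuration

_VALID_METHODS = ("sai", "lucy", "bscnn")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Full description of one star-target benchmark run.

    ``eta = d_psf_px / d_sp_px`` must be >= 1 (the regime where the speckle
    grain is finer than the collection PSF).  All randomness derives from
    ``seed``.  ``model_path`` is required only when ``bscnn`` is among the
    methods.
    """

    star_size_px: int = 128
    star_fov_in_dpsf: float = 13.0
    n_lobes: int = 20
    n_frames: int = 200
    eta: float = 2.5
    methods: tuple[str, ...] = ("sai", "lucy")
    seed: int = 0
    lucy_iterations: int = 50
    sai_k: int | None = None
    sai_max_proposals: int | None = None
    model_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.eta < 1.0:
            raise ValueError(f"eta must be >= 1, got {self.eta}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for m in self.methods:
            if m not in _VALID_METHODS:
                raise ValueError(f"unknown method {m!r} (valid: {_VALID_METHODS})")
        if "bscnn" in self.methods and not self.model_path:
            raise ValueError("method 'bscnn' requires model_path")

    @property
    def d_psf_px(self) -> float:
        return self.star_size_px / self.star_fov_in_dpsf

    @property
    def d_sp_px(self) -> float:
        return self.d_psf_px / self.eta

    def to_file(self, path: str) -> None:
        write_keyvalues(
            {
                "star_size_px": self.star_size_px,
                "star_fov_in_dpsf": self.star_fov_in_dpsf,
                "n_lobes": self.n_lobes,
                "n_frames": self.n_frames,
                "eta": self.eta,
                "methods": list(self.methods),
                "seed": self.seed,
                "lucy_iterations": self.lucy_iterations,
                "sai_k": self.sai_k,
                "sai_max_proposals": self.sai_max_proposals,
                "model_path": self.model_path,
                "output_dir": self.output_dir,
            },
            path,
        )

    @classmethod
    def from_file(cls, path: str) -> "BenchmarkConfig":
        kv = read_keyvalues(path)
        if "methods" in kv:
            methods = kv["methods"]
            if isinstance(methods, str):
                methods = [methods]
            elif methods is None:
                methods = []
            kv["methods"] = tuple(methods)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(kv) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**kv)
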