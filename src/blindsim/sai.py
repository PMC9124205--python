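"""Scattering Assisted Imaging (SAI) deconvolution.

Each sparsified HP frame is approximated by a synthetic frame built from K
Airy-disk "atoms" of size ``d_sp`` at sub-pixel positions ``r_nk`` with
positive amplitudes ``P_nk``:

    g_n(r) = sum_k P_nk * h_atom(r - r_nk)

A stochastic local search looks for the atom configuration whose PSF-blurred
rendering best matches the HP frame under the L1 objective

    F = sum_r | (g_n * h)(r) - HP_n(r) |

one proposal at a time: pick an atom uniformly at random, move it uniformly
within a disc of radius ``d_sp`` and redraw its amplitude from a unit-mean
exponential, then jointly rescale all amplitudes so the blurred model flux
matches the HP flux (a single closed-form scale), accepting the proposal only
if F strictly decreases.  The final reconstruction is the ensemble average
G = mean_n g_n over the independently fitted frames.

Numerical conventions (this package's, stated once):

* Atoms are rendered from a finely tabulated radial Airy profile (peak 1,
  FWHM ``d_sp``), truncated where the profile falls below ~2e-4 of the peak.
* The model-side convolution ``g_n * h`` assumes a zero background outside
  the frame (plain 'same' convolution) — the model lives on an isolated
  frame, unlike the data-side blur which uses reflective padding.
* With continuous positions (the default, used on benchmark-size frames)
  the blurred contribution of a single atom is maintained incrementally from
  a radially interpolated blurred-atom profile — a truncation-level
  approximation of the objective that keeps one proposal cheap.  With
  pixel-quantized positions (a correctness mode for small frames) every
  proposal re-evaluates the exact objective by rendering and convolving the
  full configuration, so the search optimizes precisely the F that an
  exhaustive enumeration would score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve

from .forward import FrameStack, PSFModel, airy_profile
from .phantoms import DensityMap

__all__ = [
    "AiryAtomSet",
    "SearchParams",
    "SAIResult",
    "default_k",
    "render_atoms",
    "model_convolve",
    "sai_objective",
    "sai_fit_frame",
    "sai_reconstruct",
]

_TABLE_STEP = 0.02  # px, radial table sampling for atom rendering
_ATOM_CUTOFF_FWHM = 6.0  # atom truncation radius in units of d_sp


@dataclass(frozen=True)
class AiryAtomSet:
    """K Airy atoms describing one fitted HP frame.

    ``positions`` are sub-pixel ``(row, col)`` coordinates inside
    ``frame_shape``; ``amplitudes`` are the (already flux-scaled) positive
    weights ``P_nk``; ``atom_fwhm`` is the speckle grain size ``d_sp`` in
    pixels.  ``flagged_empty`` marks fits of all-zero frames (zero-effect
    amplitudes, skipped when averaging).
    """

    positions: np.ndarray  # (K, 2) row, col
    amplitudes: np.ndarray  # (K,)
    atom_fwhm: float
    frame_shape: tuple[int, int]
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=np.float64))
        if pos.shape[0] != amp.shape[0] or pos.shape[1] != 2:
            raise ValueError("positions must be (K, 2) and amplitudes (K,)")
        if pos.shape[0] < 1:
            raise ValueError("need at least one atom")
        h, w = self.frame_shape
        if (
            pos[:, 0].min() < 0
            or pos[:, 1].min() < 0
            or pos[:, 0].max() > h - 1
            or pos[:, 1].max() > w - 1
        ):
            raise ValueError("atom positions outside frame bounds")
        if not self.flagged_empty and amp.min() <= 0:
            raise ValueError("amplitudes must be positive")
        if self.atom_fwhm < 2.0:
            raise ValueError("atom_fwhm must be >= 2 px (sampling adequacy)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def k(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SearchParams:
    """Local-search budget and proposal settings.

    ``max_proposals`` defaults to 20 proposals per atom — enough to settle
    the bright-grain positions; pushing much further makes each frame fit
    sparser (the L1 objective concentrates flux) and the ensemble average
    visibly grainier.  ``stall_window`` is
    the number of consecutive rejected proposals after which the search
    stops; ``n_restarts`` > 1 repeats the search from random initializations
    keeping the best configuration; ``quantize`` restricts positions to the
    integer pixel grid (exact incremental objective); ``proposal_radius``
    defaults to ``d_sp``.
    """

    max_proposals: int | None = None
    stall_window: int = 2000
    n_restarts: int = 1
    quantize: bool = False
    proposal_radius: float | None = None


@dataclass(frozen=True)
class SAIResult:
    """Ensemble SAI fit: per-frame atom sets, objectives and the average G."""

    per_frame_atoms: list[AiryAtomSet]
    per_frame_objective: list[float]
    reconstruction: DensityMap
    diagnostics: list[dict[str, Any]]
    n_used: int


# ---------------------------------------------------------------------------
# atom rendering


def _atom_table(d_sp: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Fine radial table of the unit-peak Airy atom profile and its radius."""
    r_max = float(np.ceil(_ATOM_CUTOFF_FWHM * d_sp))
    r = np.arange(0.0, r_max + _TABLE_STEP, _TABLE_STEP)
    return r, airy_profile(r, d_sp), r_max


def _add_window(
    canvas: np.ndarray,
    pos: tuple[float, float],
    radius: float,
    table_r: np.ndarray,
    table_v: np.ndarray,
    weight: float,
) -> None:
    h, w = canvas.shape
    y, x = pos
    y0 = max(int(np.floor(y - radius)), 0)
    y1 = min(int(np.ceil(y + radius)) + 1, h)
    x0 = max(int(np.floor(x - radius)), 0)
    x1 = min(int(np.ceil(x + radius)) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    rows = np.arange(y0, y1, dtype=np.float64) - y
    cols = np.arange(x0, x1, dtype=np.float64) - x
    rr = np.hypot(rows[:, None], cols[None, :])
    canvas[y0:y1, x0:x1] += weight * np.interp(rr, table_r, table_v, right=0.0)


def render_atoms(atoms: AiryAtomSet) -> np.ndarray:
    """Render ``g_n(r) = sum_k P_nk h_atom(r - r_nk)`` on the pixel grid.

    Linear in the amplitudes; each atom is an Airy profile of FWHM
    ``atom_fwhm`` with peak value equal to its amplitude, truncated at
    ``6 * atom_fwhm``.
    """
    table_r, table_v, r_max = _atom_table(atoms.atom_fwhm)
    canvas = np.zeros(atoms.frame_shape, dtype=np.float64)
    for pos, amp in zip(atoms.positions, atoms.amplitudes):
        _add_window(canvas, (pos[0], pos[1]), r_max, table_r, table_v, amp)
    return canvas


def model_convolve(image: np.ndarray, psf: PSFModel) -> np.ndarray:
    """Model-side PSF convolution: plain 'same' conv, zero background."""
    return fftconvolve(image, psf.kernel, mode="same")


def sai_objective(atoms: AiryAtomSet, psf: PSFModel, hp_frame: np.ndarray) -> float:
    """L1 objective ``F = sum_r |(g_n * h) - HP_n|``."""
    hp = np.asarray(hp_frame, dtype=np.float64)
    if hp.shape != atoms.frame_shape:
        raise ValueError(
            f"frame shape mismatch: atoms {atoms.frame_shape}, hp {hp.shape}"
        )
    model = model_convolve(render_atoms(atoms), psf)
    return float(np.abs(model - hp).sum())


def default_k(hp_frame: np.ndarray, d_sp: float) -> int:
    """Default atom count: one atom per ~2-grain area of the frame.

    The positive part of a fully developed speckle field holds roughly one
    grain per ``(2 d_sp)^2`` of area; the PSF blur merges several of those
    grains into each visible HP blob, so the count of HP local maxima badly
    underestimates the atoms needed and is deliberately not used as a cap.
    """
    h, w = hp_frame.shape
    return max(1, int(round(h * w / (2.0 * d_sp) ** 2)))


def _local_maxima(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions (rows, cols) of strictly positive local maxima, by value."""
    mask = (maximum_filter(frame, size=3, mode="nearest") == frame) & (frame > 0)
    rows, cols = np.nonzero(mask)
    order = np.argsort(frame[rows, cols])[::-1]
    return rows[order], cols[order]


# ---------------------------------------------------------------------------
# local search


class _ExactModel:
    """Exact objective evaluation: render + convolve per tentative move.

    Used in quantized mode so the search scores exactly the F of
    :func:`sai_objective` (with the closed-form flux scale applied).
    """

    def __init__(self, hp: np.ndarray, psf: PSFModel, d_sp: float) -> None:
        self.hp = hp
        self.hp_sum = float(hp.sum())
        self.shape = hp.shape
        self.psf = psf
        self.table_r, self.table_v, self.r_atom = _atom_table(d_sp)
        self.positions = np.zeros((0, 2))
        self.amplitudes = np.zeros(0)

    def _objective_of(self, positions: np.ndarray, amplitudes: np.ndarray) -> float:
        canvas = np.zeros(self.shape)
        for pos, amp in zip(positions, amplitudes):
            _add_window(
                canvas, (pos[0], pos[1]), self.r_atom, self.table_r, self.table_v, amp
            )
        m = fftconvolve(canvas, self.psf.kernel, mode="same")
        total = m.sum()
        s = self.hp_sum / total if total > 0 else 0.0
        return float(np.abs(s * m - self.hp).sum())

    def set_atoms(self, positions: np.ndarray, amplitudes: np.ndarray) -> None:
        self.positions = positions.copy()
        self.amplitudes = amplitudes.copy()

    def objective(self) -> float:
        return self._objective_of(self.positions, self.amplitudes)

    def try_move(self, index: int, pos: tuple[float, float], amp: float):
        cand_pos = self.positions.copy()
        cand_amp = self.amplitudes.copy()
        cand_pos[index] = pos
        cand_amp[index] = amp
        return self._objective_of(cand_pos, cand_amp), (cand_pos, cand_amp)

    def revert(self, index: int, token) -> None:
        pass

    def commit(self, index: int, token) -> None:
        self.positions, self.amplitudes = token

    def flux_scale(self) -> float:
        canvas = np.zeros(self.shape)
        for pos, amp in zip(self.positions, self.amplitudes):
            _add_window(
                canvas, (pos[0], pos[1]), self.r_atom, self.table_r, self.table_v, amp
            )
        total = fftconvolve(canvas, self.psf.kernel, mode="same").sum()
        return self.hp_sum / total if total > 0 else 0.0


class _IncrementalModel:
    """Maintains m = g*h and F = sum |s*m - hp| under single-atom updates.

    ``s`` is the closed-form flux scale sum(HP)/sum(m) recomputed after every
    tentative move.  Contributions of each atom are cached as (slices, array)
    so rejects revert exactly.
    """

    def __init__(self, hp: np.ndarray, psf: PSFModel, d_sp: float) -> None:
        self.hp = hp
        self.hp_sum = float(hp.sum())
        self.shape = hp.shape
        table_r, table_v, r_atom = _atom_table(d_sp)
        # radial profile of the blurred atom on a fine grid
        step = 0.25
        r_cut = r_atom + psf.support + 2.0
        n = int(np.ceil(r_cut / step))
        ax = (np.arange(2 * n + 1) - n) * step
        rr = np.hypot(ax[:, None], ax[None, :])
        atom_fine = np.interp(rr, table_r, table_v, right=0.0)
        psf_fine = airy_profile(rr, psf.d_psf)
        psf_fine /= psf_fine.sum() * step**2
        conv = fftconvolve(atom_fine, psf_fine, mode="same") * step**2
        prof = conv[n, n:]
        self.eprof_r = np.arange(len(prof)) * step
        self.eprof_v = prof
        # truncate the blurred atom where it falls below ~2e-4 of peak
        above = np.nonzero(prof >= 2e-4 * prof.max())[0]
        self.e_radius = float(min(self.eprof_r[above[-1]] + 1.0, self.eprof_r[-1]))
        self.m = np.zeros(self.shape, dtype=np.float64)
        self.contribs: list[tuple[tuple[slice, slice], np.ndarray]] = []

    def _contribution(
        self, pos: tuple[float, float], amp: float
    ) -> tuple[tuple[slice, slice], np.ndarray]:
        h, w = self.shape
        y, x = pos
        r = self.e_radius
        y0 = max(int(np.floor(y - r)), 0)
        y1 = min(int(np.ceil(y + r)) + 1, h)
        x0 = max(int(np.floor(x - r)), 0)
        x1 = min(int(np.ceil(x + r)) + 1, w)
        rows = np.arange(y0, y1, dtype=np.float64) - y
        cols = np.arange(x0, x1, dtype=np.float64) - x
        rr = np.hypot(rows[:, None], cols[None, :])
        win = amp * np.interp(rr, self.eprof_r, self.eprof_v, right=0.0)
        return (slice(y0, y1), slice(x0, x1)), win

    def set_atoms(self, positions: np.ndarray, amplitudes: np.ndarray) -> None:
        self.m[:] = 0.0
        self.contribs = []
        for pos, amp in zip(positions, amplitudes):
            sl, win = self._contribution((pos[0], pos[1]), float(amp))
            self.m[sl] += win
            self.contribs.append((sl, win))

    def objective(self) -> float:
        total = self.m.sum()
        s = self.hp_sum / total if total > 0 else 0.0
        return float(np.abs(s * self.m - self.hp).sum())

    def try_move(
        self, index: int, pos: tuple[float, float], amp: float
    ) -> tuple[float, tuple[tuple[slice, slice], np.ndarray]]:
        """Apply the move, return the new F and the new contribution."""
        old_sl, old_win = self.contribs[index]
        self.m[old_sl] -= old_win
        new_sl, new_win = self._contribution(pos, amp)
        self.m[new_sl] += new_win
        return self.objective(), (new_sl, new_win)

    def revert(self, index: int, new: tuple[tuple[slice, slice], np.ndarray]) -> None:
        new_sl, new_win = new
        self.m[new_sl] -= new_win
        old_sl, old_win = self.contribs[index]
        self.m[old_sl] += old_win

    def commit(self, index: int, new: tuple[tuple[slice, slice], np.ndarray]) -> None:
        self.contribs[index] = new

    def flux_scale(self) -> float:
        total = self.m.sum()
        return self.hp_sum / total if total > 0 else 0.0


def _init_positions(
    hp: np.ndarray, k: int, rng: np.random.Generator, quantize: bool, random_init: bool
) -> np.ndarray:
    h, w = hp.shape
    positions = np.empty((k, 2), dtype=np.float64)
    n_seeded = 0
    if not random_init:
        rows, cols = _local_maxima(hp)
        n_seeded = min(k, len(rows))
        positions[:n_seeded, 0] = rows[:n_seeded]
        positions[:n_seeded, 1] = cols[:n_seeded]
    for i in range(n_seeded, k):
        positions[i, 0] = rng.uniform(0, h - 1)
        positions[i, 1] = rng.uniform(0, w - 1)
    if quantize:
        positions = np.round(positions)
    return positions


def sai_fit_frame(
    hp_frame: np.ndarray,
    d_sp: float,
    psf: PSFModel,
    k: int | None = None,
    search: SearchParams | None = None,
    seed: int = 0,
    _trace_out: list[float] | None = None,
) -> AiryAtomSet:
    """Fit one HP frame with K Airy atoms by greedy stochastic local search.

    Initialization places atoms on the K largest HP local maxima (shortfall
    filled uniformly at random); each proposal perturbs one atom's position
    (uniform in a disc of radius ``d_sp``) and redraws its amplitude from a
    unit-mean exponential, accepting only strict decreases of F.  The search
    stops at the proposal budget or after ``stall_window`` consecutive
    rejections.  Deterministic given ``seed``.  An all-zero frame returns a
    zero-amplitude atom set flagged for exclusion from averaging.

    ``_trace_out``, if given, receives the objective value at initialization
    and after every accepted proposal (diagnostic hook).
    """
    hp = np.asarray(hp_frame, dtype=np.float64)
    if hp.ndim != 2:
        raise ValueError("hp_frame must be 2-D")
    sp = search or SearchParams()
    if k is None:
        k = default_k(hp, d_sp)
    if k < 1:
        raise ValueError("k must be >= 1")
    h, w = hp.shape

    if hp.sum() == 0:
        center = np.array([[(h - 1) / 2.0, (w - 1) / 2.0]] * k)
        return AiryAtomSet(
            positions=center,
            amplitudes=np.zeros(k),
            atom_fwhm=d_sp,
            frame_shape=(h, w),
            flagged_empty=True,
        )

    rng = np.random.default_rng(seed)
    radius = sp.proposal_radius if sp.proposal_radius is not None else d_sp
    budget = sp.max_proposals if sp.max_proposals is not None else 20 * k
    model = (
        _ExactModel(hp, psf, d_sp) if sp.quantize else _IncrementalModel(hp, psf, d_sp)
    )

    best_f = np.inf
    best_positions: np.ndarray | None = None
    best_amplitudes: np.ndarray | None = None
    best_scale = 0.0

    for restart in range(max(sp.n_restarts, 1)):
        positions = _init_positions(hp, k, rng, sp.quantize, random_init=restart > 0)
        amplitudes = rng.exponential(1.0, size=k)
        model.set_atoms(positions, amplitudes)
        f_cur = model.objective()
        if _trace_out is not None:
            _trace_out.append(f_cur)
        proposals = 0
        stalled = 0
        while proposals < budget and stalled < sp.stall_window:
            proposals += 1
            i = int(rng.integers(0, k))
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius * np.sqrt(rng.uniform(0, 1))
            ny = positions[i, 0] + rad * np.sin(ang)
            nx = positions[i, 1] + rad * np.cos(ang)
            if sp.quantize:
                ny, nx = round(ny), round(nx)
            if not (0 <= ny <= h - 1 and 0 <= nx <= w - 1):
                stalled += 1
                continue
            namp = rng.exponential(1.0)
            f_new, contrib = model.try_move(i, (ny, nx), namp)
            if f_new < f_cur:
                model.commit(i, contrib)
                positions[i] = (ny, nx)
                amplitudes[i] = namp
                f_cur = f_new
                stalled = 0
                if _trace_out is not None:
                    _trace_out.append(f_cur)
            else:
                model.revert(i, contrib)
                stalled += 1
        if f_cur < best_f:
            best_f = f_cur
            best_positions = positions.copy()
            best_amplitudes = amplitudes.copy()
            best_scale = model.flux_scale()

    assert best_positions is not None and best_amplitudes is not None
    return AiryAtomSet(
        positions=best_positions,
        amplitudes=best_amplitudes * best_scale,
        atom_fwhm=d_sp,
        frame_shape=(h, w),
    )


def sai_reconstruct(
    hp_stack: FrameStack,
    d_sp: float,
    psf: PSFModel,
    k: int | None = None,
    search: SearchParams | None = None,
    seed: int = 0,
    pixel_pitch: float | None = None,
) -> SAIResult:
    """Fit every HP frame independently and average the renderings.

    Frame fits share no state (parallelizable by contract); each frame gets
    a seed derived from ``seed``.  Frames flagged empty are skipped; if all
    frames are empty a "no signal" error is raised.  The reconstruction is
    the pixelwise mean of the rendered ``g_n`` over the used frames.
    """
    if hp_stack.n < 1:
        raise ValueError("need at least one frame")
    child_seeds = np.random.SeedSequence(seed).generate_state(hp_stack.n) % (2**31)
    atoms_list: list[AiryAtomSet] = []
    objectives: list[float] = []
    diagnostics: list[dict[str, Any]] = []
    acc = np.zeros(hp_stack.frame_shape, dtype=np.float64)
    n_used = 0
    for i in range(hp_stack.n):
        trace: list[float] = []
        atoms = sai_fit_frame(
            hp_stack.frames[i],
            d_sp,
            psf,
            k=k,
            search=search,
            seed=int(child_seeds[i]),
            _trace_out=trace,
        )
        atoms_list.append(atoms)
        if atoms.flagged_empty:
            objectives.append(float(np.abs(hp_stack.frames[i]).sum()))
            diagnostics.append({"frame": i, "flagged_empty": True, "trace": trace})
            continue
        objectives.append(sai_objective(atoms, psf, hp_stack.frames[i]))
        diagnostics.append(
            {
                "frame": i,
                "flagged_empty": False,
                "k": atoms.k,
                "acceptances": max(len(trace) - 1, 0),
                "seed": int(child_seeds[i]),
                "trace": trace,
            }
        )
        acc += render_atoms(atoms)
        n_used += 1
    if n_used == 0:
        raise ValueError("no signal: every HP frame is empty")
    g = acc / n_used
    pitch = pixel_pitch if pixel_pitch is not None else 1.0 / psf.d_psf
    return SAIResult(
        per_frame_atoms=atoms_list,
        per_frame_objective=objectives,
        reconstruction=DensityMap(pixels=g, pixel_pitch=pitch),
        diagnostics=diagnostics,
        n_used=n_used,
    )
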