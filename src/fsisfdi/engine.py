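"""Single-pixel acquisition and image reconstruction.

A bucket detector measures one number per projected pattern: the inner
product of the pattern with the scene.  Probing one Fourier coefficient
``(fx, fy)`` with four pattern phases (0, pi/2, pi, 3pi/2) and differencing,

    C(fx, fy) = (D_0 - D_pi) + j * (D_pi/2 - D_3pi/2),

yields ``2*b`` times the discrete Fourier transform of the scene at that
index — the pattern mean ``a`` cancels in the differences.  The spectrum is
completed by conjugate symmetry and inverted either directly (inverse FFT of
the zero-filled spectrum) or by a total-variation-regularized least-squares
solver for undersampled masks.

Because the four-step assembly is algebraically identical to ``2b * DFT``,
acquisition offers a fast FFT path (the default) and a literal
pattern-by-pattern bucket path (``method="bucket"``) kept as the physical
oracle; both are tested to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .patterns import (
    PatternSpec,
    SamplingMask,
    SFDISpec,
    conjugate_index,
    fourier_basis_pattern,
    sfdi_illumination,
)

__all__ = [
    "BucketSignal",
    "Spectrum",
    "ReconConfig",
    "CSResult",
    "measure",
    "four_step_coefficient",
    "acquire_spectrum",
    "reconstruct_ifft",
    "reconstruct_cs_tv",
    "save_spectrum",
    "load_spectrum",
]

FOUR_STEP_PHASES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


@dataclass(frozen=True)
class BucketSignal:
    """One detector reading and the (fx, fy, phase) pattern that produced it."""

    value: float
    pattern_id: tuple[int, int, float]


@dataclass
class Spectrum:
    """Fourier coefficients assembled from bucket measurements.

    ``grid`` is an M×N complex array in DFT (corner-origin) layout holding
    ``2*b*DFT`` coefficients at measured indices and their conjugate
    partners, zero elsewhere.  ``b`` is the pattern contrast used during
    acquisition, needed to undo the ``2b`` factor on reconstruction.
    """

    grid: np.ndarray
    mask: SamplingMask
    b: float
    filled: bool = False

    @property
    def pattern_count(self) -> int:
        return self.mask.pattern_count


@dataclass(frozen=True)
class ReconConfig:
    """Settings for the TV-regularized reconstruction (see Eq. below).

    ``lambda1`` (sparsity) and ``lambda2`` (total variation) are relative to
    the scene's mean intensity; the solver multiplies them by the DC-derived
    mean so the defaults transfer across intensity scales.
    """

    method: str = "cs_tv"
    lambda1: float = 0.0
    lambda2: float = 1e-3
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CSResult:
    """TV reconstruction output with solver diagnostics."""

    image: np.ndarray
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

def measure(object_image: np.ndarray, pattern: np.ndarray,
            pattern_id: tuple[int, int, float] = (0, 0, 0.0)) -> BucketSignal:
    """Bucket-detector reading: the full-frame inner product of pattern and
    scene.  Linear in both arguments; nonnegative when both are."""
    object_image = np.asarray(object_image, dtype=float)
    pattern = np.asarray(pattern, dtype=float)
    if object_image.shape != pattern.shape:
        raise ValueError(
            f"shape mismatch: object {object_image.shape} vs pattern {pattern.shape}"
        )
    return BucketSignal(float(np.sum(pattern * object_image)), pattern_id)


def four_step_coefficient(d0: float, d_half_pi: float, d_pi: float,
                          d_3half_pi: float) -> complex:
    """Complex Fourier coefficient from the four phase-shifted readings."""
    return complex(d0 - d_pi) + 1j * (d_half_pi - d_3half_pi)


def _is_self_conjugate(fx: int, fy: int, M: int, N: int) -> bool:
    return conjugate_index(fx, fy, M, N) == (fx, fy)


def acquire_spectrum(
    object_image: np.ndarray,
    mask: SamplingMask,
    a: float = 0.5,
    b: float = 0.5,
    sfdi: SFDISpec | None = None,
    method: str = "fft",
) -> Spectrum:
    """Acquire the masked Fourier spectrum of a scene by four-step FSI.

    When `sfdi` is given, every projected pattern is the product of the SFDI
    illumination and the Fourier basis pattern, so the assembled spectrum is
    that of the illuminated scene (the modulated image).  ``method="fft"``
    exploits the exact identity C = 2b·DFT; ``method="bucket"`` projects the
    four patterns per coefficient literally and sums pixels.
    """
    obj = np.asarray(object_image, dtype=float)
    if obj.ndim != 2:
        raise ValueError(f"object must be 2-D, got shape {obj.shape}")
    if obj.shape != mask.shape:
        raise ValueError(f"shape mismatch: object {obj.shape} vs mask {mask.shape}")
    if np.any(obj < 0):
        raise ValueError("object must be nonnegative")
    M, N = obj.shape
    effective = obj if sfdi is None else sfdi_illumination(sfdi, obj.shape) * obj

    grid = np.zeros((M, N), dtype=complex)
    if method == "fft":
        F = np.fft.fft2(effective)
        sel = np.array(sorted(mask.selected), dtype=int).reshape(-1, 2)
        if len(sel):
            grid[sel[:, 0], sel[:, 1]] = 2.0 * b * F[sel[:, 0], sel[:, 1]]
    elif method == "bucket":
        for fx, fy in mask.selected:
            readings = []
            for phase in FOUR_STEP_PHASES:
                pat = fourier_basis_pattern(PatternSpec(a, b, fx, fy, phase, M, N))
                if sfdi is not None:
                    pat = sfdi_illumination(sfdi, obj.shape) * pat
                readings.append(measure(obj, pat, (fx, fy, phase)).value)
            d0, dh, dp, d3 = readings
            grid[fx, fy] = four_step_coefficient(d0, dh, dp, d3)
    else:
        raise ValueError(f"unknown acquisition method {method!r}")

    # conjugate completion; real-image constraint on self-conjugate points
    sel = np.array(sorted(mask.selected), dtype=int).reshape(-1, 2)
    if len(sel):
        cx, cy = (-sel[:, 0]) % M, (-sel[:, 1]) % N
        self_conj = (cx == sel[:, 0]) & (cy == sel[:, 1])
        sc = sel[self_conj]
        grid[sc[:, 0], sc[:, 1]] = grid[sc[:, 0], sc[:, 1]].real
        pr = sel[~self_conj]
        grid[(-pr[:, 0]) % M, (-pr[:, 1]) % N] = np.conj(grid[pr[:, 0], pr[:, 1]])
    return Spectrum(grid=grid, mask=mask, b=b, filled=True)


# --------------------------------------------------------------------------
# reconstruction
# --------------------------------------------------------------------------

def reconstruct_ifft(spectrum: Spectrum) -> np.ndarray:
    """Zero-filled inverse-DFT reconstruction.

    The unnormalized inverse transform divided by ``2b`` returns the scene
    exactly at full sampling; the vanishing imaginary residue of the
    conjugate-symmetric spectrum is discarded and negatives are clipped.
    """
    if not spectrum.filled:
        raise RuntimeError("spectrum must be conjugate-filled before inversion")
    img = np.fft.ifft2(spectrum.grid) / (2.0 * spectrum.b)
    return np.clip(img.real, 0.0, None)


def _grad(u: np.ndarray) -> np.ndarray:
    """Forward differences with Neumann boundary, stacked (2, M, N)."""
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1, :] = u[1:, :] - u[:-1, :]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return np.stack([gx, gy])


def _div(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_grad`."""
    px, py = p
    dx = np.zeros_like(px)
    dx[0, :] = px[0, :]
    dx[1:-1, :] = px[1:-1, :] - px[:-2, :]
    dx[-1, :] = -px[-2, :]
    dy = np.zeros_like(py)
    dy[:, 0] = py[:, 0]
    dy[:, 1:-1] = py[:, 1:-1] - py[:, :-2]
    dy[:, -1] = -py[:, -2]
    return dx + dy


def total_variation(u: np.ndarray) -> float:
    """Isotropic discrete total variation of `u`."""
    g = _grad(u)
    return float(np.sqrt(g[0] ** 2 + g[1] ** 2).sum())


def _tv_prox(v: np.ndarray, weight: float, n_iter: int = 30) -> np.ndarray:
    """Chambolle dual iteration for min_u 0.5||u-v||^2 + weight*TV(u)."""
    if weight <= 0:
        return v.copy()
    p = np.zeros((2,) + v.shape)
    tau = 0.25
    for _ in range(n_iter):
        g = _grad(_div(p) - v / weight)
        denom = 1.0 + tau * np.sqrt(g[0] ** 2 + g[1] ** 2)
        p = (p + tau * g) / denom
    return v - weight * _div(p)


def reconstruct_cs_tv(spectrum: Spectrum, config: ReconConfig | None = None) -> CSResult:
    """Approximate minimizer of the undersampled-spectrum objective

        ||F t - T'||^2 + lambda1*||t||_1 + lambda2*TV(t)

    where F restricts the (orthonormal) Fourier transform to the measured
    coefficient set and T' is the acquired data.  Solved by monotone
    proximal-gradient descent with backtracking: a step is only accepted if
    the objective does not increase, so the recorded objective history is
    nonincreasing by construction.  Non-convergence within ``max_iter`` sets
    ``converged=False`` on the result instead of raising.
    """
    if config is None:
        config = ReconConfig()
    if not spectrum.filled:
        raise RuntimeError("spectrum must be conjugate-filled before inversion")
    M, N = spectrum.grid.shape
    root = np.sqrt(M * N)
    mask_full = spectrum.mask.dense(conjugate_filled=True)
    Y = spectrum.grid / (2.0 * spectrum.b) / root  # ortho-normalized data

    dc = abs(spectrum.grid[0, 0]) / (2.0 * spectrum.b * M * N)
    scale = dc if dc > 0 else 1.0
    lam1 = config.lambda1 * scale
    lam2 = config.lambda2 * scale

    def objective(t: np.ndarray) -> float:
        r = (np.fft.fft2(t, norm="ortho") * mask_full) - Y * mask_full
        fid = float(np.sum(np.abs(r) ** 2))
        reg1 = lam1 * float(np.abs(t).sum()) if lam1 > 0 else 0.0
        reg2 = lam2 * total_variation(t) if lam2 > 0 else 0.0
        return fid + reg1 + reg2

    def prox(v: np.ndarray, step: float) -> np.ndarray:
        if lam1 > 0:
            v = np.sign(v) * np.maximum(np.abs(v) - step * lam1, 0.0)
        if lam2 > 0:
            v = _tv_prox(v, step * lam2)
        return v

    t = reconstruct_ifft(spectrum)
    result = CSResult(image=t)
    J = objective(t)
    result.objective.append(J)
    step = 0.5  # 1/L for the ortho-masked fidelity (L = 2)
    converged = False
    for it in range(config.max_iter):
        r = (np.fft.fft2(t, norm="ortho") * mask_full) - Y * mask_full
        g = 2.0 * np.fft.ifft2(r * mask_full, norm="ortho").real
        accepted = False
        s = step
        for _ in range(20):
            cand = prox(t - s * g, s)
            Jc = objective(cand)
            if Jc <= J:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
        rel_drop = (J - Jc) / max(abs(J), 1e-300)
        t, J = cand, Jc
        result.objective.append(J)
        result.n_iter = it + 1
        if rel_drop < config.tol:
            converged = True
            break
    result.converged = bool(converged or J == 0.0)
    result.image = np.clip(t, 0.0, None)
    return result


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write the complex grid as a two-page float32 TIFF (real, imaginary)."""
    path = Path(path)
    pages = np.stack([spectrum.grid.real, spectrum.grid.imag]).astype(np.float32)
    tifffile.imwrite(path, pages, metadata={"b": spectrum.b})


def load_spectrum(path: str | Path, mask: SamplingMask, b: float = 0.5) -> Spectrum:
    """Read a spectrum written by :func:`save_spectrum` (mask from its sidecar)."""
    pages = tifffile.imread(path)
    grid = pages[0].astype(float) + 1j * pages[1].astype(float)
    return Spectrum(grid=grid, mask=mask, b=b, filled=True)
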