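"""Three-phase demodulation, reflectance calibration, and lookup-table
inversion to optical properties.

SFDI recovers per-pixel absorption (mu_a) and reduced scattering (mu_s')
from the diffuse reflectance Rd measured at two spatial frequencies: a
planar (DC, typically 0 /mm) and a modulated (AC, typically 0.2 /mm)
illumination.  Three phase-shifted images per frequency are demodulated to
amplitude maps, calibrated against a reference phantom of known reflectance,
and the resulting (Rd_dc, Rd_ac) pair is inverted through a forward model of
spatially modulated diffuse reflectance.

The forward model here is the standard diffusion approximation for a
semi-infinite homogeneous turbid medium under sinusoidal illumination:

    Rd(f) = 3 A a' / ((mu_eff'/mu_tr + 1) (mu_eff'/mu_tr + 3A))

with transport coefficient mu_tr = mu_a + mu_s', reduced albedo
a' = mu_s'/mu_tr, scalar attenuation mu_eff' = sqrt(3 mu_a mu_tr +
(2 pi f)^2), and A the internal-reflection parameter derived from the tissue
refractive index.  The model is tabulated on a (mu_a, mu_s') grid once; each
pixel's inversion is seeded by the nearest tabulated (Rd_dc, Rd_ac) pair and
refined by a damped Newton iteration on the closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MIStack",
    "RdMaps",
    "RdLUT",
    "OpticalMap",
    "demodulate_ac",
    "demodulate_dc",
    "calibrate",
    "diffusion_rd",
    "build_lut",
    "default_lut",
    "invert_lut",
    "save_lut",
    "load_lut",
]

DEFAULT_PHASES = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


@dataclass
class MIStack:
    """Six modulated images: three phases at the DC and the AC frequency.

    ``dc`` and ``ac`` are (3, M, N) arrays ordered like ``phases``;
    ``pixel_pitch`` is in mm/pixel, frequencies in 1/mm.
    """

    dc: np.ndarray
    ac: np.ndarray
    phases: tuple[float, float, float] = DEFAULT_PHASES
    f_dc: float = 0.0
    f_ac: float = 0.2
    pixel_pitch: float = 0.25

    def __post_init__(self) -> None:
        self.dc = np.asarray(self.dc, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        if self.dc.shape != self.ac.shape or self.dc.ndim != 3 or self.dc.shape[0] != 3:
            raise ValueError(
                f"expected two (3, M, N) stacks, got dc {self.dc.shape}, ac {self.ac.shape}"
            )
        if np.any(self.dc < 0) or np.any(self.ac < 0):
            raise ValueError("modulated images must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dc.shape[1:]


@dataclass
class RdMaps:
    """Calibrated diffuse-reflectance maps at the two spatial frequencies."""

    rd_dc: np.ndarray
    rd_ac: np.ndarray


@dataclass
class OpticalMap:
    """Per-pixel optical properties in 1/mm with an in-range validity flag."""

    mua: np.ndarray
    musp: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mua = np.asarray(self.mua, dtype=float)
        self.musp = np.asarray(self.musp, dtype=float)
        if self.mua.shape != self.musp.shape:
            raise ValueError("mua and musp must have the same shape")
        if self.valid is None:
            self.valid = np.ones(self.mua.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mua.shape


# --------------------------------------------------------------------------
# demodulation and calibration
# --------------------------------------------------------------------------

def _check_three(i1, i2, i3):
    a1, a2, a3 = (np.asarray(i, dtype=float) for i in (i1, i2, i3))
    if not (a1.shape == a2.shape == a3.shape):
        raise ValueError(
            f"phase images must share a shape, got {a1.shape}, {a2.shape}, {a3.shape}"
        )
    return a1, a2, a3


def demodulate_ac(i1, i2, i3) -> np.ndarray:
    """AC amplitude of a three-phase stack (phases 0, 2pi/3, 4pi/3).

    The sqrt(2)/3 prefactor makes the result equal the sinusoid amplitude:
    for I_k = DC + A cos(theta + phi_k) the bracketed sum is (9/2) A^2.
    """
    a1, a2, a3 = _check_three(i1, i2, i3)
    return (np.sqrt(2.0) / 3.0) * np.sqrt(
        (a1 - a2) ** 2 + (a2 - a3) ** 2 + (a3 - a1) ** 2
    )


def demodulate_dc(i1, i2, i3) -> np.ndarray:
    """DC amplitude: the mean of the three phase images."""
    a1, a2, a3 = _check_three(i1, i2, i3)
    return (a1 + a2 + a3) / 3.0


def calibrate(m: np.ndarray, m_ref: np.ndarray, rd_ref_value: float) -> np.ndarray:
    """Diffuse reflectance from amplitude ratio against a known reference.

    ``Rd = (M / M_ref) * Rd_ref``; any demodulation prefactor or source
    intensity common to sample and reference cancels in the ratio.  Pixels
    where the reference amplitude is zero are returned as NaN (flagged
    invalid downstream).
    """
    m = np.asarray(m, dtype=float)
    m_ref = np.asarray(m_ref, dtype=float)
    if m.shape != m_ref.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {m_ref.shape}")
    if not 0.0 < rd_ref_value <= 1.0:
        raise ValueError(f"reference reflectance must be in (0, 1], got {rd_ref_value}")
    if np.all(m_ref == 0):
        raise ValueError("reference amplitude is zero everywhere")
    out = np.full(m.shape, np.nan)
    ok = m_ref > 0
    out[ok] = m[ok] / m_ref[ok] * rd_ref_value
    return out


# --------------------------------------------------------------------------
# diffusion forward model
# --------------------------------------------------------------------------

def _internal_reflection_A(n_index: float) -> float:
    """Internal-reflection parameter from the effective reflection
    coefficient polynomial R_eff(n)."""
    r_eff = 0.0636 * n_index + 0.668 + 0.710 / n_index - 1.440 / n_index**2
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


def diffusion_rd(mua, musp, fx: float, n_index: float = 1.4):
    """Diffuse reflectance of a semi-infinite medium at spatial frequency
    `fx` (1/mm).  Vectorized over ``mua``/``musp`` arrays (1/mm)."""
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(mua <= 0) or np.any(musp <= 0):
        raise ValueError("optical coefficients must be > 0")
    if fx < 0:
        raise ValueError(f"spatial frequency must be >= 0, got {fx}")
    A = _internal_reflection_A(n_index)
    mutr = mua + musp
    mueff = np.sqrt(3.0 * mua * mutr + (2.0 * np.pi * fx) ** 2)
    u = mueff / mutr
    rd = 3.0 * A * (musp / mutr) / ((u + 1.0) * (u + 3.0 * A))
    return rd if rd.ndim else float(rd)


@dataclass
class RdLUT:
    """Tabulated forward model over a (mu_a, mu_s') grid at two frequencies."""

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    rd_dc: np.ndarray  # (len(mua_grid), len(musp_grid))
    rd_ac: np.ndarray
    f_dc: float
    f_ac: float
    n_index: float


def build_lut(
    mua_grid: np.ndarray,
    musp_grid: np.ndarray,
    f_dc: float = 0.0,
    f_ac: float = 0.2,
    n_index: float = 1.4,
) -> RdLUT:
    """Tabulate :func:`diffusion_rd` over the grid outer product.

    Validates that every planar-frequency row is strictly decreasing in mu_a
    (more absorption, less reflectance) and that all entries are physical
    (0 < Rd < 1).  At the modulated frequency the diffusion model has a
    shallow (~1e-4) non-monotonic ridge at low albedo (mu_s' below ~0.6/mm
    for f = 0.2/mm), so the AC table is only required to be decreasing
    within that model-intrinsic slack.
    """
    mua_grid = np.asarray(mua_grid, dtype=float)
    musp_grid = np.asarray(musp_grid, dtype=float)
    for g, name in ((mua_grid, "mua_grid"), (musp_grid, "musp_grid")):
        if np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be positive and strictly increasing")
    ma = mua_grid[:, None]
    ms = musp_grid[None, :]
    rd_dc = diffusion_rd(ma, ms, f_dc, n_index)
    rd_ac = diffusion_rd(ma, ms, f_ac, n_index)
    if np.any(np.diff(rd_dc, axis=0) >= 0):
        raise RuntimeError("planar LUT not strictly decreasing in mua; grid invalid")
    if np.any(np.diff(rd_ac, axis=0) >= 5e-4):
        raise RuntimeError("modulated LUT rises in mua beyond model slack; grid invalid")
    for tab in (rd_dc, rd_ac):
        if np.any(tab <= 0) or np.any(tab >= 1):
            raise RuntimeError("LUT entries outside (0, 1)")
    return RdLUT(mua_grid, musp_grid, rd_dc, rd_ac, f_dc, f_ac, n_index)


def default_lut(n_mua: int = 100, n_musp: int = 100, f_dc: float = 0.0,
                f_ac: float = 0.2, n_index: float = 1.4) -> RdLUT:
    """Log-spaced default grid: mu_a in [0.001, 0.5], mu_s' in [0.1, 5] /mm."""
    mua = np.geomspace(0.001, 0.5, n_mua)
    musp = np.geomspace(0.1, 5.0, n_musp)
    return build_lut(mua, musp, f_dc, f_ac, n_index)


# --------------------------------------------------------------------------
# inversion
# --------------------------------------------------------------------------

def invert_lut(rd_maps: RdMaps, lut: RdLUT, max_iter: int = 25,
               tol: float = 1e-12) -> OpticalMap:
    """Map (Rd_dc, Rd_ac) pixel pairs to (mu_a, mu_s').

    Each pixel is seeded with the tabulated grid node nearest in
    (Rd_dc, Rd_ac) (KD-tree) and refined by a damped Newton iteration on the
    closed-form forward model with finite-difference Jacobians.  Pixels with
    nonfinite reflectance, a boundary-node seed, or an out-of-grid result
    are flagged invalid (never raised); results are clamped to the grid.
    """
    rd_dc = np.asarray(rd_maps.rd_dc, dtype=float)
    rd_ac = np.asarray(rd_maps.rd_ac, dtype=float)
    if rd_dc.shape != rd_ac.shape:
        raise ValueError("rd_dc and rd_ac must have the same shape")
    shape = rd_dc.shape
    tdc = rd_dc.ravel()
    tac = rd_ac.ravel()
    finite = np.isfinite(tdc) & np.isfinite(tac)

    na, ns = len(lut.mua_grid), len(lut.musp_grid)
    nodes = np.column_stack([lut.rd_dc.ravel(), lut.rd_ac.ravel()])
    tree = cKDTree(nodes)
    query = np.column_stack([np.where(finite, tdc, 0.0), np.where(finite, tac, 0.0)])
    _, idx = tree.query(query)
    ia, is_ = np.unravel_index(idx, (na, ns))
    boundary = (ia == 0) | (ia == na - 1) | (is_ == 0) | (is_ == ns - 1)

    mua = lut.mua_grid[ia].astype(float)
    musp = lut.musp_grid[is_].astype(float)
    lo_a, hi_a = lut.mua_grid[0], lut.mua_grid[-1]
    lo_s, hi_s = lut.musp_grid[0], lut.musp_grid[-1]

    def fwd(ma, ms, f):
        return diffusion_rd(np.maximum(ma, 1e-12), np.maximum(ms, 1e-12), f, lut.n_index)

    clipped = np.zeros(mua.shape, dtype=bool)
    for _ in range(max_iter):
        r1 = fwd(mua, musp, lut.f_dc) - np.where(finite, tdc, 0.0)
        r2 = fwd(mua, musp, lut.f_ac) - np.where(finite, tac, 0.0)
        da = mua * 1e-6
        ds = musp * 1e-6
        j11 = (fwd(mua + da, musp, lut.f_dc) - fwd(mua - da, musp, lut.f_dc)) / (2 * da)
        j12 = (fwd(mua, musp + ds, lut.f_dc) - fwd(mua, musp - ds, lut.f_dc)) / (2 * ds)
        j21 = (fwd(mua + da, musp, lut.f_ac) - fwd(mua - da, musp, lut.f_ac)) / (2 * da)
        j22 = (fwd(mua, musp + ds, lut.f_ac) - fwd(mua, musp - ds, lut.f_ac)) / (2 * ds)
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        du = (j22 * r1 - j12 * r2) / det
        dv = (-j21 * r1 + j11 * r2) / det
        du = np.nan_to_num(du)
        dv = np.nan_to_num(dv)
        # damped update, at most a factor-of-2 relative move per iteration
        du = np.clip(du, -0.5 * mua, 0.5 * mua)
        dv = np.clip(dv, -0.5 * musp, 0.5 * musp)
        new_a = mua - du
        new_s = musp - dv
        clipped |= (new_a < lo_a) | (new_a > hi_a) | (new_s < lo_s) | (new_s > hi_s)
        mua = np.clip(new_a, lo_a, hi_a)
        musp = np.clip(new_s, lo_s, hi_s)
        if max(np.max(np.abs(du) / mua), np.max(np.abs(dv) / musp)) < tol:
            break

    valid = finite & ~boundary & ~clipped
    return OpticalMap(
        mua.reshape(shape), musp.reshape(shape), valid.reshape(shape)
    )


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_lut(lut: RdLUT, path: str | Path) -> None:
    """Persist the table as an NPZ archive plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path, mua_grid=lut.mua_grid, musp_grid=lut.musp_grid,
             rd_dc=lut.rd_dc, rd_ac=lut.rd_ac)
    meta = {"f_dc": lut.f_dc, "f_ac": lut.f_ac, "n_index": lut.n_index}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_lut(path: str | Path) -> RdLUT:
    path = Path(path)
    arch = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return RdLUT(arch["mua_grid"], arch["musp_grid"], arch["rd_dc"], arch["rd_ac"],
                 meta["f_dc"], meta["f_ac"], meta["n_index"])
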