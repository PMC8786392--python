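"""Fourier basis patterns, SFDI illumination, and spectrum sampling masks.

A Fourier single-pixel camera projects cosine patterns

    P(x, y) = a + b * cos(2*pi*fx*x/M + 2*pi*fy*y/N + phase)

onto the scene and records the total reflected intensity with a bucket
detector.  For spatial-frequency-domain imaging the basis pattern is
multiplied by a one-dimensional sinusoidal illumination field

    S(x) = 0.5 * (1 + cos(2*pi*fk*x*pitch + phase1))

so that a single projected pattern performs both the structured SFDI
illumination and the single-pixel encoding.

Frequencies ``(fx, fy)`` are integer cycles per frame, stored as DFT
(corner-origin) indices.  Because the scene is real-valued its spectrum is
conjugate symmetric, so only one canonical representative per conjugate pair
needs to be measured.  This module defines that canonical *half-plane* and
three strategies for choosing a measurement budget's worth of coefficients
from it: a deterministic low-frequency disc, uniform random selection, and
variable-density random selection weighted toward low frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "PatternSpec",
    "SFDISpec",
    "SamplingMask",
    "fourier_basis_pattern",
    "sfdi_illumination",
    "modulation_pattern",
    "half_plane_indices",
    "conjugate_index",
    "circular_mask",
    "uniform_random_mask",
    "variable_density_mask",
    "full_mask",
    "save_mask",
    "load_mask",
]


# --------------------------------------------------------------------------
# pattern specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternSpec:
    """One Fourier basis pattern: mean ``a``, contrast ``b``, integer
    frequencies ``(fx, fy)`` in cycles per frame, initial ``phase`` in
    radians, frame size ``(M, N)`` in pixels."""

    a: float
    b: float
    fx: int
    fy: int
    phase: float
    M: int
    N: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ValueError(f"pattern dimensions must be >= 1, got {self.M}x{self.N}")
        if self.a < 0:
            raise ValueError(f"mean intensity a must be >= 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"contrast b must be > 0, got {self.b}")


@dataclass(frozen=True)
class SFDISpec:
    """Sinusoidal SFDI illumination: spatial frequency ``fk`` in 1/mm,
    illumination phase ``phase1`` in radians, ``pixel_pitch`` in mm/pixel."""

    fk: float
    phase1: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        if self.fk < 0:
            raise ValueError(f"SFDI frequency must be >= 0, got {self.fk}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel pitch must be > 0, got {self.pixel_pitch}")


def fourier_basis_pattern(spec: PatternSpec) -> np.ndarray:
    """Evaluate the cosine basis pattern of `spec` on its (M, N) grid.

    The first array axis is x, the second y; coordinates are 0-based, so
    ``out[x, y] = a + b*cos(2*pi*(fx*x/M + fy*y/N) + phase)``.
    """
    x = np.arange(spec.M)[:, None]
    y = np.arange(spec.N)[None, :]
    theta = 2.0 * np.pi * (spec.fx * x / spec.M + spec.fy * y / spec.N) + spec.phase
    return spec.a + spec.b * np.cos(theta)


def sfdi_illumination(spec: SFDISpec, shape: tuple[int, int]) -> np.ndarray:
    """SFDI illumination field on `shape`, varying along the first (x) axis.

    Values lie in [0, 1]; at ``fk = 0, phase1 = 0`` the field is constant 1.
    """
    M, N = shape
    if M < 1 or N < 1:
        raise ValueError(f"shape must be positive, got {shape}")
    x = np.arange(M)[:, None] * spec.pixel_pitch
    field_1d = 0.5 * (1.0 + np.cos(2.0 * np.pi * spec.fk * x + spec.phase1))
    return np.broadcast_to(field_1d, (M, N)).copy()


def modulation_pattern(pspec: PatternSpec, sspec: SFDISpec) -> np.ndarray:
    """Projected pattern combining SFDI illumination and Fourier encoding.

    Pixelwise product of :func:`sfdi_illumination` and
    :func:`fourier_basis_pattern`; a single projection of this pattern
    simultaneously modulates the scene at ``fk`` and probes Fourier
    coefficient ``(fx, fy)``.
    """
    basis = fourier_basis_pattern(pspec)
    illum = sfdi_illumination(sspec, (pspec.M, pspec.N))
    return illum * basis


# --------------------------------------------------------------------------
# the measured half-plane
# --------------------------------------------------------------------------

def conjugate_index(fx: int, fy: int, M: int, N: int) -> tuple[int, int]:
    """DFT index of the conjugate partner of ``(fx, fy)`` on an M×N grid."""
    return (-fx) % M, (-fy) % N


def _centered(f: int, n: int) -> int:
    """Signed frequency of DFT index `f` (Nyquist mapped to -n/2)."""
    return f - n if f >= (n + 1) // 2 else f


@lru_cache(maxsize=8)
def half_plane_indices(shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Canonical representatives, one per conjugate pair, for an M×N grid.

    An index is canonical when it is lexicographically <= its conjugate
    partner in DFT coordinates; self-conjugate points (DC and, for even
    sizes, the Nyquist corners) are canonical once.  For even M, N this
    yields ``M*N/2 + 2`` indices.  Returned sorted by
    (radius, centered fy, centered fx) so a prefix of the list is the
    deterministic low-frequency disc.
    """
    M, N = shape
    fx, fy = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    gx, gy = (-fx) % M, (-fy) % N
    canonical = (fx < gx) | ((fx == gx) & (fy <= gy))
    cx = np.where(fx >= (M + 1) // 2, fx - M, fx)
    cy = np.where(fy >= (N + 1) // 2, fy - N, fy)
    radius = np.hypot(cx, cy)
    sel = np.nonzero(canonical.ravel())[0]
    order = np.lexsort((cx.ravel()[sel], cy.ravel()[sel], radius.ravel()[sel]))
    sel = sel[order]
    return [(int(i), int(j)) for i, j in zip(sel // N, sel % N)]


def _radius(idx, shape):
    fx, fy = idx
    cx, cy = _centered(fx, shape[0]), _centered(fy, shape[1])
    return float(np.hypot(cx, cy))


# --------------------------------------------------------------------------
# sampling masks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingMask:
    """A budgeted selection of half-plane Fourier coefficients.

    ``selected`` holds DFT (corner-origin) ``(fx, fy)`` indices; each costs
    four projected patterns (four-step phase shifting), so
    ``4 * len(selected) <= budget``.
    """

    shape: tuple[int, int]
    selected: frozenset[tuple[int, int]]
    scheme: str
    budget: int
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def pattern_count(self) -> int:
        """Number of projected patterns this mask costs (4 per coefficient)."""
        return 4 * len(self.selected)

    @property
    def sampling_rate(self) -> float:
        """Pattern budget over pixel count (2.0 means every conjugate pair)."""
        return self.budget / (self.shape[0] * self.shape[1])

    def dense(self, conjugate_filled: bool = False) -> np.ndarray:
        """Boolean array in DFT layout; optionally include conjugate partners."""
        m = np.zeros(self.shape, dtype=bool)
        for fx, fy in self.selected:
            m[fx, fy] = True
            if conjugate_filled:
                m[conjugate_index(fx, fy, *self.shape)] = True
        return m


def _validate_budget(budget: int) -> int:
    if budget < 4:
        raise ValueError(f"budget must be >= 4 (one four-step coefficient), got {budget}")
    return budget // 4


def circular_mask(shape: tuple[int, int], budget: int) -> SamplingMask:
    """Deterministic low-frequency disc: the ``budget // 4`` half-plane
    coefficients of smallest frequency radius, ties broken by
    (radius, centered fy, centered fx)."""
    shape = (int(shape[0]), int(shape[1]))
    k = _validate_budget(budget)
    half = half_plane_indices(shape)  # already radius-sorted
    k = min(k, len(half))
    return SamplingMask(shape, frozenset(half[:k]), "circular", budget)


def full_mask(shape: tuple[int, int]) -> SamplingMask:
    """Every half-plane coefficient (exact, lossless acquisition).

    For even M, N the pattern count is ``2*M*N + 8``: the four self-conjugate
    coefficients each still cost a four-step measurement, a constant excess
    over the 2·M·N pairs-only count.
    """
    shape = (int(shape[0]), int(shape[1]))
    half = half_plane_indices(shape)
    return SamplingMask(shape, frozenset(half), "full", 4 * len(half))


def uniform_random_mask(shape: tuple[int, int], budget: int, seed: int) -> SamplingMask:
    """DC plus ``budget//4 - 1`` half-plane coefficients drawn uniformly
    without replacement; reproducible for a fixed seed."""
    shape = (int(shape[0]), int(shape[1]))
    k = _validate_budget(budget)
    half = half_plane_indices(shape)
    if k > len(half):
        raise ValueError(
            f"budget {budget} exceeds the {4 * len(half)} patterns of full sampling"
        )
    rng = np.random.default_rng(seed)
    rest = [h for h in half if h != (0, 0)]
    picks = rng.choice(len(rest), size=k - 1, replace=False)
    sel = {(0, 0)} | {rest[i] for i in picks}
    return SamplingMask(shape, frozenset(sel), "uniform_random", budget, seed)


def variable_density_mask(
    shape: tuple[int, int],
    budget: int,
    R: float = 0.1,
    p: float = 6.0,
    seed: int = 0,
) -> SamplingMask:
    """Variable-density random selection.

    All half-plane coefficients with normalized radius ``r <= R`` (radius
    over the maximum corner distance) are always included; the remaining
    budget is filled by weighted sampling without replacement with weight
    ``(1 - r)**p``, concentrating picks near DC.
    """
    if not 0.0 < R < 1.0:
        raise ValueError(f"R must be in (0, 1), got {R}")
    if p < 0:
        raise ValueError(f"p must be >= 0, got {p}")
    shape = (int(shape[0]), int(shape[1]))
    k = _validate_budget(budget)
    half = half_plane_indices(shape)
    if k > len(half):
        raise ValueError(
            f"budget {budget} exceeds the {4 * len(half)} patterns of full sampling"
        )
    rmax = float(np.hypot(shape[0] / 2.0, shape[1] / 2.0))
    radii = np.array([_radius(h, shape) for h in half]) / rmax
    core = [h for h, r in zip(half, radii) if r <= R]
    if k < len(core):
        raise ValueError(
            f"budget {budget} cannot cover the r <= R core; "
            f"minimum feasible budget is {4 * len(core)}"
        )
    rng = np.random.default_rng(seed)
    tail = [(h, r) for h, r in zip(half, radii) if r > R]
    n_extra = k - len(core)
    sel = set(core)
    if n_extra > 0 and tail:
        w = np.array([(1.0 - r) ** p for _, r in tail])
        w = w / w.sum()
        picks = rng.choice(len(tail), size=min(n_extra, len(tail)), replace=False, p=w)
        sel |= {tail[i][0] for i in picks}
    return SamplingMask(
        shape, frozenset(sel), "variable_density", budget, seed, {"R": R, "p": p}
    )


# --------------------------------------------------------------------------
# serialization: boolean PNG (centered layout) + JSON sidecar
# --------------------------------------------------------------------------

def save_mask(mask: SamplingMask, png_path: str | Path) -> None:
    """Write the mask as a 0/255 PNG (DC at image center) plus a JSON sidecar."""
    png_path = Path(png_path)
    img = np.fft.fftshift(mask.dense()).astype(np.uint8) * 255
    iio.imwrite(png_path, img)
    meta = {
        "shape": list(mask.shape),
        "scheme": mask.scheme,
        "budget": mask.budget,
        "seed": mask.seed,
        "params": mask.params,
    }
    png_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_mask(png_path: str | Path) -> SamplingMask:
    """Read a mask written by :func:`save_mask`."""
    png_path = Path(png_path)
    img = iio.imread(png_path)
    dense = np.fft.ifftshift(img > 0)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    sel = frozenset((int(i), int(j)) for i, j in zip(*np.nonzero(dense)))
    return SamplingMask(
        tuple(meta["shape"]), sel, meta["scheme"], meta["budget"],
        meta["seed"], meta.get("params", {}),
    )
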