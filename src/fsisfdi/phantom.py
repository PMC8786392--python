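"""Synthetic optical-property scenes and forward-simulated modulated images.

Two scene families cover the experiments the package reproduces without any
external data:

* homogeneous two-tone phantoms — a uniform background with circular
  anomaly disks of different absorption/scattering, mimicking
  tissue-simulating phantom measurements;
* smooth heterogeneous tissue-like scenes — correlated random (mu_a, mu_s')
  fields inside a soft elliptical silhouette over a low-reflectance
  background, a stand-in for in-vivo structured-illumination data.

The forward simulator renders the six modulated images a camera would see:
per pixel, per frequency fk and illumination phase phi,

    I = S * Rd(mu_a, mu_s', fk) * 0.5 * (1 + cos(2 pi fk x pitch + phi))

plus optional additive Gaussian noise, and renders an identical stack for a
homogeneous reference phantom whose model reflectance serves as the
calibration standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .inversion import DEFAULT_PHASES, MIStack, OpticalMap, diffusion_rd

__all__ = [
    "Anomaly",
    "PhantomSpec",
    "NoiseSpec",
    "DEFAULT_REFERENCE_PROPS",
    "make_two_tone_phantom",
    "make_smooth_tissue_scene",
    "simulate_mi_stack",
    "save_stack",
    "load_stack",
]

# homogeneous calibration phantom: a typical silicone reference
DEFAULT_REFERENCE_PROPS = (0.0046, 0.7)


@dataclass(frozen=True)
class Anomaly:
    """Circular inclusion: center (px), radius (px), and its (mua, musp)."""

    center: tuple[int, int]
    radius: float
    mua: float
    musp: float


def _default_anomalies() -> list[Anomaly]:
    return [
        Anomaly((78, 78), 25.0, 0.02, 1.5),
        Anomaly((78, 178), 25.0, 0.03, 1.5),
        Anomaly((178, 128), 25.0, 0.04, 1.5),
    ]


@dataclass
class PhantomSpec:
    """Two-tone phantom: background properties plus anomaly disks.

    Defaults are typical-tissue values well inside the lookup-table range:
    background mu_a = 0.01, mu_s' = 1.0 /mm with three radius-25 disks at
    mu_a in {0.02, 0.03, 0.04} and mu_s' = 1.5 /mm on a 256x256 frame at
    0.5 mm/pixel.
    """

    shape: tuple[int, int] = (256, 256)
    background: tuple[float, float] = (0.01, 1.0)
    anomalies: list[Anomaly] = field(default_factory=_default_anomalies)
    pixel_pitch: float = 0.5


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise with standard deviation `sigma` relative to
    the mean DC-image intensity; seeded for reproducibility."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.sigma}")


def make_two_tone_phantom(spec: PhantomSpec) -> OpticalMap:
    """Piecewise-constant optical maps: background with disks overwritten."""
    M, N = spec.shape
    mua = np.full((M, N), spec.background[0], dtype=float)
    musp = np.full((M, N), spec.background[1], dtype=float)
    x, y = np.ogrid[:M, :N]
    for an in spec.anomalies:
        cx, cy = an.center
        if (cx - an.radius < 0 or cx + an.radius > M - 1
                or cy - an.radius < 0 or cy + an.radius > N - 1):
            raise ValueError(f"anomaly at {an.center} r={an.radius} exceeds the frame")
        disk = (x - cx) ** 2 + (y - cy) ** 2 <= an.radius**2
        mua[disk] = an.mua
        musp[disk] = an.musp
    return OpticalMap(mua, musp)


def make_smooth_tissue_scene(
    shape: tuple[int, int] = (256, 256),
    mua_range: tuple[float, float] = (0.005, 0.05),
    musp_range: tuple[float, float] = (0.5, 2.0),
    correlation_px: float = 16.0,
    seed: int = 0,
    edge_px: float = 3.0,
) -> OpticalMap:
    """Smooth heterogeneous scene inside a soft elliptical silhouette.

    Seeded white noise is Gaussian-filtered (sigma = correlation_px / 2,
    periodic boundaries) and min-max mapped into the stated ranges; the
    silhouette blends the fields toward the most absorbing / least
    scattering corner of the ranges outside an ellipse with semi-axes
    0.38 M x 0.30 N, over an edge of width ``edge_px`` pixels.  All output
    values stay inside the stated ranges.
    """
    if correlation_px < 1:
        raise ValueError(f"correlation_px must be >= 1, got {correlation_px}")
    for lo, hi, name in (*mua_range, "mua_range"), (*musp_range, "musp_range"):
        if lo >= hi:
            raise ValueError(f"{name} must be increasing, got ({lo}, {hi})")
    M, N = shape
    rng = np.random.default_rng(seed)

    def smooth_field(lo: float, hi: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((M, N)), correlation_px / 2.0,
                            mode="wrap")
        f = (f - f.min()) / (f.max() - f.min())
        return lo + f * (hi - lo)

    mua = smooth_field(*mua_range)
    musp = smooth_field(*musp_range)
    x, y = np.mgrid[:M, :N]
    rho = np.sqrt(((x - M / 2) / (0.38 * M)) ** 2 + ((y - N / 2) / (0.30 * N)) ** 2)
    dist = (rho - 1.0) * 0.30 * N  # signed pixel distance from the silhouette
    inside = 1.0 / (1.0 + np.exp(dist / edge_px))
    bg_mua, bg_musp = mua_range[1], musp_range[0]
    mua = bg_mua + inside * (mua - bg_mua)
    musp = bg_musp + inside * (musp - bg_musp)
    return OpticalMap(mua, musp)


def simulate_mi_stack(
    optical_map: OpticalMap,
    phases: tuple[float, float, float] = DEFAULT_PHASES,
    f_dc: float = 0.0,
    f_ac: float = 0.2,
    pixel_pitch: float = 0.25,
    source_intensity: float = 1e4,
    noise: NoiseSpec | None = None,
    n_index: float = 1.4,
    reference_props: tuple[float, float] = DEFAULT_REFERENCE_PROPS,
) -> tuple[MIStack, MIStack]:
    """Render the six-image modulated stack of a scene and of the reference.

    Returns ``(sample_stack, reference_stack)``; the reference is a
    homogeneous phantom at ``reference_props`` rendered identically
    (including noise draws from the same seeded stream).  Noiseless stacks
    are exact closed forms, so demodulation + calibration recovers the model
    reflectance to machine precision.
    """
    M, N = optical_map.shape
    if (np.any(optical_map.mua < 0.001) or np.any(optical_map.mua > 0.5)
            or np.any(optical_map.musp < 0.1) or np.any(optical_map.musp > 5.0)):
        raise ValueError("optical map outside the default LUT range "
                         "(mua in [0.001, 0.5], musp in [0.1, 5] /mm)")
    rng = np.random.default_rng(noise.seed) if noise is not None else None

    def render(mua, musp):
        x = np.arange(M)[:, None] * pixel_pitch
        imgs = {}
        for fk, key in ((f_dc, "dc"), (f_ac, "ac")):
            rd = diffusion_rd(mua, musp, fk, n_index) * np.ones((M, N))
            stack = np.empty((3, M, N))
            for i, phi in enumerate(phases):
                illum = 0.5 * (1.0 + np.cos(2.0 * np.pi * fk * x + phi))
                stack[i] = source_intensity * rd * illum
            imgs[key] = stack
        return imgs

    sample = render(optical_map.mua, optical_map.musp)
    ref_mua = np.full((M, N), reference_props[0])
    ref_musp = np.full((M, N), reference_props[1])
    reference = render(ref_mua, ref_musp)

    if rng is not None and noise.sigma > 0:
        level = noise.sigma * float(np.mean(sample["dc"]))
        for imgs in (sample, reference):
            for key in ("dc", "ac"):
                imgs[key] = np.clip(imgs[key] + rng.normal(0.0, level, imgs[key].shape),
                                    0.0, None)

    mk = lambda imgs: MIStack(imgs["dc"], imgs["ac"], tuple(phases), f_dc, f_ac,
                              pixel_pitch)
    return mk(sample), mk(reference)


# --------------------------------------------------------------------------
# persistence: multi-page float TIFF + JSON manifest
# --------------------------------------------------------------------------

def save_stack(stack: MIStack, path: str | Path) -> None:
    path = Path(path)
    pages = np.concatenate([stack.dc, stack.ac]).astype(np.float32)
    tifffile.imwrite(path, pages)
    manifest = {
        "phases": list(stack.phases),
        "f_dc": stack.f_dc,
        "f_ac": stack.f_ac,
        "pixel_pitch": stack.pixel_pitch,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_stack(path: str | Path) -> MIStack:
    path = Path(path)
    pages = tifffile.imread(path).astype(float)
    manifest = json.loads(path.with_suffix(".json").read_text())
    return MIStack(pages[:3], pages[3:], tuple(manifest["phases"]),
                   manifest["f_dc"], manifest["f_ac"], manifest["pixel_pitch"])
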