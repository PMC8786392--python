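"""Experiment drivers: the full compressive-SFDI pipeline and its sweeps.

The pipeline chains every stage of the method: a scene's six modulated
images (simulated or supplied) are each pushed through single-pixel
acquisition at a sampling mask, reconstructed, demodulated to AC/DC
amplitudes, calibrated against the reference stack, and inverted to
per-pixel optical properties.  Sweeps score compressed runs against the
full-sampling pipeline output (the noncompressive ground truth) with
normalized RMSE and global SSIM, and additionally against the generating
maps for synthetic scenes.

Geometry of the synthetic surrogates: the smooth tissue scene is imaged at
a fixed 64 mm field of view regardless of resolution (pixel pitch 64/M mm),
which places the 0.2 /mm AC carrier at 12.8 cycles per frame — comfortably
inside the lowest-budget circular disc, the operating regime compressive
Fourier acquisition of modulated images requires.  The two-tone phantom
keeps its conventional 0.5 mm pitch.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .engine import ReconConfig, acquire_spectrum, reconstruct_cs_tv, reconstruct_ifft
from .inversion import (
    DEFAULT_PHASES,
    MIStack,
    OpticalMap,
    RdLUT,
    RdMaps,
    calibrate,
    default_lut,
    demodulate_ac,
    demodulate_dc,
    diffusion_rd,
    invert_lut,
)
from .metrics import MetricReport, rmse_percent, ssim_global
from .patterns import (
    SamplingMask,
    circular_mask,
    full_mask,
    uniform_random_mask,
    variable_density_mask,
)
from .phantom import (
    DEFAULT_REFERENCE_PROPS,
    NoiseSpec,
    PhantomSpec,
    make_smooth_tissue_scene,
    make_two_tone_phantom,
    simulate_mi_stack,
)

__all__ = [
    "RunConfig",
    "SMOOTH_FIELD_OF_VIEW_MM",
    "surrogate_scene",
    "make_mask",
    "process_stacks",
    "run_sampling_sweep",
    "compare_schemes",
    "write_reports_csv",
]

log = logging.getLogger("fsisfdi")

SMOOTH_FIELD_OF_VIEW_MM = 64.0
DEFAULT_BUDGETS = (5242, 10486, 15729, 20972, 26214)


@dataclass
class RunConfig:
    """One sweep or comparison run.

    ``scene`` selects the synthetic surrogate ("phantom" or "smooth");
    budgets are projected-pattern counts; ``recon`` is "ifft" or "cs_tv".
    """

    scene: str = "smooth"
    shape: tuple[int, int] = (256, 256)
    scheme: str = "circular"
    budgets: tuple[int, ...] = DEFAULT_BUDGETS
    recon: str = "ifft"
    phases: tuple[float, float, float] = DEFAULT_PHASES
    f_dc: float = 0.0
    f_ac: float = 0.2
    noise_sigma: float = 0.0
    seed: int = 0
    lut_points: int = 100
    outdir: str | None = None
    cs: ReconConfig = field(default_factory=ReconConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cs" in raw:
            raw["cs"] = ReconConfig(**raw["cs"])
        for key in ("shape", "budgets", "phases"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for b in cfg.budgets:
            if b < 4:
                raise ValueError(f"budgets must be >= 4, got {b}")
        return cfg


def surrogate_scene(kind: str, shape: tuple[int, int], seed: int) -> tuple[OpticalMap, float]:
    """Build a synthetic scene and its pixel pitch (mm/px).

    "phantom": the default two-tone phantom (256×256 only, 0.5 mm pitch,
    independent of seed).  "smooth": the tissue-like scene at a constant
    64 mm field of view with correlation length scaled with resolution.
    """
    M, N = shape
    if kind == "phantom":
        spec = PhantomSpec()
        if tuple(shape) != tuple(spec.shape):
            # scale the default anomaly geometry with the frame
            sx, sy = M / spec.shape[0], N / spec.shape[1]
            scaled = [
                type(an)((int(an.center[0] * sx), int(an.center[1] * sy)),
                         an.radius * min(sx, sy), an.mua, an.musp)
                for an in spec.anomalies
            ]
            spec = PhantomSpec(shape=(M, N), anomalies=scaled)
        return make_two_tone_phantom(spec), spec.pixel_pitch
    if kind == "smooth":
        corr = 16.0 * M / 256.0
        scene = make_smooth_tissue_scene(tuple(shape), correlation_px=corr, seed=seed)
        return scene, SMOOTH_FIELD_OF_VIEW_MM / M
    raise ValueError(f"unknown scene kind {kind!r}")


def make_mask(scheme: str, shape: tuple[int, int], budget: int,
              seed: int = 0) -> SamplingMask:
    if scheme == "circular":
        return circular_mask(shape, budget)
    if scheme == "uniform_random":
        return uniform_random_mask(shape, budget, seed)
    if scheme == "variable_density":
        return variable_density_mask(shape, budget, seed=seed)
    if scheme == "full":
        return full_mask(shape)
    raise ValueError(f"unknown sampling scheme {scheme!r}")


def _reconstruct_image(img: np.ndarray, mask: SamplingMask, recon: str,
                       cs: ReconConfig | None) -> np.ndarray:
    spectrum = acquire_spectrum(img, mask)
    if recon == "ifft":
        return reconstruct_ifft(spectrum)
    if recon == "cs_tv":
        return reconstruct_cs_tv(spectrum, cs).image
    raise ValueError(f"unknown reconstruction method {recon!r}")


def process_stacks(
    sample: MIStack,
    reference: MIStack,
    lut: RdLUT,
    mask: SamplingMask | None = None,
    recon: str = "ifft",
    cs: ReconConfig | None = None,
    reference_props: tuple[float, float] = DEFAULT_REFERENCE_PROPS,
) -> OpticalMap:
    """Run acquisition → reconstruction → demodulation → calibration →
    inversion on a sample/reference stack pair.

    With ``mask=None`` the camera images are used directly (no single-pixel
    stage); a full mask gives the identical result through the single-pixel
    path and is what sweeps use as ground truth.
    """
    if sample.shape != reference.shape:
        raise ValueError("sample and reference stacks must share a shape")

    def push(stack3):
        if mask is None:
            return [np.asarray(im, dtype=float) for im in stack3]
        return [_reconstruct_image(im, mask, recon, cs) for im in stack3]

    s_dc, s_ac = push(sample.dc), push(sample.ac)
    r_dc, r_ac = push(reference.dc), push(reference.ac)

    m_dc = demodulate_dc(*s_dc)
    m_ac = demodulate_ac(*s_ac)
    m_dc_ref = demodulate_dc(*r_dc)
    m_ac_ref = demodulate_ac(*r_ac)

    rd_ref_dc = diffusion_rd(*reference_props, sample.f_dc, lut.n_index)
    rd_ref_ac = diffusion_rd(*reference_props, sample.f_ac, lut.n_index)
    rd = RdMaps(
        rd_dc=calibrate(m_dc, m_dc_ref, rd_ref_dc),
        rd_ac=calibrate(m_ac, m_ac_ref, rd_ref_ac),
    )
    return invert_lut(rd, lut)


def _score(estimate: OpticalMap, reference: OpticalMap, scheme: str, budget: int,
           shape: tuple[int, int], seed: int | None,
           truth: OpticalMap | None = None) -> MetricReport:
    report = MetricReport(
        scheme=scheme,
        budget=budget,
        sampling_rate=budget / (shape[0] * shape[1]),
        seed=seed,
        rmse_mua=rmse_percent(estimate.mua, reference.mua),
        rmse_musp=rmse_percent(estimate.musp, reference.musp),
        ssim_mua=ssim_global(estimate.mua, reference.mua),
        ssim_musp=ssim_global(estimate.musp, reference.musp),
    )
    if truth is not None:
        report.rmse_mua_true = rmse_percent(estimate.mua, truth.mua)
        report.rmse_musp_true = rmse_percent(estimate.musp, truth.musp)
    return report


def _prepare(config: RunConfig):
    scene, pitch = surrogate_scene(config.scene, config.shape, config.seed)
    noise = NoiseSpec(config.noise_sigma, config.seed) if config.noise_sigma > 0 else None
    sample, reference = simulate_mi_stack(
        scene, phases=config.phases, f_dc=config.f_dc, f_ac=config.f_ac,
        pixel_pitch=pitch, noise=noise,
    )
    lut = default_lut(config.lut_points, config.lut_points,
                      f_dc=config.f_dc, f_ac=config.f_ac)
    truth = process_stacks(sample, reference, lut, mask=full_mask(config.shape),
                           recon="ifft")
    return scene, sample, reference, lut, truth


def run_sampling_sweep(config: RunConfig) -> list[MetricReport]:
    """Score one scheme across pattern budgets against full sampling.

    Writes ``sweep.csv`` and per-budget optical-map TIFFs under
    ``config.outdir`` when set.
    """
    scene, sample, reference, lut, truth = _prepare(config)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    reports = []
    for budget in config.budgets:
        mask = make_mask(config.scheme, config.shape, budget, config.seed)
        est = process_stacks(sample, reference, lut, mask=mask,
                             recon=config.recon, cs=config.cs)
        reports.append(_score(est, truth, config.scheme, budget, config.shape,
                              config.seed, scene))
        log.info("budget %d: rmse mua %.3f%% musp %.3f%%", budget,
                 reports[-1].rmse_mua, reports[-1].rmse_musp)
        if outdir:
            tifffile.imwrite(outdir / f"maps_{budget}.tiff",
                             np.stack([est.mua, est.musp]).astype(np.float32))
    if outdir:
        write_reports_csv(reports, outdir / "sweep.csv")
        tifffile.imwrite(outdir / "maps_full.tiff",
                         np.stack([truth.mua, truth.musp]).astype(np.float32))
    return reports


def compare_schemes(config: RunConfig, budget: int | None = None) -> list[MetricReport]:
    """Circular vs uniform-random vs variable-density at one budget."""
    scene, sample, reference, lut, truth = _prepare(config)
    if budget is None:
        budget = config.budgets[0]
    reports = []
    for scheme in ("circular", "uniform_random", "variable_density"):
        mask = make_mask(scheme, config.shape, budget, config.seed)
        est = process_stacks(sample, reference, lut, mask=mask,
                             recon=config.recon, cs=config.cs)
        reports.append(_score(est, truth, scheme, budget, config.shape,
                              config.seed, scene))
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_reports_csv(reports, outdir / "schemes.csv")
    return reports


def write_reports_csv(reports: list[MetricReport], path: str | Path) -> None:
    """Deterministic CSV: fixed column order, repr-stable float formatting."""
    rows = [r.as_row() for r in reports]
    fields = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for row in rows:
            writer.writerow(
                [f"{v:.10g}" if isinstance(v, float) else ("" if v is None else v)
                 for v in (row[k] for k in fields)]
            )
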