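"""Image-quality metrics for recovered optical-property maps.

RMSE is reported in percent after both images are normalized by the
reference map's dynamic range, so "2%" means a root-mean-square deviation of
2% of the reference's min-to-max span.  SSIM is the single-window (global)
structural similarity: means, variances, and covariance over the whole
image, with the conventional stabilizers C1 = (K1 L)^2, C2 = (K2 L)^2.  A
sliding-window SSIM (scikit-image) is available behind a flag for
comparison but all reported scores use the global form.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

__all__ = ["MetricReport", "rmse_percent", "ssim_global"]


def rmse_percent(estimate: np.ndarray, reference: np.ndarray) -> float:
    """Dynamic-range-normalized root-mean-square error, in percent."""
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {ref.shape}")
    span = float(ref.max() - ref.min())
    if span == 0.0:
        raise ValueError("reference image is constant; dynamic range undefined")
    a = (est - ref.min()) / span
    b = (ref - ref.min()) / span
    return float(np.sqrt(np.mean((a - b) ** 2)) * 100.0)


def ssim_global(
    estimate: np.ndarray,
    reference: np.ndarray,
    K1: float = 0.01,
    K2: float = 0.03,
    L: float | None = None,
    windowed: bool = False,
) -> float:
    """Structural similarity with global statistics (sample covariance).

    ``L`` defaults to 255 for uint8 inputs and to the reference dynamic
    range otherwise.  With ``windowed=True`` the scikit-image sliding-window
    mean SSIM is returned instead.
    """
    est = np.asarray(estimate)
    ref = np.asarray(reference)
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {ref.shape}")
    if L is None:
        L = 255.0 if ref.dtype == np.uint8 else float(ref.max() - ref.min())
    if windowed:
        return float(_sk_ssim(ref.astype(float), est.astype(float),
                              data_range=L, K1=K1, K2=K2))
    a = est.astype(float).ravel()
    b = ref.astype(float).ravel()
    c1 = (K1 * L) ** 2
    c2 = (K2 * L) ** 2
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    cov = float(np.dot(a - ma, b - mb)) / (a.size - 1)
    return float(
        (2 * ma * mb + c1) * (2 * cov + c2) / ((ma**2 + mb**2 + c1) * (va + vb + c2))
    )


@dataclass
class MetricReport:
    """Scores of one compressed run against the full-sampling reference.

    The ``*_true`` columns additionally score against the scene's generating
    optical maps when those are known (synthetic runs only).
    """

    scheme: str
    budget: int
    sampling_rate: float
    seed: int | None
    rmse_mua: float
    rmse_musp: float
    ssim_mua: float
    ssim_musp: float
    rmse_mua_true: float | None = None
    rmse_musp_true: float | None = None

    def as_row(self) -> dict:
        return asdict(self)
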