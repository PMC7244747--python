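"""Image-quality metrics (PSNR, SSIM) and method-comparison tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["MetricRecord", "ReconRecord", "psnr", "ssim", "score", "summarize", "evaluate"]


@dataclass(frozen=True)
class MetricRecord:
    """Quality of one reconstruction against its ground truth."""

    method: str
    n_sensors: int
    psnr_db: float
    ssim: float
    image_id: str


@dataclass
class ReconRecord:
    """A reconstructed image tagged with its method and provenance."""

    image: np.ndarray
    method: str
    n_sensors: int
    image_id: str


def psnr(image: np.ndarray, reference: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in dB.

    The peak is fixed at 1.0 for [0, 1]-normalized data so values are
    comparable across images.  Identical images give +inf (flagged by callers
    before averaging).
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reference.shape}")
    mse = float(np.mean((image - reference) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(image: np.ndarray, reference: np.ndarray) -> float:
    """Mean local structural similarity.

    Canonical configuration: 11 x 11 Gaussian window with sigma 1.5,
    K1 = 0.01, K2 = 0.03, data range 1.0, population covariances.
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reference.shape}")
    if min(image.shape) < 11:
        raise ValueError("image smaller than the 11 x 11 SSIM window")
    return float(structural_similarity(
        reference, image, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def score(recons: list[ReconRecord], truths: dict[str, np.ndarray]) -> list[MetricRecord]:
    """PSNR/SSIM of every reconstruction against its ground truth by image_id."""
    orphans = [r.image_id for r in recons if r.image_id not in truths]
    if orphans:
        raise ValueError(f"reconstructions without a matching truth: {orphans}")
    return [
        MetricRecord(method=r.method, n_sensors=r.n_sensors,
                     psnr_db=psnr(r.image, truths[r.image_id]),
                     ssim=ssim(r.image, truths[r.image_id]),
                     image_id=r.image_id)
        for r in recons
    ]


def evaluate(recons: list[ReconRecord], truths: dict[str, np.ndarray]) -> pd.DataFrame:
    """Score reconstructions and assemble the method x sensor-count table."""
    return summarize(score(recons, truths))


def summarize(records: list[MetricRecord]) -> pd.DataFrame:
    """Mean +/- std of PSNR and SSIM per (method, n_sensors) cell.

    Records with infinite PSNR (identical images) are excluded from the PSNR
    statistics with a warning; the cell sample size ``n`` counts all records.
    """
    if not records:
        raise ValueError("no records to evaluate")
    df = pd.DataFrame([r.__dict__ for r in records])
    n_inf = int(np.isinf(df["psnr_db"]).sum())
    if n_inf:
        warnings.warn(f"excluding {n_inf} infinite PSNR value(s) from the summary",
                      stacklevel=2)
    rows = []
    for (method, n_sensors), g in df.groupby(["method", "n_sensors"], sort=True):
        p = g["psnr_db"][np.isfinite(g["psnr_db"])]
        rows.append({
            "method": method,
            "n_sensors": n_sensors,
            "psnr_mean": p.mean() if len(p) else np.nan,
            "psnr_std": p.std(ddof=0) if len(p) else np.nan,
            "ssim_mean": g["ssim"].mean(),
            "ssim_std": g["ssim"].std(ddof=0),
            "n": len(g),
        })
    return pd.DataFrame(rows)
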