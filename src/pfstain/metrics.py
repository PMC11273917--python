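"""Evaluation metrics: paired image quality (RMSE, PSNR, SSIM) and
classification rates from confusion counts.

Image metrics follow the conventions that make the published magnitudes
mutually consistent: intensities are rescaled to [0, 1] (so RMSE of ~0.01
and PSNR of ~38 dB with MAX_I = 1 agree), and a set of image pairs is scored
per image first and then averaged (PSNR of a mean RMSE is *not* the mean of
per-image PSNRs; the per-image convention is the implemented one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ConfusionCounts",
    "PairedEvalRecord",
    "rmse",
    "psnr",
    "psnr_from_rmse",
    "ssim",
    "classification_metrics",
    "confusion_from_labels",
    "evaluate_pairs",
    "round_sig",
]

_GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])  # ITU-R BT.601 luminance


def _to_unit(img: np.ndarray) -> np.ndarray:
    """Rescale 8-bit images to [0, 1]; floats are assumed already scaled."""
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3 and img.shape[2] == 3:
        return img @ _GRAY_WEIGHTS
    if img.ndim == 2:
        return img
    raise ValueError(f"expected a 2-D or (H, W, 3) image, got shape {img.shape}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PairedEvalRecord:
    generated: np.ndarray
    reference: np.ndarray
    max_intensity: float = 1.0

    def __post_init__(self):
        if np.asarray(self.generated).shape != np.asarray(self.reference).shape:
            raise ValueError("generated and reference must have equal dimensions")
        if self.max_intensity <= 0:
            raise ValueError("max_intensity must be > 0")


def rmse(generated: np.ndarray, reference: np.ndarray) -> float:
    """Root mean squared per-pixel difference on the [0, 1] scale.

    For multi-channel images the mean runs over all pixels and channels.
    """
    a, b = _to_unit(generated), _to_unit(reference)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr_from_rmse(rmse_value: float, max_intensity: float = 1.0) -> float:
    """20 * log10(MAX_I / RMSE); +inf for a zero RMSE (identical images)."""
    if rmse_value < 0:
        raise ValueError("rmse must be >= 0")
    if rmse_value == 0:
        return math.inf
    return 20.0 * math.log10(max_intensity / rmse_value)


def psnr(record: PairedEvalRecord) -> float:
    return psnr_from_rmse(rmse(record.generated, record.reference), record.max_intensity)


def ssim(
    generated: np.ndarray,
    reference: np.ndarray,
    c1: float | None = None,
    c2: float | None = None,
    window: int = 11,
    data_range: float = 1.0,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity with a Gaussian-weighted window.

    The local statistics (means, variances, covariance) are Gaussian-filtered
    moments; the map is cropped by the filter radius before averaging so that
    edge effects do not enter. Defaults follow the SSIM literature:
    C1 = (0.01 L)^2, C2 = (0.03 L)^2, an 11-pixel window (sigma 1.5). RGB
    input is converted to luminance first. Result lies in [-1, 1].
    """
    a = _to_gray(_to_unit(generated))
    b = _to_gray(_to_unit(reference))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if min(a.shape) < window:
        raise ValueError(f"window {window} larger than image {a.shape}")
    if c1 is None:
        c1 = (0.01 * data_range) ** 2
    if c2 is None:
        c2 = (0.03 * data_range) ** 2
    if c1 <= 0 or c2 <= 0:
        raise ValueError("C1 and C2 must be > 0")

    radius = (window - 1) // 2
    truncate = radius / sigma
    smooth = lambda x: gaussian_filter(x, sigma=sigma, truncate=truncate)
    ua, ub = smooth(a), smooth(b)
    vaa = smooth(a * a) - ua * ua
    vbb = smooth(b * b) - ub * ub
    vab = smooth(a * b) - ua * ub
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / (
        (ua**2 + ub**2 + c1) * (vaa + vbb + c2)
    )
    interior = s[radius:-radius, radius:-radius]
    return float(interior.mean())


def classification_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, recall, specificity and F1 from counts.

    A metric whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": ratio(tp + tn, counts.total),
        "precision": precision,
        "recall": recall,
        "specificity": ratio(tn, tn + fp),
        "f1": f1,
    }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    if precision + recall == 0:
        raise ValueError("precision + recall must be > 0")
    return 2 * precision * recall / (precision + recall)


def confusion_from_labels(predicted, truth) -> ConfusionCounts:
    """Tally a confusion matrix from {0, 1} label sequences."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    for name, arr in (("predicted", p), ("truth", t)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be in {{0, 1}}")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def evaluate_pairs(pairs: list[tuple[np.ndarray, np.ndarray]], max_intensity: float = 1.0) -> pd.DataFrame:
    """Per-pair RMSE/PSNR/SSIM plus an unweighted mean row.

    The returned frame has one row per pair and a final ``mean`` row; the
    `psnr_infinite` column flags identical pairs whose PSNR is unbounded.
    """
    rows = []
    for i, (gen, ref) in enumerate(pairs):
        r = rmse(gen, ref)
        p = psnr_from_rmse(r, max_intensity)
        rows.append(
            {
                "pair": str(i),
                "rmse": r,
                "psnr": p,
                "psnr_infinite": math.isinf(p),
                "ssim": ssim(gen, ref, data_range=max_intensity),
            }
        )
    frame = pd.DataFrame(rows)
    finite = frame[~frame["psnr_infinite"]]
    mean_row = {
        "pair": "mean",
        "rmse": frame["rmse"].mean(),
        "psnr": finite["psnr"].mean() if len(finite) else math.inf,
        "psnr_infinite": bool(frame["psnr_infinite"].any()),
        "ssim": frame["ssim"].mean(),
    }
    return pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)


def round_sig(x: float, sig: int = 4) -> float:
    """Round to `sig` significant figures (report-table convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
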