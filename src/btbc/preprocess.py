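"""Three-step conditioning of raw motion-energy series.

Order is fixed — smooth, then outlier removal, then standardization — so
that every series entering the coupling analysis has mean 0 and SD 1:

1. centred moving average, window 0.5 s;
2. samples above mean + 10 SD (of the smoothed series) flagged as outliers
   and replaced by linear interpolation between the nearest clean
   neighbours (a regular time grid is required downstream, so flagged
   samples are interpolated rather than deleted);
3. z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .motion import MotionSeries

__all__ = [
    "PreprocessReport",
    "smooth_series",
    "remove_outliers",
    "standardize_series",
    "preprocess_series",
]

DEFAULT_SMOOTH_WINDOW = 0.5  # seconds
DEFAULT_OUTLIER_K = 10.0  # SD multiplier


@dataclass
class PreprocessReport:
    """Bookkeeping for one series' pass through the pipeline."""

    n_outliers: int
    outlier_fraction: float
    smoothing_window: float
    input_length: int
    output_length: int

    def to_dict(self) -> dict:
        return asdict(self)


def _odd_window_samples(window: float, sampling_rate: float) -> int:
    n = int(round(window * sampling_rate))
    if n < 1:
        raise ValueError(
            f"window {window} s is shorter than one sample at {sampling_rate} Hz"
        )
    if n % 2 == 0:
        n += 1
    return n


def smooth_series(series: MotionSeries, window: float = DEFAULT_SMOOTH_WINDOW) -> MotionSeries:
    """Centred moving average; window rounded to the nearest odd sample count.

    Edges use shrinking windows (the average runs over the samples that
    exist), so the output length equals the input length and a constant
    series is reproduced exactly.
    """
    n = _odd_window_samples(window, series.sampling_rate)
    x = series.values
    if n > len(x):
        raise ValueError(f"smoothing window of {n} samples exceeds series length {len(x)}")
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return series.with_values(num / den)


def remove_outliers(
    series: MotionSeries, k_sd: float = DEFAULT_OUTLIER_K
) -> tuple[MotionSeries, PreprocessReport]:
    """Flag samples above mean + ``k_sd``·SD and interpolate across them.

    Mean and SD are those of the input series.  Flagged samples are
    replaced by linear interpolation between the nearest unflagged
    neighbours; flagged runs at either edge take the nearest unflagged
    value.
    """
    x = series.values
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    thresh = x.mean() + k_sd * x.std()
    bad = x > thresh
    n_bad = int(bad.sum())
    if n_bad == len(x):
        raise ValueError("all samples flagged as outliers; degenerate series")
    if n_bad:
        idx = np.arange(len(x))
        clean = x.copy()
        clean[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    else:
        clean = x
    report = PreprocessReport(
        n_outliers=n_bad,
        outlier_fraction=n_bad / len(x),
        smoothing_window=float("nan"),
        input_length=len(x),
        output_length=len(x),
    )
    return series.with_values(clean), report


def standardize_series(series: MotionSeries) -> MotionSeries:
    """Z-score to mean 0, SD 1 (population SD)."""
    x = series.values
    sd = x.std()
    if sd <= 0:
        raise ValueError(
            f"zero-variance series (roi={series.roi_id!r}); flag dyad for exclusion"
        )
    return series.with_values((x - x.mean()) / sd, standardized=True)


def preprocess_series(
    series: MotionSeries,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    outlier_k: float = DEFAULT_OUTLIER_K,
) -> tuple[MotionSeries, PreprocessReport]:
    """The full pipeline in its fixed order: smooth → de-outlier → z-score."""
    smoothed = smooth_series(series, smooth_window)
    cleaned, report = remove_outliers(smoothed, outlier_k)
    report.smoothing_window = smooth_window
    return standardize_series(cleaned), report
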