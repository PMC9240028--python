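"""Body-to-body coupling (BtBC): windowed, lagged cross-correlation.

The statistic
-------------
Both motion-energy series are preprocessed to zero mean and unit SD.  For
every moving window (default 30 s, advancing in 1-s increments, anchored on
the learner's clock) and every signed lag on a grid of ±5 s in 0.04-s steps
(251 lags at 25 Hz), the Pearson correlation ``r`` is computed between the
learner segment at ``[t, t + W)`` and the instructor segment at
``[t + lag, t + lag + W)``.  Positive lags therefore mean the learner's
motion occurred earlier (the learner leads).  Per lag, the coupling value
is the window-average of the absolute Fisher-z transform ``|atanh(r)|``, so
positive and negative correlations both count toward coupling.  Averaging
the 251 per-lag values gives *overall* BtBC; averaging only the positive or
only the negative lags gives the learner-leading and instructor-leading
summaries.

Windows whose lag-shifted instructor segment would run off the series are
skipped for that lag (no zero-padding — padding biases |r| downward), as
are windows with zero variance in either segment; ``n_windows_used``
records how many windows entered each per-lag average.

Use :class:`DyadCoupling` / :class:`DyadCouplingResults` for the
model-object interface, or the functional layer
(:func:`windowed_lagged_xcorr`, :func:`summarize_btbc`) directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conventions import LEARNER_LEADS_SIGN
from .motion import MotionSeries
from .preprocess import preprocess_series

__all__ = [
    "LagGrid",
    "LagProfile",
    "BtBCSummary",
    "windowed_lagged_xcorr",
    "summarize_btbc",
    "DyadCoupling",
    "DyadCouplingResults",
]

DEFAULT_WINDOW = 30.0  # seconds
DEFAULT_STEP = 1.0  # seconds
DEFAULT_MAX_LAG = 5.0  # seconds
DEFAULT_LAG_STEP = 0.04  # seconds

#: |r| is clipped here before atanh so the profile stays finite.
R_CLIP = 1.0 - 1e-6

# Windows with per-sample variance below this (on the unit-SD scale) are
# treated as degenerate and skipped.
_VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class LagGrid:
    """Symmetric grid of signed lags: −max_lag … +max_lag in lag_step steps."""

    max_lag: float = DEFAULT_MAX_LAG
    lag_step: float = DEFAULT_LAG_STEP

    def __post_init__(self) -> None:
        if self.max_lag <= 0 or self.lag_step <= 0:
            raise ValueError("max_lag and lag_step must be positive")
        if self.n_per_side < 1:
            raise ValueError("lag_step larger than max_lag")

    @property
    def n_per_side(self) -> int:
        return int(round(self.max_lag / self.lag_step))

    @property
    def n_lags(self) -> int:
        return 2 * self.n_per_side + 1

    @property
    def offsets(self) -> np.ndarray:
        """Signed lags in seconds, ordered, symmetric about (and containing) 0."""
        k = self.n_per_side
        return np.arange(-k, k + 1) * self.lag_step

    def lag_samples(self, sampling_rate: float) -> np.ndarray:
        """Integer sample offsets; lag_step must be a multiple of 1/rate."""
        offs = self.offsets * sampling_rate
        rounded = np.round(offs)
        if np.max(np.abs(offs - rounded)) > 1e-6:
            raise ValueError(
                f"lag_step={self.lag_step}s is not an integer number of samples "
                f"at {sampling_rate} Hz"
            )
        return rounded.astype(int)


@dataclass
class LagProfile:
    """Window-averaged |Fisher-z| coupling at each lag of a grid."""

    grid: LagGrid
    values: np.ndarray
    n_windows_used: np.ndarray
    dyad_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_windows_used = np.asarray(self.n_windows_used, dtype=int)
        if len(self.values) != self.grid.n_lags:
            raise ValueError("profile length does not match grid")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("profile values must be finite and non-negative")

    @property
    def offsets(self) -> np.ndarray:
        return self.grid.offsets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dyad_id": self.dyad_id,
                "condition": self.condition,
                "lag_s": self.offsets,
                "value": self.values,
                "n_windows": self.n_windows_used,
            }
        )


@dataclass
class BtBCSummary:
    """Scalar couplings per dyad-condition derived from a lag profile."""

    overall: float
    learner_leading: float
    instructor_leading: float
    zero_lag: float
    peak_lag: float
    dyad_id: str = ""
    condition: str = ""

    def to_dict(self) -> dict:
        return {
            "dyad_id": self.dyad_id,
            "condition": self.condition,
            "overall": self.overall,
            "learner_leading": self.learner_leading,
            "instructor_leading": self.instructor_leading,
            "zero_lag": self.zero_lag,
            "peak_lag": self.peak_lag,
        }


def _window_cross_sums(
    x: np.ndarray, y: np.ndarray, lags: np.ndarray, starts: np.ndarray, w: int, s: int
) -> np.ndarray:
    """``sum_j y[t+j] * x[t+j+lag]`` for every (lag, window start).

    When the window and every start are commensurate with the step, the
    sums are assembled from step-sized block sums computed by a batched
    matmul (fast path); otherwise each lag's product series is summed via
    prefix sums.  Out-of-range shifts read zero padding; the caller masks
    those windows out, so padded entries never reach a reported value.
    """
    n = len(y)
    pad_lo = max(0, -int(lags.min()))
    pad_hi = max(0, int(lags.max()))
    x_pad = np.concatenate([np.zeros(pad_lo), x, np.zeros(pad_hi)])
    fast = w % s == 0 and np.all(starts % s == 0) and n >= s
    if fast:
        nblk = n // s
        yb = y[: nblk * s].reshape(nblk, s)
        base = np.lib.stride_tricks.sliding_window_view(x_pad, s)
        rows = (np.arange(nblk) * s)[:, None] + (lags + pad_lo)[None, :]
        win = base[rows]  # (nblk, n_lags, s): x[k*s + lag + j]
        block = (win @ yb[:, :, None])[:, :, 0]  # (nblk, n_lags)
        cum = np.zeros((len(lags), nblk + 1))
        np.cumsum(block.T, axis=1, out=cum[:, 1:])
        b = starts // s
        return cum[:, b + w // s] - cum[:, b]
    shifted = np.lib.stride_tricks.sliding_window_view(x_pad, n)[lags + pad_lo]
    cz = np.zeros((len(lags), n + 1))
    np.cumsum(shifted * y, axis=1, out=cz[:, 1:])
    return cz[:, starts + w] - cz[:, starts]


def _check_standardized(series: MotionSeries, name: str) -> np.ndarray:
    x = series.values
    if len(x) < 2:
        raise ValueError(f"{name} series too short")
    if abs(x.mean()) > 1e-6 or abs(x.std() - 1.0) > 1e-3:
        raise ValueError(
            f"{name} series is not standardized (mean {x.mean():.3g}, "
            f"SD {x.std():.3g}); run the preprocessing pipeline first"
        )
    return x


def windowed_lagged_xcorr(
    instructor: MotionSeries,
    learner: MotionSeries,
    window: float = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    grid: LagGrid | None = None,
    *,
    dyad_id: str = "",
    condition: str = "",
) -> LagProfile:
    """Windowed lagged cross-correlation profile between two standardized series.

    For each window start ``t`` (anchored on the learner) and lag ``l``:
    ``r = corr(learner[t : t+W], instructor[t+l : t+l+W])`` with per-window
    means and SDs.  Per lag, the profile value is the mean over usable
    windows of ``|atanh(r)|`` with r clipped to ±(1 − 1e−6).
    """
    grid = grid or LagGrid()
    if instructor.sampling_rate != learner.sampling_rate:
        raise ValueError("sampling rates differ")
    fs = learner.sampling_rate
    y = _check_standardized(learner, "learner")
    x = _check_standardized(instructor, "instructor")
    if len(x) != len(y):
        raise ValueError(f"series lengths differ: {len(x)} vs {len(y)}")
    n = len(y)
    w = int(round(window * fs))
    s = int(round(step * fs))
    if w < 2 or s < 1:
        raise ValueError("window/step too small for the sampling rate")
    if n < w:
        raise ValueError(f"series ({n} samples) shorter than one window ({w})")
    lags = grid.lag_samples(fs)

    starts = np.arange(0, n - w + 1, s)
    # Prefix sums (zero-padded) of the standardized series and their squares.
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cx2 = np.concatenate(([0.0], np.cumsum(x * x)))
    cy2 = np.concatenate(([0.0], np.cumsum(y * y)))

    sy = cy[starts + w] - cy[starts]
    syy = cy2[starts + w] - cy2[starts]
    var_y = w * syy - sy * sy  # = w^2 * per-window variance

    sxy = _window_cross_sums(x, y, lags, starts, w, s)  # (n_lags, n_starts)

    t_shift = starts[None, :] + lags[:, None]  # instructor segment starts
    valid = (t_shift >= 0) & (t_shift + w <= n)
    if not np.all(valid.any(axis=1)):
        bad = grid.offsets[~valid.any(axis=1)][0]
        raise ValueError(f"no usable window at lag {bad:+.3f}s")
    tc = np.clip(t_shift, 0, n - w)
    sx = cx[tc + w] - cx[tc]
    var_x = w * (cx2[tc + w] - cx2[tc]) - sx * sx

    var_floor = _VAR_FLOOR * w * w
    ok = valid & (var_x > var_floor) & (var_y[None, :] > var_floor)
    n_used = ok.sum(axis=1)
    if np.any(n_used == 0):
        bad = grid.offsets[n_used == 0][0]
        raise ValueError(f"all windows degenerate (zero variance) at lag {bad:+.3f}s")
    num = w * sxy - sx * sy[None, :]
    den = np.sqrt(np.where(ok, var_x * var_y[None, :], 1.0))
    r = np.clip(np.where(ok, num, 0.0) / den, -R_CLIP, R_CLIP)
    values = np.sum(np.abs(np.arctanh(r)) * ok, axis=1) / n_used
    return LagProfile(
        grid=grid, values=values, n_windows_used=n_used, dyad_id=dyad_id, condition=condition
    )


def summarize_btbc(profile: LagProfile) -> BtBCSummary:
    """Reduce a lag profile to the scalar coupling summaries.

    ``overall`` averages every lag; learner-leading / instructor-leading
    average the strictly positive / strictly negative lags.  ``peak_lag``
    is the lag of the maximum value; ties go to the smallest |lag|, then
    to the negative lag.
    """
    offs = profile.offsets
    v = profile.values
    pos = offs > 0
    neg = offs < 0
    zero_idx = int(np.argmin(np.abs(offs)))
    peak_candidates = np.flatnonzero(v == v.max())
    peak_idx = min(peak_candidates, key=lambda i: (abs(offs[i]), offs[i]))
    return BtBCSummary(
        overall=float(v.mean()),
        learner_leading=float(v[pos].mean()),
        instructor_leading=float(v[neg].mean()),
        zero_lag=float(v[zero_idx]),
        peak_lag=float(offs[peak_idx]),
        dyad_id=profile.dyad_id,
        condition=profile.condition,
    )


class DyadCoupling:
    """Model object: BtBC between one instructor and one learner.

    Parameters
    ----------
    instructor, learner
        Motion-energy series at the same sampling rate and length.  Raw
        series are passed through the standard preprocessing pipeline
        (0.5-s moving average, mean + 10 SD outlier interpolation,
        z-scoring) unless ``preprocess=False`` and they are already
        standardized.
    window, step
        Moving-window length and increment in seconds (defaults 30 and 1).
    grid
        Lag grid; defaults to ±5 s in 0.04-s steps.
    """

    def __init__(
        self,
        instructor: MotionSeries,
        learner: MotionSeries,
        *,
        window: float = DEFAULT_WINDOW,
        step: float = DEFAULT_STEP,
        grid: LagGrid | None = None,
        preprocess: bool = True,
        smooth_window: float = 0.5,
        outlier_k: float = 10.0,
        dyad_id: str = "",
        condition: str = "",
    ) -> None:
        if instructor.sampling_rate != learner.sampling_rate:
            raise ValueError("sampling rates differ")
        if len(instructor) != len(learner):
            raise ValueError("series lengths differ within the dyad")
        self.window = window
        self.step = step
        self.grid = grid or LagGrid()
        self.dyad_id = dyad_id
        self.condition = condition
        self.raw_instructor = instructor
        self.raw_learner = learner
        self.preprocess_reports = None
        if preprocess and not (instructor.standardized and learner.standardized):
            self.instructor, rep_i = preprocess_series(instructor, smooth_window, outlier_k)
            self.learner, rep_l = preprocess_series(learner, smooth_window, outlier_k)
            self.preprocess_reports = {"instructor": rep_i, "learner": rep_l}
        else:
            self.instructor = instructor
            self.learner = learner

    @classmethod
    def from_file(cls, path, sampling_rate: float | None = None, **kwargs) -> "DyadCoupling":
        """Build from a two-column motion file (instructor column first)."""
        from .motion import read_motion_file

        series = read_motion_file(path, sampling_rate)
        if len(series) < 2:
            raise ValueError(f"{path}: need two columns (instructor, learner)")
        return cls(series[0], series[1], **kwargs)

    def fit(self) -> "DyadCouplingResults":
        profile = windowed_lagged_xcorr(
            self.instructor,
            self.learner,
            self.window,
            self.step,
            self.grid,
            dyad_id=self.dyad_id,
            condition=self.condition,
        )
        return DyadCouplingResults(self, profile)


class DyadCouplingResults:
    """Fitted coupling for one dyad-condition: lag profile plus summaries."""

    def __init__(self, model: DyadCoupling, profile: LagProfile) -> None:
        self.model = model
        self.profile = profile
        self.btbc = summarize_btbc(profile)

    @property
    def overall(self) -> float:
        return self.btbc.overall

    @property
    def learner_leading(self) -> float:
        return self.btbc.learner_leading

    @property
    def instructor_leading(self) -> float:
        return self.btbc.instructor_leading

    @property
    def peak_lag(self) -> float:
        return self.btbc.peak_lag

    def surrogate_ensemble(self, n: int = 100, segment: float = 60.0, seed=None):
        """Pseudo-coupling values from segment-shuffled re-pairings."""
        from .surrogates import make_surrogates

        return make_surrogates(
            self.model.instructor,
            self.model.learner,
            n=n,
            segment=segment,
            seed=seed,
            window=self.model.window,
            step=self.model.step,
            grid=self.model.grid,
            dyad_id=self.model.dyad_id,
            condition=self.model.condition,
        )

    def surrogate_test(self, n: int = 100, segment: float = 60.0, seed=None):
        """Permutation test of this dyad's overall BtBC against its own
        segment-shuffled null: p = (1 + #{null ≥ observed}) / (1 + n)."""
        from .surrogates import PermutationResult

        ens = self.surrogate_ensemble(n=n, segment=segment, seed=seed)
        null = np.asarray(ens.values)
        p = (1 + int(np.sum(null >= self.overall))) / (1 + len(null))
        return PermutationResult(
            observed=self.overall, null_values=null, p=p, n_resamples=len(null), seed=seed
        )

    def summary(self) -> str:
        g = self.profile.grid
        lines = [
            "Body-to-Body Coupling (windowed lagged cross-correlation)",
            "=" * 58,
            f"dyad: {self.model.dyad_id or '-'}    condition: {self.model.condition or '-'}",
            f"window {self.model.window:g} s, step {self.model.step:g} s, "
            f"lags ±{g.max_lag:g} s in {g.lag_step:g}-s steps ({g.n_lags} lags)",
            "-" * 58,
            f"overall BtBC            {self.overall:10.4f}",
            f"learner-leading BtBC    {self.learner_leading:10.4f}",
            f"instructor-leading BtBC {self.instructor_leading:10.4f}",
            f"zero-lag BtBC           {self.btbc.zero_lag:10.4f}",
            f"peak lag                {self.peak_lag:+10.2f} s "
            f"({'learner' if self.peak_lag > 0 else 'instructor' if self.peak_lag < 0 else 'zero'} leads)",
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Coupling as a function of lag; positive lags = learner leads."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.profile.offsets, self.profile.values)
        ax.axvline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("lag (s)  [positive: learner leads]")
        ax.set_ylabel("|Fisher-z| coupling")
        ax.set_title(f"BtBC lag profile {self.model.dyad_id} {self.model.condition}".strip())
        return ax


# The module-level convention constant is referenced so the dependency is
# explicit: the profile's positive half *is* the learner-leading side.
assert LEARNER_LEADS_SIGN == +1
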