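"""Segment-shuffled surrogate dyads and the chance-level permutation test.

A surrogate dyad re-pairs movement segments that never occurred at the same
time: one partner's series is cut into fixed-length segments (default 60 s)
whose order is then permuted (identity permutations are rejected), while
the other partner's series is left intact.  Within segments the time
structure — and hence each person's marginal value distribution and
autocorrelation — is preserved exactly, so the pseudo-coupling of surrogate
pairings estimates the coupling expected by chance.

The group-level test compares the grand mean of genuine overall couplings
against a null distribution built by repeatedly drawing one pseudo-coupling
per dyad from its surrogate ensemble and averaging.  The study's own
surrogate construction (100 pseudo-pairings per dyad) does not pin down a
group-level resampling rule, so this dyad-level resampling (default 10000
resamples) is this package's construction; it is logged on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coupling import LagGrid, summarize_btbc, windowed_lagged_xcorr
from .motion import MotionSeries

__all__ = [
    "SurrogateEnsemble",
    "PermutationResult",
    "shuffle_segments",
    "make_surrogates",
    "test_genuine_vs_surrogate",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SURROGATES = 100
DEFAULT_SEGMENT = 60.0  # seconds
DEFAULT_N_RESAMPLES = 10_000


@dataclass
class SurrogateEnsemble:
    """Pseudo-coupling values from segment-shuffled pseudo-pairings."""

    dyad_id: str
    condition: str
    n_surrogates: int
    segment_length: float
    values: np.ndarray
    permutations: np.ndarray  # (n_surrogates, n_segments) segment orders
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_surrogates:
            raise ValueError("ensemble size mismatch")
        if np.any(self.values < 0):
            raise ValueError("pseudo-coupling values must be non-negative")


@dataclass
class PermutationResult:
    """Observed statistic against a resampled null, add-one p-value."""

    observed: float
    null_values: np.ndarray
    p: float
    n_resamples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")


def _segment_view(values: np.ndarray, seg_len: int) -> np.ndarray:
    n_seg = len(values) // seg_len
    return values[: n_seg * seg_len].reshape(n_seg, seg_len)


def shuffle_segments(series: MotionSeries, segment: float, perm: np.ndarray) -> MotionSeries:
    """Reorder a series' fixed-length segments by ``perm`` (trailing
    remainder beyond a whole number of segments is dropped)."""
    seg_len = int(round(segment * series.sampling_rate))
    segs = _segment_view(series.values, seg_len)
    if len(perm) != len(segs):
        raise ValueError(f"permutation length {len(perm)} != {len(segs)} segments")
    return series.with_values(segs[np.asarray(perm)].reshape(-1))


def _restandardize(series: MotionSeries) -> MotionSeries:
    # Trimming to whole segments perturbs mean/SD slightly; per-window
    # Pearson r is affine-invariant, so re-centring is exact and harmless.
    x = series.values
    return series.with_values((x - x.mean()) / x.std(), standardized=True)


def make_surrogates(
    instructor: MotionSeries,
    learner: MotionSeries,
    n: int = DEFAULT_N_SURROGATES,
    segment: float = DEFAULT_SEGMENT,
    seed: int | None = None,
    *,
    window: float = 30.0,
    step: float = 1.0,
    grid: LagGrid | None = None,
    shuffle: str = "instructor",
    dyad_id: str = "",
    condition: str = "",
) -> SurrogateEnsemble:
    """Overall pseudo-BtBC of ``n`` segment-shuffled re-pairings of one dyad.

    One partner (default the instructor) has its segment order permuted per
    surrogate — uniformly random non-identity permutations, drawn with
    replacement across surrogates — while the other partner stays intact.
    Each pseudo-pairing's overall coupling is computed with the same
    windowed lagged cross-correlation as the genuine pairing.
    """
    if shuffle not in ("instructor", "learner"):
        raise ValueError("shuffle must be 'instructor' or 'learner'")
    if n < 1:
        raise ValueError("need at least one surrogate")
    fs = learner.sampling_rate
    seg_len = int(round(segment * fs))
    n_seg = len(learner) // seg_len
    if n_seg < 2:
        raise ValueError(
            f"need at least 2 whole segments of {segment} s; series has {len(learner)/fs:.1f} s"
        )
    dropped = len(learner) - n_seg * seg_len
    if dropped:
        logger.info(
            "surrogates %s/%s: dropping %d trailing samples beyond %d whole segments",
            dyad_id, condition, dropped, n_seg,
        )
    rng = np.random.default_rng(seed)
    grid = grid or LagGrid()

    keep = slice(0, n_seg * seg_len)
    fixed = _restandardize(learner.with_values(learner.values[keep])) \
        if shuffle == "instructor" else _restandardize(instructor.with_values(instructor.values[keep]))
    moving = instructor if shuffle == "instructor" else learner

    values = np.empty(n)
    perms = np.empty((n, n_seg), dtype=int)
    for k in range(n):
        perm = rng.permutation(n_seg)
        while np.array_equal(perm, np.arange(n_seg)):  # identity rejected
            perm = rng.permutation(n_seg)
        perms[k] = perm
        shuffled = _restandardize(shuffle_segments(moving, segment, perm))
        if shuffle == "instructor":
            profile = windowed_lagged_xcorr(shuffled, fixed, window, step, grid)
        else:
            profile = windowed_lagged_xcorr(fixed, shuffled, window, step, grid)
        values[k] = summarize_btbc(profile).overall
    return SurrogateEnsemble(
        dyad_id=dyad_id,
        condition=condition,
        n_surrogates=n,
        segment_length=segment,
        values=values,
        permutations=perms,
        seed=seed,
    )


def test_genuine_vs_surrogate(
    summaries,
    ensembles,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
) -> PermutationResult:
    """Group-level permutation test: genuine grand-mean BtBC vs chance.

    ``observed`` is the grand mean of the genuine per-record overall BtBC;
    each null resample draws one coupling value uniformly from every
    record's pool — its surrogate ensemble *plus its genuine value* — and
    averages.  Including the observed arrangement in the pool is what makes
    the permutation null valid (resampling only from the surrogates leaves
    the observed draw outside its own null and inflates the type-I error).
    p follows the add-one rule ``(1 + #{null >= observed}) /
    (1 + n_resamples)`` and is never 0.
    """
    summaries = np.asarray(list(summaries), dtype=float)
    ensembles = list(ensembles)
    if len(ensembles) == 0 or any(e.n_surrogates == 0 for e in ensembles):
        raise ValueError("empty surrogate ensembles")
    if len(summaries) != len(ensembles):
        raise ValueError("one ensemble per genuine record required")
    logger.info(
        "group permutation test: %d records, %d resamples of dyad-level pseudo-values (seed=%s)",
        len(summaries), n_resamples, seed,
    )
    rng = np.random.default_rng(seed)
    observed = float(summaries.mean())
    draws = np.empty((len(ensembles), n_resamples))
    for i, ens in enumerate(ensembles):
        pool = np.concatenate([[summaries[i]], ens.values])
        idx = rng.integers(0, len(pool), n_resamples)
        draws[i] = pool[idx]
    null = draws.mean(axis=0)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_resamples)
    return PermutationResult(
        observed=observed, null_values=null, p=p, n_resamples=n_resamples, seed=seed
    )
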