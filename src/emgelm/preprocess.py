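"""Signal conditioning: AVT stochastic filtering and GLR label refinement.

The AVT (Antonyan Vardan Transform derived) filter is a sliding-segment
outlier suppressor on the rectified signal.  For every 200 ms segment,
advanced 10 ms at a time, it forms an acceptance band MSA +/- MSD, where the
Mean Signal Amplitude and Mean Signal Deviation are weighted combinations of
the statistics of the already-seen 95% portion and the incoming 5% portion
(filter factors ff1/ff2).  Samples of the incoming stride outside the band
are replaced by the MSA value; nothing is discarded, so the output has the
same length as the input.

GLR relabeling corrects reaction-time misalignment between stimulation
labels and actual muscle activity: for each rest-movement-rest transition an
exhaustive grid search over candidate movement boundaries (t0, t1), in 30 ms
steps, maximizes the generalized likelihood ratio between a three-segment
Gaussian model (rest | movement | rest, each with its own mean and variance
of the rectified amplitude, log-likelihoods summed over channels) and the
single-segment model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("emgelm")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class AvtConfig:
    """AVT filter parameters.

    ``ff1`` weights the trailing (already filtered) portion of the segment,
    ``ff2`` the incoming stride; they must sum to 1.  Defaults follow the
    200 ms / 10 ms segmentation with ff1 = 0.8, ff2 = 0.2.
    """

    window_ms: float = 200.0
    stride_ms: float = 10.0
    ff1: float = 0.8
    ff2: float = 0.2

    def __post_init__(self) -> None:
        if not (self.window_ms > self.stride_ms > 0):
            raise ValueError("require window_ms > stride_ms > 0")
        if not (0 <= self.ff1 <= 1 and 0 <= self.ff2 <= 1):
            raise ValueError("ff1 and ff2 must lie in [0, 1]")
        if abs(self.ff1 + self.ff2 - 1.0) > 1e-9:
            raise ValueError("ff1 + ff2 must equal 1")


@dataclass(frozen=True)
class SegmentStats:
    """Acceptance band of one AVT segment: MSA centre, MSD half-width."""

    msa: float
    msd: float

    def __post_init__(self) -> None:
        if self.msd < 0:
            raise ValueError("msd must be nonnegative")

    @property
    def lower(self) -> float:
        return self.msa - self.msd

    @property
    def upper(self) -> float:
        return self.msa + self.msd


@dataclass(frozen=True)
class GlrConfig:
    """GLR boundary-search parameters (milliseconds)."""

    grid_ms: float = 30.0
    search_margin_ms: float = 500.0
    min_movement_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.grid_ms <= 0:
            raise ValueError("grid_ms must be positive")
        if self.search_margin_ms < self.grid_ms:
            raise ValueError("search_margin_ms must be >= grid_ms")
        if self.min_movement_ms < 0:
            raise ValueError("min_movement_ms must be nonnegative")


def _ms_to_samples(ms: float, sample_rate_hz: float) -> int:
    # round-half-even at the ms->samples boundary, consistent across the package
    return int(round(ms / 1000.0 * sample_rate_hz))


#: Relative slack on the MSA +/- MSD band: keeps constant signals exact fixed
#: points despite rounding in the segment mean (sigma = 0 => sample == MSA).
_BAND_RTOL = 1e-12


def _out_of_band(values: np.ndarray, msa: np.ndarray, msd: np.ndarray) -> np.ndarray:
    tol = msd + _BAND_RTOL * np.abs(msa)
    return np.abs(values - msa[:, None]) > tol[:, None]


def avt_filter(
    signal: np.ndarray,
    sample_rate_hz: float,
    config: AvtConfig | None = None,
) -> np.ndarray:
    """Apply the no-discard AVT filter per channel.

    A single causal streaming pass: each slide computes MSA/MSD from the
    current (already filtered) trailing portion and the incoming stride, and
    mutates only the incoming stride — samples outside [MSA - MSD, MSA + MSD]
    are replaced by MSA.  The first window is processed with unweighted
    whole-window statistics.  Negative inputs are rectified first.  Output
    shape equals input shape; trailing samples after the last complete window
    pass through untouched.
    """
    if config is None:
        config = AvtConfig()
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if x.size == 0:
        raise ValueError("empty signal")
    n = x.shape[1]
    W = _ms_to_samples(config.window_ms, sample_rate_hz)
    S = _ms_to_samples(config.stride_ms, sample_rate_hz)
    if S < 1 or W < 2 * S:
        raise ValueError(
            f"window of {W} samples must be at least two strides of {S} samples"
        )
    if n < W:
        raise ValueError(f"signal of {n} samples is shorter than one {W}-sample window")

    if np.any(x < 0):
        logger.info("avt_filter: negative input values; rectifying")
        y = np.abs(x)
    else:
        y = x.copy()

    # first window: unweighted whole-window stats, every sample eligible
    seg = y[:, :W]
    msa = seg.mean(axis=1)
    msd = seg.std(axis=1)
    y[:, :W] = np.where(_out_of_band(seg, msa, msd), msa[:, None], seg)

    n_slides = (n - W) // S
    ff1, ff2 = config.ff1, config.ff2
    for k in range(1, n_slides + 1):
        start = k * S
        old = y[:, start: start + W - S]
        inc = y[:, start + W - S: start + W]
        msa = ff1 * old.mean(axis=1) + ff2 * inc.mean(axis=1)
        msd = ff1 * old.std(axis=1) + ff2 * inc.std(axis=1)
        y[:, start + W - S: start + W] = np.where(
            _out_of_band(inc, msa, msd), msa[:, None], inc)

    if signal is not None and np.asarray(signal).ndim == 1:
        return y[0]
    return y


def _find_bursts(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode the nonzero runs of a label stream.

    Returns (start, end, class_id) per burst, end exclusive.
    """
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [
        (int(s), int(e), int(labels[s]))
        for s, e in zip(starts, ends)
        if labels[s] != 0
    ]


def _segment_loglik(cs1: np.ndarray, cs2: np.ndarray, i, j, var_floor: float) -> np.ndarray:
    """Gaussian log-likelihood of segments [i, j), summed over channels.

    ``cs1``/``cs2`` are zero-prepended cumulative sums of the rectified
    amplitude and its square, shape (channels, n+1).  Maximum-likelihood
    (population) variance, floored to avoid -inf on constant segments.
    ``i`` and ``j`` broadcast against each other; empty segments contribute 0.
    """
    i, j = np.broadcast_arrays(np.asarray(i), np.asarray(j))
    nseg = (j - i).astype(float)
    s1 = cs1[:, j] - cs1[:, i]  # (channels, ...)
    s2 = cs2[:, j] - cs2[:, i]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1 / nseg
        var = np.maximum(s2 / nseg - mean ** 2, var_floor)
        ll = -0.5 * nseg * (_LOG_2PI + np.log(var) + 1.0)
    return np.where(nseg > 0, ll, 0.0).sum(axis=0)


def glr_relabel(
    signal: np.ndarray,
    stim_labels: np.ndarray,
    sample_rate_hz: float,
    config: GlrConfig | None = None,
) -> np.ndarray:
    """Refine movement boundaries by exhaustive GLR grid search.

    For each burst in ``stim_labels`` the candidate onset t0 sweeps a
    ``grid_ms``-spaced grid within ``search_margin_ms`` of the stimulation
    onset, and for each t0 the candidate offset t1 sweeps the grid around the
    stimulation offset; the (t0, t1) pair (with t1 - t0 >= min_movement_ms)
    maximizing the three-segment-vs-one-segment Gaussian log-likelihood ratio
    of the rectified amplitude defines the refined burst.  Class ids and
    burst count are preserved; rest (0) elsewhere.  Ties break to the
    earliest pair in scan order.  If no rest-movement-rest transition exists
    the input labels are returned unchanged with a warning.
    """
    if config is None:
        config = GlrConfig()
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    stim_labels = np.asarray(stim_labels, dtype=np.int64)
    n = x.shape[1]
    if stim_labels.shape[0] != n:
        raise ValueError("stim_labels length does not match signal")

    bursts = _find_bursts(stim_labels)
    if not bursts:
        warnings.warn("glr_relabel: no movement bursts found; labels unchanged")
        return stim_labels.copy()

    rect = np.abs(x)
    cs1 = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(rect, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(rect ** 2, axis=1)], axis=1)
    rng_amp = float(rect.max() - rect.min())
    var_floor = max(1e-12 * rng_amp ** 2, np.finfo(float).tiny)

    grid = _ms_to_samples(config.grid_ms, sample_rate_hz)
    margin = _ms_to_samples(config.search_margin_ms, sample_rate_hz)
    min_move = _ms_to_samples(config.min_movement_ms, sample_rate_hz)

    refined = np.zeros(n, dtype=np.int64)
    for bi, (onset, offset, cls) in enumerate(bursts):
        # analysis window clamped to the signal and to midpoints between
        # neighbouring bursts so searches never overlap
        lo_lim = 0 if bi == 0 else (bursts[bi - 1][1] + onset) // 2
        hi_lim = n if bi == len(bursts) - 1 else (offset + bursts[bi + 1][0]) // 2
        ws = max(onset - margin, lo_lim)
        we = min(offset + margin, hi_lim)

        t0_grid = onset + grid * np.arange(-(margin // grid), margin // grid + 1)
        t0_grid = t0_grid[(t0_grid >= ws) & (t0_grid < we)]
        t1_grid = offset + grid * np.arange(-(margin // grid), margin // grid + 1)
        t1_grid = t1_grid[(t1_grid > ws) & (t1_grid <= we)]
        if t0_grid.size == 0 or t1_grid.size == 0:
            refined[onset:offset] = cls
            continue
        rest1_ll = _segment_loglik(cs1, cs2, ws, t0_grid, var_floor)
        rest2_ll = _segment_loglik(cs1, cs2, t1_grid, we, var_floor)
        best = (-np.inf, onset, offset)
        for ti, t0 in enumerate(t0_grid):
            ok = t1_grid - t0 >= max(min_move, 1)
            if not np.any(ok):
                continue
            t1s = t1_grid[ok]
            ll = (
                rest1_ll[ti]
                + _segment_loglik(cs1, cs2, int(t0), t1s, var_floor)
                + rest2_ll[ok]
            )
            k = int(np.argmax(ll))
            # strict > keeps the earliest pair in scan order on ties
            if ll[k] > best[0]:
                best = (float(ll[k]), int(t0), int(t1s[k]))
        _, t0, t1 = best
        refined[t0:t1] = cls

    return refined
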