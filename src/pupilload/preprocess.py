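"""Pupil-trace cleaning: channel merging, Hampel outlier removal, blink
interpolation, and interval extraction.

The Hampel filter slides a ``2k + 1``-sample window along the series; a
sample deviating from the window median by more than ``n_mads`` scaled
median absolute deviations is replaced by that median.  The MAD is scaled by
1.4826 so the threshold is expressed in Gaussian-sigma-equivalent units, and
a small floor on the MAD prevents a locally constant signal from flagging
every harmless fluctuation.  Missing samples are excluded from window
statistics and are never themselves replaced.

Every cleaning step preserves timestamps and records per-sample provenance
flags, so the number of replaced / interpolated / missing samples is always
reportable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PupilTrace

__all__ = [
    "CleanTrace",
    "BaselineEstimate",
    "FLAG_RAW",
    "FLAG_HAMPEL",
    "FLAG_INTERP",
    "FLAG_MISSING",
    "merge_eyes",
    "hampel_filter",
    "interpolate_blinks",
    "extract_interval",
    "estimate_baseline",
    "clean_trace",
]

FLAG_RAW = 0
FLAG_HAMPEL = 1
FLAG_INTERP = 2
FLAG_MISSING = 3

#: MAD-to-sigma consistency constant for Gaussian data.
MAD_SCALE = 1.4826
#: floor (pixels) applied to the window MAD before thresholding
EPS_FLOOR = 0.01


@dataclass
class CleanTrace:
    """A merged, cleaned single-channel pupil series with provenance flags."""

    t: np.ndarray
    d: np.ndarray
    flags: np.ndarray
    rate_hz: float
    participant_id: str = ""
    interval_tag: str = "measurement"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.flags = np.asarray(self.flags, dtype=np.uint8)
        if not (self.t.size == self.d.size == self.flags.size):
            raise ValueError("t, d, flags must have equal length")
        if self.t.size == 0:
            raise ValueError("no samples")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.d[np.isfinite(self.d)] <= 0):
            raise ValueError("non-missing diameters must be positive")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.d)))

    @property
    def counts(self) -> dict[str, int]:
        return {
            "raw": int(np.sum(self.flags == FLAG_RAW)),
            "hampel_replaced": int(np.sum(self.flags == FLAG_HAMPEL)),
            "interpolated": int(np.sum(self.flags == FLAG_INTERP)),
            "missing": int(np.sum(self.flags == FLAG_MISSING)),
        }


@dataclass(frozen=True)
class BaselineEstimate:
    """Mean pupil diameter over a designated baseline window."""

    mean_d: float
    window: tuple[float, float]
    n_valid: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_d) or self.mean_d <= 0:
            raise ValueError("baseline mean must be positive and finite")


def merge_eyes(trace: PupilTrace) -> CleanTrace:
    """Average the two eye channels; a sample is missing only if both are."""
    both = np.stack([trace.d_left, trace.d_right])
    finite = np.isfinite(both)
    n_valid = finite.sum(axis=0)
    total = np.where(finite, both, 0.0).sum(axis=0)
    d = np.divide(total, n_valid, out=np.full(n_valid.shape, np.nan),
                  where=n_valid > 0)
    flags = np.where(np.isfinite(d), FLAG_RAW, FLAG_MISSING).astype(np.uint8)
    return CleanTrace(trace.t, d, flags, trace.rate_hz,
                      trace.participant_id, trace.interval_tag)


def _row_nanmedian(windows: np.ndarray) -> np.ndarray:
    """Median per row ignoring NaNs; NaN for all-NaN rows.  Sort-based, fast."""
    a = np.sort(windows, axis=1)  # NaNs sort to the end
    n_valid = np.sum(np.isfinite(windows), axis=1)
    out = np.full(windows.shape[0], np.nan)
    ok = n_valid > 0
    lo = np.maximum(n_valid - 1, 0) // 2
    hi = np.maximum(n_valid, 1) // 2
    rows = np.arange(windows.shape[0])
    vals = 0.5 * (a[rows, lo] + a[rows, hi])
    out[ok] = vals[ok]
    return out


def hampel_filter(
    series: np.ndarray,
    half_window: int = 5,
    n_mads: float = 3.0,
    eps_floor: float = EPS_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Hampel filter a series with NaN-coded missing samples.

    Returns ``(filtered, replaced)`` where ``replaced`` is a boolean mask of
    samples substituted by their window median.  Windows at the edges are
    truncated.  A sample ``x`` with window median ``m`` and window MAD is
    replaced when ``|x - m| > n_mads * 1.4826 * max(MAD, eps_floor)``.
    """
    x = np.asarray(series, dtype=float)
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    n = x.size
    k = half_window
    padded = np.concatenate([np.full(k, np.nan), x, np.full(k, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * k + 1)
    med = _row_nanmedian(windows)
    mad = _row_nanmedian(np.abs(windows - med[:, None]))
    threshold = n_mads * MAD_SCALE * np.maximum(mad, eps_floor)
    with np.errstate(invalid="ignore"):
        replaced = np.isfinite(x) & np.isfinite(med) & (np.abs(x - med) > threshold)
    out = x.copy()
    out[replaced] = med[replaced]
    return out, replaced


def interpolate_blinks(trace: CleanTrace, max_gap_ms: float = 500.0) -> CleanTrace:
    """Linearly fill short missing runs; long runs stay missing.

    A run is filled only when the unobserved span between its flanking valid
    samples, ``t[next_valid] - t[prev_valid]``, does not exceed
    ``max_gap_ms``.  Leading and trailing runs have no flank on one side and
    are never extrapolated.
    """
    d = trace.d.copy()
    flags = trace.flags.copy()
    valid = np.isfinite(d)
    if not valid.any():
        raise ValueError("no valid samples")
    idx = np.arange(d.size)
    missing = ~valid
    if missing.any():
        # boundaries of missing runs
        starts = np.flatnonzero(missing & ~np.r_[False, missing[:-1]])
        ends = np.flatnonzero(missing & ~np.r_[missing[1:], False])
        for s, e in zip(starts, ends):
            if s == 0 or e == d.size - 1:
                continue  # edge run: no extrapolation
            t0, t1 = trace.t[s - 1], trace.t[e + 1]
            if t1 - t0 > max_gap_ms:
                continue
            d[s:e + 1] = np.interp(trace.t[s:e + 1], [t0, t1], [d[s - 1], d[e + 1]])
            flags[s:e + 1] = FLAG_INTERP
    return CleanTrace(trace.t, d, flags, trace.rate_hz,
                      trace.participant_id, trace.interval_tag)


def extract_interval(trace, t_start: float, t_end: float, tag: str):
    """Select samples with ``t_start <= t < t_end`` (half-open, ms).

    Works on both :class:`~pupilload.io.PupilTrace` and :class:`CleanTrace`;
    returns the same type with ``interval_tag`` set to ``tag``.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    mask = (trace.t >= t_start) & (trace.t < t_end)
    if not mask.any():
        raise ValueError(f"no samples in [{t_start}, {t_end}) ms")
    if isinstance(trace, PupilTrace):
        return PupilTrace(trace.t[mask], trace.d_left[mask], trace.d_right[mask],
                          trace.rate_hz, trace.participant_id, tag)
    return CleanTrace(trace.t[mask], trace.d[mask], trace.flags[mask],
                      trace.rate_hz, trace.participant_id, tag)


def estimate_baseline(
    trace: CleanTrace,
    window_ms: float = 2000.0,
    min_valid_frac: float = 0.5,
) -> BaselineEstimate:
    """Mean diameter over the final ``window_ms`` of a baseline interval.

    The window ends one sample period past the last timestamp so the final
    sample is included under the half-open convention.  Errors out when fewer
    than ``min_valid_frac`` of the expected samples are valid.
    """
    dt = 1000.0 / trace.rate_hz
    t_end = float(trace.t[-1]) + dt
    t_start = t_end - window_ms
    mask = (trace.t >= t_start) & (trace.t < t_end)
    d = trace.d[mask]
    n_valid = int(np.sum(np.isfinite(d)))
    n_expected = max(int(round(window_ms / dt)), 1)
    if n_valid < min_valid_frac * n_expected:
        raise ValueError(
            f"insufficient baseline data: {n_valid}/{n_expected} valid samples"
        )
    return BaselineEstimate(
        mean_d=float(np.nanmean(d)), window=(t_start, t_end), n_valid=n_valid
    )


def clean_trace(
    trace: PupilTrace,
    hampel_half_window: int = 5,
    hampel_n_mads: float = 3.0,
    max_gap_ms: float = 500.0,
) -> CleanTrace:
    """Standard cleaning pipeline: merge eyes, Hampel filter, fill blinks."""
    merged = merge_eyes(trace)
    filtered, replaced = hampel_filter(merged.d, hampel_half_window, hampel_n_mads)
    flags = merged.flags.copy()
    flags[replaced] = FLAG_HAMPEL
    ct = CleanTrace(merged.t, filtered, flags, merged.rate_hz,
                    merged.participant_id, merged.interval_tag)
    return interpolate_blinks(ct, max_gap_ms)
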