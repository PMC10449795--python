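"""Pupil-trace processing for pupillary-light-reflex comparisons.

A smartphone prototype records pupil size in *pixels* at 60 Hz while a clinical
pupillometer records *millimeters* at 30 Hz, so traces are made comparable by
(1) downsampling the faster trace to the common 30 Hz base, (2) excluding
blink-contaminated samples from both devices jointly, and (3) normalising each
trace to percent change from its own mean, which removes the unit entirely.
Temporal alignment between the two recordings (started by simultaneous button
press) is automated by maximising Pearson correlation over a small lag grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PupilTrace",
    "AlignedTracePair",
    "AlignmentError",
    "AllSamplesExcludedError",
    "downsample_trace",
    "percent_change_from_mean",
    "flag_blink_spikes",
    "align_traces",
    "exclude_blinks",
]


class AlignmentError(RuntimeError):
    """Raised when no lag leaves enough jointly valid overlap to compare."""


class AllSamplesExcludedError(ValueError):
    """Raised when every sample of a trace is blink-excluded or missing."""


@dataclass
class PupilTrace:
    """A time-stamped pupil-diameter series with per-sample blink flags.

    ``unit`` is carried as metadata ("px", "mm", or "percent" after
    normalisation) and never mixed implicitly.  Diameters may be NaN where
    detection failed; such samples must also be blink-flagged.
    """

    timestamps_s: np.ndarray
    diameter: np.ndarray
    blink: np.ndarray
    unit: str = "px"
    confidence: np.ndarray | None = None
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.blink = np.asarray(self.blink, dtype=bool)
        if not (len(self.timestamps_s) == len(self.diameter) == len(self.blink)):
            raise ValueError("trace arrays must have equal length")
        if len(self.timestamps_s) > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps_s)

    @property
    def sample_rate_hz(self) -> float:
        if len(self) < 2:
            raise ValueError("cannot infer sample rate from fewer than 2 samples")
        return float(1.0 / np.median(np.diff(self.timestamps_s)))

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.blink & np.isfinite(self.diameter)


def downsample_trace(trace: PupilTrace, target_rate_hz: float = 30.0, method: str = "mean") -> PupilTrace:
    """Downsample to ``target_rate_hz`` (source rate must be an integer multiple).

    With the default ``method="mean"`` each output sample is the mean of its
    source window (NaNs ignored); ``"decimate"`` keeps the first sample of the
    window.  A window containing any blink-flagged source sample is
    blink-flagged in the output.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    ratio = trace.sample_rate_hz / target_rate_hz
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6 * max(1.0, ratio):
        raise ValueError(f"source rate {trace.sample_rate_hz:.6g} Hz is not an integer multiple of {target_rate_hz:.6g} Hz")
    if k == 1:
        return replace(trace)
    m = len(trace) // k
    if m == 0:
        raise ValueError("trace too short to downsample")
    t = trace.timestamps_s[: m * k].reshape(m, k)
    d = trace.diameter[: m * k].reshape(m, k)
    b = trace.blink[: m * k].reshape(m, k)
    blink_out = b.any(axis=1) | ~np.isfinite(d).all(axis=1)
    if method == "mean":
        counts = np.isfinite(d).sum(axis=1)
        d_out = np.where(counts > 0, np.nansum(np.where(np.isfinite(d), d, 0.0), axis=1) / np.maximum(counts, 1), np.nan)
        t_out = t.mean(axis=1)
    elif method == "decimate":
        d_out = d[:, 0]
        t_out = t[:, 0]
    else:
        raise ValueError(f"unknown downsampling method {method!r}")
    return PupilTrace(timestamps_s=t_out, diameter=d_out, blink=blink_out, unit=trace.unit)


def percent_change_from_mean(trace: PupilTrace) -> PupilTrace:
    """Normalise to ``100 * (d - d_mean) / d_mean``.

    The reference mean is computed over non-excluded samples only, so spurious
    blink diameters cannot bias it.  The result is unit-free: a trace in px
    and the same trace in mm (or scaled by any positive constant) map to the
    identical percent-change trace.
    """
    valid = trace.valid_mask
    if not valid.any():
        raise AllSamplesExcludedError("no non-excluded samples to compute the reference mean")
    dbar = float(trace.diameter[valid].mean())
    if dbar <= 0:
        raise ValueError("mean diameter of non-excluded samples must be positive")
    pct = 100.0 * (trace.diameter - dbar) / dbar
    return PupilTrace(timestamps_s=trace.timestamps_s.copy(), diameter=pct, blink=trace.blink.copy(), unit="percent")


def flag_blink_spikes(trace: PupilTrace, window: int = 5, threshold: float = 0.2) -> PupilTrace:
    """Flag dropout spikes: samples deviating from their local median.

    A sample is flagged when detection already failed (NaN) or when
    ``|d - median(window neighbours)| > threshold * local median``.  This is a
    stand-in blink detector for prototype-style traces whose acquisition
    device reports no blink channel of its own.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    d = trace.diameter
    n = len(d)
    blink = trace.blink.copy() | ~np.isfinite(d)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        neigh = d[lo:hi]
        neigh = neigh[np.isfinite(neigh)]
        if neigh.size == 0 or not np.isfinite(d[i]):
            continue
        med = float(np.median(neigh))
        if med > 0 and abs(d[i] - med) > threshold * med:
            blink[i] = True
    return replace(trace, blink=blink)


@dataclass
class AlignedTracePair:
    """Two percent-change traces on a common 30 Hz base after lag alignment.

    ``lag_s`` is how much trace ``b`` is delayed relative to ``a`` (positive:
    ``b`` started later).  ``excluded`` is the joint mask: a sample flagged as
    a blink (or missing) in *either* source is excluded from *both*.
    """

    timestamps_s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    excluded: np.ndarray
    lag_s: float
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if not (len(self.timestamps_s) == len(self.a) == len(self.b) == len(self.excluded)):
            raise ValueError("aligned pair arrays must have equal length")

    def __len__(self) -> int:
        return len(self.timestamps_s)

    @property
    def n_valid(self) -> int:
        return int((~self.excluded).sum())

    def valid_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.excluded
        return self.a[keep], self.b[keep]


def _pair_at_lag(a: PupilTrace, b: PupilTrace, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index windows pairing a[i] with b[i + k], truncated to common support."""
    na, nb = len(a), len(b)
    i0 = max(0, -k)
    i1 = min(na, nb - k)
    if i1 <= i0:
        return np.array([]), np.array([]), np.array([]), np.array([])
    idx_a = np.arange(i0, i1)
    idx_b = idx_a + k
    av, bv = a.diameter[idx_a], b.diameter[idx_b]
    excl = ~(a.valid_mask[idx_a] & b.valid_mask[idx_b])
    return av, bv, excl, a.timestamps_s[idx_a]


def align_traces(a: PupilTrace, b: PupilTrace, max_lag_s: float = 0.5, min_overlap: int = 10) -> AlignedTracePair:
    """Align two same-rate percent-change traces by cross-correlation.

    The lag is chosen on a grid of whole samples in ``[-max_lag_s, max_lag_s]``
    to maximise Pearson correlation over the jointly non-excluded overlap;
    ties prefer the smaller absolute lag, so identical traces align at lag 0.
    With ``max_lag_s = 0`` the traces are compared as-is.
    """
    if max_lag_s < 0:
        raise ValueError("max_lag_s must be >= 0")
    rate = a.sample_rate_hz
    if abs(rate - b.sample_rate_hz) > 0.01 * rate:
        raise ValueError("traces must share a sample rate before alignment")
    k_max = int(round(max_lag_s * rate))
    best: tuple[float, int] | None = None
    for k in sorted(range(-k_max, k_max + 1), key=lambda k: (abs(k), k)):
        av, bv, excl, _ = _pair_at_lag(a, b, k)
        keep = ~excl
        if keep.sum() < min_overlap:
            continue
        x, y = av[keep], bv[keep]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if best is None or r > best[0] + 1e-12:
            best = (r, k)
    if best is None:
        raise AlignmentError(f"no lag within +/-{max_lag_s} s leaves >= {min_overlap} jointly valid samples")
    k = best[1]
    av, bv, excl, ts = _pair_at_lag(a, b, k)
    return AlignedTracePair(
        timestamps_s=ts, a=av, b=bv, excluded=excl, lag_s=k / rate, sample_rate_hz=rate
    )


def exclude_blinks(pair: AlignedTracePair) -> AlignedTracePair:
    """Drop jointly excluded samples so they are absent from all statistics."""
    keep = ~pair.excluded
    return AlignedTracePair(
        timestamps_s=pair.timestamps_s[keep],
        a=pair.a[keep],
        b=pair.b[keep],
        excluded=np.zeros(int(keep.sum()), dtype=bool),
        lag_s=pair.lag_s,
        sample_rate_hz=pair.sample_rate_hz,
    )
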