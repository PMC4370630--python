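"""Quality control and preprocessing of raw sensor series.

The preprocessing chain mirrors standard practice for autonomous reef
sensors: trim the deployment window, invalidate physically impossible values
and single-sample spikes, resample to a uniform grid (wavelet transforms need
one), and apply a zero-phase one-hour low-pass filter.

The low-pass realization is a 4th-order Butterworth applied forward-backward
(so effectively 8th order in magnitude, zero phase) with cutoff 1/3600 s⁻¹.
Zero phase matters: wavelet phase and coherence downstream depend on the
timing of diel extrema, which a causal filter would shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import EmptySeriesError, InvalidConfigError
from .series import EnvironmentalSeries

#: Default physical plausibility ranges per variable.
DEFAULT_RANGES = {
    "pH_total": (7.0, 9.0),
    "temperature_C": (10.0, 40.0),
    "salinity": (20.0, 40.0),
    "depth_m": (0.0, 50.0),
    "voltage_V": (-2.0, 2.0),
}


@dataclass
class QcReport:
    """Bookkeeping for one cleaning pass: n_input − removals = valid output."""

    n_input: int
    n_removed_out_of_range: int = 0
    n_removed_spike: int = 0
    segments_excluded: list = field(default_factory=list)

    @property
    def n_valid_output(self) -> int:
        return self.n_input - self.n_removed_out_of_range - self.n_removed_spike

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_out_of_range": self.n_removed_out_of_range,
            "n_removed_spike": self.n_removed_spike,
            "n_valid_output": self.n_valid_output,
            "segments_excluded": [[str(a), str(b)] for a, b in self.segments_excluded],
        }


def trim(series: EnvironmentalSeries, start, stop) -> EnvironmentalSeries:
    """Retain samples with timestamps in [start, stop] (inclusive endpoints)."""
    start = np.datetime64(start, "ns")
    stop = np.datetime64(stop, "ns")
    if start >= stop:
        raise InvalidConfigError("trim start must precede stop")
    keep = (series.timestamps >= start) & (series.timestamps <= stop)
    if not keep.any():
        raise EmptySeriesError("trim window contains no samples")
    return EnvironmentalSeries(
        site=series.site,
        variable=series.variable,
        timestamps=series.timestamps[keep],
        values=series.values[keep],
        valid=series.valid[keep],
    )


def clean_outliers(
    series: EnvironmentalSeries,
    *,
    valid_range: tuple[float, float] | None = None,
    spike_k: float | None = 6.0,
    spike_window: str = "6h",
) -> tuple[EnvironmentalSeries, QcReport]:
    """Invalidate out-of-range values and single-sample spikes.

    A sample is a spike when its deviation from the centered rolling median
    (window ``spike_window``) exceeds ``spike_k`` times the rolling median
    absolute deviation (raw MAD, no normal-consistency scaling).  Samples
    whose local MAD is zero are never flagged as spikes.  Empty rules
    (``valid_range=None, spike_k=None``) make this a pass-through.

    The exact QC criteria used on real deployments vary; both thresholds are
    configurable for that reason.
    """
    out = series.copy()
    report = QcReport(n_input=series.n_valid)

    if valid_range is None:
        valid_range = DEFAULT_RANGES.get(series.variable)
    if valid_range is not None:
        lo, hi = valid_range
        bad = out.valid & ((out.values < lo) | (out.values > hi) | ~np.isfinite(out.values))
        report.n_removed_out_of_range = int(bad.sum())
        out.valid[bad] = False

    if spike_k is not None and out.n_valid >= 5:
        s = pd.Series(np.where(out.valid, out.values, np.nan), index=pd.DatetimeIndex(out.timestamps))
        med = s.rolling(spike_window, center=True, min_periods=3).median()
        dev = (s - med).abs()
        mad = dev.rolling(spike_window, center=True, min_periods=3).median()
        spike = out.valid & (mad.to_numpy() > 0) & (dev.to_numpy() > spike_k * mad.to_numpy())
        report.n_removed_spike = int(spike.sum())
        out.valid[spike] = False

    return out, report


def resample_uniform(
    series: EnvironmentalSeries,
    dt_seconds: float,
    *,
    gap_tolerance_seconds: float | None = None,
) -> EnvironmentalSeries:
    """Linearly interpolate valid samples onto a uniform grid.

    Grid points bracketed by valid samples more than ``gap_tolerance_seconds``
    apart stay invalid — interpolation never invents data inside an excluded
    segment.  The default tolerance is 3× the requested dt.
    """
    if dt_seconds <= 0:
        raise InvalidConfigError("dt must be positive")
    if series.n_valid < 2:
        raise EmptySeriesError("need at least 2 valid samples to resample")
    if gap_tolerance_seconds is None:
        gap_tolerance_seconds = 3.0 * dt_seconds

    t = series.t_seconds
    tv = t[series.valid]
    vv = series.values[series.valid]
    n_out = int(np.floor((t[-1] - t[0]) / dt_seconds)) + 1
    t_new = np.arange(n_out) * dt_seconds
    values = np.interp(t_new, tv, vv)

    # a grid point is valid when its bracketing valid samples are close enough
    right = np.searchsorted(tv, t_new, side="left")
    left = np.clip(right - 1, 0, len(tv) - 1)
    right = np.clip(right, 0, len(tv) - 1)
    on_sample = np.isclose(t_new[:, None], tv[np.stack([left, right], axis=1)], atol=1e-9).any(axis=1)
    gap = tv[right] - tv[left]
    valid = on_sample | (gap <= gap_tolerance_seconds)
    valid &= (t_new >= tv[0] - 1e-9) & (t_new <= tv[-1] + 1e-9)

    t0 = series.timestamps[0]
    timestamps = t0 + (t_new * 1e9).astype("timedelta64[ns]")
    return EnvironmentalSeries(
        site=series.site, variable=series.variable,
        timestamps=timestamps, values=values, valid=valid,
    )


def lowpass_1h(series: EnvironmentalSeries, *, cutoff_hours: float = 1.0,
               order: int = 4) -> EnvironmentalSeries:
    """Zero-phase Butterworth low-pass with a one-hour cutoff period.

    Requires a uniform grid with dt ≤ 30 min.  Each contiguous run of valid
    samples is filtered independently; runs too short for the filter's edge
    padding are left unfiltered (they stay valid and unchanged).  Because the
    filter's DC gain is exactly one, each segment is re-centered to its input
    mean after filtering, cancelling the small mean drift that edge transients
    would otherwise introduce.
    """
    dt = series.dt
    if dt is None:
        raise InvalidConfigError("lowpass_1h requires a uniformly sampled series")
    if dt > 1800.0:
        raise InvalidConfigError("lowpass_1h requires dt <= 30 minutes")
    fc = 1.0 / (cutoff_hours * 3600.0)
    sos = butter(order, fc, btype="low", fs=1.0 / dt, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))

    out = series.copy()
    v = out.valid
    # contiguous valid runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], v.astype(int), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a > padlen:
            seg = sosfiltfilt(sos, series.values[a:b])
            out.values[a:b] = seg + (series.values[a:b].mean() - seg.mean())
    return out
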