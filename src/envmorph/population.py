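"""Population-level curve statistics for plate-reader assays.

Growth rates are log-derivatives d ln(OD)/dt from a centered windowed
linear fit; lysis curves are normalized to the OD at the moment of transfer
to spent medium; replicate curves are summarized pointwise by mean and
sample standard deviation; permeability readouts are expressed as relative
light units, fluorescence divided by OD600.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .synthetic import ODCurve

__all__ = [
    "NormalizedCurve", "RateSeries", "od_growth_rate", "normalize_at_transfer",
    "replicate_summary", "relative_light_units",
]


@dataclass
class NormalizedCurve:
    """OD curve rescaled to 1 at the transfer time (times shifted to t=0)."""

    times: np.ndarray
    value: np.ndarray
    replicate_id: str = ""


@dataclass(frozen=True)
class RateSeries:
    times: np.ndarray
    rate: np.ndarray      # 1/h
    max_rate: float       # 1/h


def od_growth_rate(curve: ODCurve, window: int = 5) -> RateSeries:
    """d ln(OD)/dt by a centered local linear fit of ln(OD) against time.

    Ends use the largest centered window available (>= 3 points).  Also
    reports the maximum rate over the series.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    t = np.asarray(curve.times, float)
    od = np.asarray(curve.od, float)
    if np.any(od <= 0):
        raise ValueError("nonpositive OD in curve")
    if len(t) < window:
        raise ValueError("curve shorter than the fit window")
    ln_od = np.log(od)
    half = window // 2
    n = len(t)
    rate = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        lo, hi = i - h, i + h + 1
        if hi - lo < 3:
            lo, hi = (0, 3) if i < half else (n - 3, n)
        rate[i] = np.polyfit(t[lo:hi], ln_od[lo:hi], 1)[0]
    return RateSeries(times=t, rate=rate, max_rate=float(rate.max()))


def normalize_at_transfer(curve: ODCurve, t_transfer: float) -> NormalizedCurve:
    """Divide the curve by its OD at the sample closest to the transfer time.

    Times are shifted so the transfer sample sits at t = 0; the normalized
    value there is exactly 1.  Normalization is idempotent: renormalizing an
    already-normalized curve at t = 0 changes nothing.
    """
    t = np.asarray(curve.times, float)
    od = np.asarray(curve.od, float)
    if not (t.min() <= t_transfer <= t.max()):
        raise ValueError("transfer time outside the measured range")
    i0 = int(np.argmin(np.abs(t - t_transfer)))
    if od[i0] <= 0:
        raise ValueError("OD at transfer is nonpositive")
    return NormalizedCurve(times=t - t[i0], value=od / od[i0],
                           replicate_id=curve.replicate_id)


def replicate_summary(curves: Sequence[Union[ODCurve, NormalizedCurve]]):
    """Pointwise mean and sample SD across replicate curves.

    Curves on different time grids are linearly interpolated onto the union
    of time points restricted to the overlapping range (no extrapolation).
    Returns ``(times, mean, sd)``; ``sd`` is ``None`` for a single replicate.
    """
    if not curves:
        raise ValueError("no curves")

    def _tv(c):
        v = c.od if isinstance(c, ODCurve) else c.value
        return np.asarray(c.times, float), np.asarray(v, float)

    series = [_tv(c) for c in curves]
    if len(series) == 1:
        t, v = series[0]
        return t, v, None
    lo = max(t.min() for t, _ in series)
    hi = min(t.max() for t, _ in series)
    grid = np.unique(np.concatenate([t[(t >= lo) & (t <= hi)] for t, _ in series]))
    vals = np.vstack([np.interp(grid, t, v) for t, v in series])
    return grid, vals.mean(axis=0), vals.std(axis=0, ddof=1)


def relative_light_units(fluorescence: float, od: float) -> float:
    """Permeability readout: fluorescence normalized by OD600."""
    if od <= 0:
        raise ValueError("OD must be positive")
    return fluorescence / od
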