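"""Single-cell statistics: instantaneous growth rate, width CV, shape-group
comparisons, membrane-rupture ordering, and viability fractions.

The instantaneous growth rate is the slope of a local least-squares fit of
``ln A`` against time (projected cell area as biomass proxy).  The width
coefficient of variation — the shape-defect metric — is the sample standard
deviation over the mean of local widths along the cell body, pole stations
excluded.  Rupture ordering compares the loss times of a periplasmic and a
cytoplasmic fluorescence channel: an outer-membrane-first rupture keeps the
cytoplasmic marker after the periplasmic one is gone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union
import warnings

import numpy as np
from scipy import stats

from .contours import CenterlineMesh
from .synthetic import CellTrack, FluorTrace

__all__ = [
    "WidthStats", "RuptureCall", "ShapeGroup", "GroupedRates",
    "instantaneous_growth_rate", "width_cv", "group_by_shape",
    "call_rupture", "viability_fraction",
]


@dataclass(frozen=True)
class WidthStats:
    mean_width: float   # µm
    width_cv: float     # dimensionless, sd/mean over non-pole stations
    n_stations: int


@dataclass(frozen=True)
class RuptureCall:
    """Loss times of the two compartments and the inferred rupture order.

    ``order`` is one of ``"OM_first"`` (periplasmic marker lost more than a
    coincidence window before the cytoplasmic one), ``"coincident"``,
    ``"IM_first"``, or ``"none"`` (neither lost).
    """

    t_loss_periplasm: Optional[float]
    t_loss_cytoplasm: Optional[float]
    order: str


@dataclass(frozen=True)
class ShapeGroup:
    label: str
    n: int
    median_rate: float
    q25: float
    q75: float
    rates: np.ndarray


@dataclass(frozen=True)
class GroupedRates:
    groups: tuple[ShapeGroup, ...]
    #: KS test between adjacent groups: ((label_i, label_j), statistic, p)
    ks_adjacent: tuple[tuple[tuple[str, str], float, float], ...]


# --------------------------------------------------------------------------

def instantaneous_growth_rate(track: CellTrack, window: int = 5) -> np.ndarray:
    """Slope of a centered local linear fit of ln(area) vs time, per frame.

    Returns an ``(n, 2)`` array of ``(t, rate)``.  Interior frames use the
    full centered ``window``; frames near the ends use the largest centered
    window available, never fewer than 3 points.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    t = np.asarray(track.times, float)
    A = np.asarray(track.areas, float)
    if len(t) < window:
        raise ValueError(f"track has {len(t)} frames, needs >= {window}")
    if np.any(A <= 0):
        raise ValueError("nonpositive area in track")
    lnA = np.log(A)
    half = window // 2
    n = len(t)
    rates = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        if 2 * h + 1 < 3:
            h = 1
        lo, hi = max(0, i - h), min(n, i + h + 1)
        if hi - lo < 3:   # clamp end windows to 3 points
            lo, hi = (0, 3) if i < half else (n - 3, n)
        rates[i] = np.polyfit(t[lo:hi], lnA[lo:hi], 1)[0]
    return np.column_stack([t, rates])


def width_cv(mesh: CenterlineMesh) -> WidthStats:
    """Width coefficient of variation along the cell body, poles excluded.

    Uses the sample (n−1) standard deviation over non-pole station widths
    divided by their mean.  Requires at least 5 non-pole stations.
    """
    w = mesh.nonpole_widths()
    if len(w) < 5:
        raise ValueError(f"only {len(w)} non-pole stations; cell too short for a width CV")
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1))
    return WidthStats(mean_width=mean, width_cv=sd / mean, n_stations=len(w))


def group_by_shape(cells: Sequence[tuple[WidthStats, float]],
                   bin_edges: Optional[Sequence[float]] = None) -> GroupedRates:
    """Group cells by width CV and compare growth rates between groups.

    ``cells`` is a sequence of ``(WidthStats, mean growth rate)`` pairs.
    ``bin_edges`` are interior CV cut points; by default the quartiles of
    the observed CV distribution.  Per group the summary reports n, the
    median rate and the 25th/75th percentiles; adjacent groups are compared
    with a two-sample Kolmogorov–Smirnov test.  Empty groups are dropped
    with a warning.
    """
    cvs = np.array([ws.width_cv for ws, _ in cells])
    rates = np.array([r for _, r in cells])
    if bin_edges is None:
        bin_edges = np.quantile(cvs, [0.25, 0.5, 0.75])
    edges = np.concatenate([[-np.inf], np.asarray(bin_edges, float), [np.inf]])
    groups = []
    for k in range(len(edges) - 1):
        sel = (cvs >= edges[k]) & (cvs < edges[k + 1])
        label = f"CV[{edges[k]:.3g},{edges[k+1]:.3g})"
        if not sel.any():
            warnings.warn(f"shape group {label} is empty; dropped")
            continue
        g = rates[sel]
        groups.append(ShapeGroup(label=label, n=int(sel.sum()),
                                 median_rate=float(np.median(g)),
                                 q25=float(np.percentile(g, 25)),
                                 q75=float(np.percentile(g, 75)),
                                 rates=g))
    if len(groups) < 2:
        raise ValueError("need at least 2 nonempty shape groups")
    ks = []
    for g1, g2 in zip(groups[:-1], groups[1:]):
        res = stats.ks_2samp(g1.rates, g2.rates)
        ks.append(((g1.label, g2.label), float(res.statistic), float(res.pvalue)))
    return GroupedRates(groups=tuple(groups), ks_adjacent=tuple(ks))


# --------------------------------------------------------------------------

def _loss_time(t: np.ndarray, y: np.ndarray, threshold: float) -> Optional[float]:
    """Time y drops below threshold for good, sub-frame by linear interpolation.

    The loss frame is the first sample below the threshold that never
    recovers above it; the returned time interpolates the threshold
    crossing between that frame and the previous one.
    """
    below = y < threshold
    if not below.any():
        return None
    # last index where the signal is at/above threshold
    above_idx = np.nonzero(~below)[0]
    i = 0 if len(above_idx) == 0 else above_idx[-1] + 1
    if i >= len(t):
        return None  # recovered at the very end; never persistently lost
    if i == 0:
        return float(t[0])
    frac = (y[i - 1] - threshold) / (y[i - 1] - y[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def call_rupture(trace: FluorTrace, loss_frac: float = 0.5,
                 coincidence_window: Optional[float] = None) -> RuptureCall:
    """Classify the rupture order of one cell from its two-channel trace.

    A channel is *lost* at the first time it falls below ``loss_frac`` times
    its baseline (median of the first 3 frames) and never recovers above
    that threshold.  The order is ``OM_first`` when the periplasmic loss
    precedes the cytoplasmic one by more than ``coincidence_window``
    (default: one frame interval), ``coincident`` within the window,
    ``IM_first`` otherwise, and ``none`` when neither channel is lost.
    """
    t = np.asarray(trace.times, float)
    if len(t) < 3:
        raise ValueError("trace must have at least 3 frames")
    peri = np.asarray(trace.periplasm, float)
    cyto = np.asarray(trace.cytoplasm, float)
    base_p = float(np.median(peri[:3]))
    base_c = float(np.median(cyto[:3]))
    if base_p <= 0 or base_c <= 0:
        raise ValueError("nonpositive baseline in one of the channels")
    if coincidence_window is None:
        coincidence_window = float(np.median(np.diff(t)))
    tp = _loss_time(t, peri, loss_frac * base_p)
    tc = _loss_time(t, cyto, loss_frac * base_c)
    if tp is None and tc is None:
        order = "none"
    elif tp is not None and tc is None:
        order = "OM_first"
    elif tp is None:
        order = "IM_first"
    else:
        dt_loss = tc - tp
        if dt_loss > coincidence_window:
            order = "OM_first"
        elif dt_loss < -coincidence_window:
            order = "IM_first"
        else:
            order = "coincident"
    return RuptureCall(t_loss_periplasm=tp, t_loss_cytoplasm=tc, order=order)


def viability_fraction(calls: Iterable[Union[RuptureCall, bool]]) -> tuple[float, int]:
    """Fraction of viable (unruptured) cells and the sample size.

    Accepts :class:`RuptureCall` objects (viable = order ``"none"``) or raw
    lysis flags (``True`` = lysed).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    viable = 0
    for c in calls:
        if isinstance(c, RuptureCall):
            viable += c.order == "none"
        else:
            viable += not bool(c)
    return viable / len(calls), len(calls)
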