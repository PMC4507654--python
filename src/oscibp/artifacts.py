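"""Detection and removal of movement-artifact outlier pulses.

Two complementary rules screen each pulse before envelope fitting:

1. *Neighbour consistency*: for each of the four per-pulse height series
   (peak, bottom, peak-above-preceding-trough, peak-above-following-trough),
   a pulse is compared with the median of its neighbours.  It is flagged when
   the absolute variation relative to that median exceeds
   ``max_abs_variation`` (default 0.4) or when the height falls outside
   +/-50% of the neighbour median.
2. *Pressure rise*: a sudden sustained increase of the low-passed cuff
   pressure during deflation (slope above ``rise_slope_threshold`` for at
   least ``rise_min_duration``) marks an artifact interval; pulses peaking
   inside such an interval are discarded.

Pulses flagged by either rule are removed before the envelope spline is
fitted; corrupted pulses are never repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocess import Pulse

HEIGHT_SERIES = ("peak_value", "bottom_value", "pk2bt_prev", "pk2bt_next")


@dataclass(frozen=True)
class OutlierConfig:
    """Thresholds for the outlier rules.

    Parameters
    ----------
    max_abs_variation : float
        Maximum allowed |height - neighbour median| / |median| (dimensionless).
    neighbour_tolerance : float
        Fractional half-width of the allowed band around the neighbour
        median (0.5 = +/-50%).
    neighbour_halfwidth : int
        Number of neighbour pulses on each side entering the median.
    rise_slope_threshold : float
        Baseline slope (mmHg/s) above which a pressure rise is suspicious;
        nominal deflation runs at -2 to -3 mmHg/s.
    rise_min_duration : float
        Minimum duration (s) the slope must stay above threshold.
    min_height : float
        Heights below this floor (mmHg) are exempt from the relative
        neighbour comparisons — near-zero tail oscillations carry no
        envelope information and their relative variation is noise-dominated.
    normalized : bool
        Apply the 0.4 rule to median-normalized deviations (default); if
        False the rule reads raw mmHg deviations.
    """

    max_abs_variation: float = 0.4
    neighbour_tolerance: float = 0.5
    neighbour_halfwidth: int = 2
    rise_slope_threshold: float = 1.0
    rise_min_duration: float = 0.2
    min_height: float = 0.1
    eps: float = 1e-6
    normalized: bool = True

    def __post_init__(self) -> None:
        if min(
            self.max_abs_variation,
            self.neighbour_tolerance,
            self.rise_slope_threshold,
            self.rise_min_duration,
        ) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.neighbour_halfwidth < 1:
            raise ValueError("neighbour_halfwidth must be >= 1")


def flag_outlier_pulses(
    pulses: Sequence[Pulse], cfg: OutlierConfig = OutlierConfig()
) -> list[tuple[int, str]]:
    """Flag pulses inconsistent with their neighbours.

    Returns a list of ``(index, reason)`` entries; a pulse may appear more
    than once if several series or rules fire.  Reasons are
    ``"abs-variation:<series>"`` and ``"neighbour-range:<series>"``.
    """
    hw = cfg.neighbour_halfwidth
    if len(pulses) < 2 * hw + 1:
        raise ValueError(f"need at least {2 * hw + 1} pulses, got {len(pulses)}")

    flags: list[tuple[int, str]] = []
    for series in HEIGHT_SERIES:
        values = np.array([getattr(p, series) for p in pulses], dtype=float)
        for i in range(values.size):
            lo, hi = max(0, i - hw), min(values.size, i + hw + 1)
            neigh = np.delete(values[lo:hi], i - lo)
            m = float(np.median(neigh))
            h = float(values[i])
            if max(abs(h), abs(m)) < cfg.min_height:
                continue
            dev = abs(h - m) if not cfg.normalized else abs(h - m) / max(abs(m), cfg.eps)
            if dev > cfg.max_abs_variation:
                flags.append((i, f"abs-variation:{series}"))
            band = sorted(((1 - cfg.neighbour_tolerance) * m, (1 + cfg.neighbour_tolerance) * m))
            if not (band[0] <= h <= band[1]):
                flags.append((i, f"neighbour-range:{series}"))
    return sorted(flags)


def flag_pressure_rises(
    baseline: np.ndarray, fs: float, cfg: OutlierConfig = OutlierConfig()
) -> list[tuple[float, float]]:
    """Locate sustained pressure rises during deflation.

    Returns maximal ``(t_start, t_end)`` intervals (seconds) where the slope
    of the low-passed baseline exceeds ``cfg.rise_slope_threshold`` for at
    least ``cfg.rise_min_duration``.  The region up to the global baseline
    maximum (initial inflation, if present) is excluded.
    """
    baseline = np.asarray(baseline, dtype=float)
    slope = np.gradient(baseline) * fs
    start_idx = int(np.argmax(baseline))
    rising = slope > cfg.rise_slope_threshold
    rising[: start_idx + 1] = False

    intervals: list[tuple[float, float]] = []
    min_len = int(cfg.rise_min_duration * fs)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], rising.astype(int), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_len:
            intervals.append((s / fs, e / fs))
    return intervals


def remove_outliers(
    pulses: Sequence[Pulse],
    flags: Iterable[tuple[int, str]],
    rise_intervals: Iterable[tuple[float, float]] = (),
) -> list[Pulse]:
    """Return the clean pulses only (order preserved; input untouched).

    Drops every pulse flagged by the neighbour rules and every pulse whose
    peak time falls inside a pressure-rise interval.  At least four pulses
    must survive (the envelope spline needs four knots).
    """
    flagged = {i for i, _ in flags}
    intervals = list(rise_intervals)
    clean = [
        p
        for i, p in enumerate(pulses)
        if i not in flagged and not any(t0 <= p.t_peak <= t1 for t0, t1 in intervals)
    ]
    if len(clean) < 4:
        raise ValueError(
            f"only {len(clean)} pulses survive outlier removal; envelope fitting needs >= 4"
        )
    return clean
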