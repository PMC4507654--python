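"""Oscillometric waveform envelope: knots, cubic-spline fit, MAP location.

The envelope (OWE) is the curve of oscillation amplitude versus cuff pressure
traced out during deflation.  Each clean pulse contributes one knot at
``(cp_at_peak, amplitude, t_peak)``; a natural interpolating cubic spline is
fitted through the knots over cuff pressure, and the mean arterial pressure
is taken as the cuff pressure at the spline's global maximum (the maximum
amplitude algorithm's central assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .preprocess import Pulse

#: cuff-pressure grid step (mmHg) for the coarse maximum scan
GRID_STEP = 0.1
#: refinement tolerance (mmHg) for the MAP location
MAP_TOL = 0.01


class EnvelopeTruncatedWarning(UserWarning):
    """Envelope maximum sits at a domain endpoint (deflation missed the apex)."""


@dataclass
class OWE:
    """Fitted oscillometric waveform envelope.

    Knot arrays are sorted by ascending cuff pressure; ``t_knots`` retains the
    acquisition times used by the duration/area features.  ``ma`` is the
    maximum spline amplitude and ``map`` the cuff pressure where it occurs.
    """

    cp_knots: np.ndarray
    amp_knots: np.ndarray
    t_knots: np.ndarray
    spline: CubicSpline | None = None
    ma: float = float("nan")
    map: float = float("nan")
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def cp_min(self) -> float:
        return float(self.cp_knots[0])

    @property
    def cp_max(self) -> float:
        return float(self.cp_knots[-1])

    def __call__(self, cp: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted spline; extrapolation is an error."""
        if self.spline is None:
            raise ValueError("envelope spline has not been fitted")
        cp_arr = np.asarray(cp, dtype=float)
        if np.any(cp_arr < self.cp_min - 1e-9) or np.any(cp_arr > self.cp_max + 1e-9):
            raise ValueError(
                f"evaluation outside envelope domain [{self.cp_min:.2f}, {self.cp_max:.2f}] mmHg"
            )
        out = self.spline(cp_arr)
        return float(out) if out.ndim == 0 else out

    def t_of_cp(self, cp: float) -> float:
        """Acquisition time at cuff pressure ``cp`` (linear between knots)."""
        return float(np.interp(cp, self.cp_knots, self.t_knots))


def build_owe(
    clean_pulses: Sequence[Pulse],
    amplitude_mode: str = "pk2bt_mean",
    min_amplitude_frac: float = 0.05,
) -> OWE:
    """Assemble envelope knots from clean pulses (one knot per pulse).

    ``amplitude_mode`` selects the knot height: ``"pk2bt_mean"`` (default)
    averages the two peak-to-trough amplitudes, which is robust to residual
    baseline in the detrended waveform; ``"peak"`` uses the raw peak value.
    Pulses sharing the same cuff pressure are merged by averaging.

    The envelope's start and end are where oscillations become detectable:
    leading and trailing pulses whose amplitude falls below
    ``min_amplitude_frac`` of the maximum are trimmed (0 disables), so
    duration and area features measure the envelope rather than how much
    silent tail the deflation window happened to record.
    """
    if len(clean_pulses) < 4:
        raise ValueError("need at least four clean pulses to build an envelope")
    t = np.array([p.t_peak for p in clean_pulses])
    if np.any(np.diff(t) <= 0):
        raise ValueError("pulse times must be strictly increasing")
    cp = np.array([p.cp_at_peak for p in clean_pulses])
    if amplitude_mode == "pk2bt_mean":
        amp = np.array([p.amplitude for p in clean_pulses])
    elif amplitude_mode == "peak":
        amp = np.array([p.peak_value for p in clean_pulses])
    else:
        raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")

    if min_amplitude_frac > 0:
        # delimit both limbs at a common relative level they both reach: the
        # envelope's start/end points are then comparable across recordings
        # even when deflation stops before the diastolic limb dies out
        thr = max(min_amplitude_frac * amp.max(), amp[0], amp[-1])
        thr = min(thr, 0.9 * amp.max())
        developed = np.flatnonzero(amp >= thr)
        lo, hi = developed[0], developed[-1] + 1
        if hi - lo >= 4:
            # boundary knots interpolated at the exact threshold crossing, so
            # the envelope window is amplitude-relative, not beat-quantized
            head, tail = [], []
            if lo > 0:
                w = (thr - amp[lo - 1]) / (amp[lo] - amp[lo - 1])
                head = [(cp[lo - 1] + w * (cp[lo] - cp[lo - 1]),
                         thr, t[lo - 1] + w * (t[lo] - t[lo - 1]))]
            if hi < amp.size:
                w = (amp[hi - 1] - thr) / (amp[hi - 1] - amp[hi])
                tail = [(cp[hi - 1] + w * (cp[hi] - cp[hi - 1]),
                         thr, t[hi - 1] + w * (t[hi] - t[hi - 1]))]
            pts = head + list(zip(cp[lo:hi], amp[lo:hi], t[lo:hi])) + tail
            cp, amp, t = (np.array(v) for v in zip(*pts))

    order = np.argsort(cp, kind="stable")
    cp, amp, t = cp[order], amp[order], t[order]
    uniq, inverse, counts = np.unique(cp, return_inverse=True, return_counts=True)
    if uniq.size < cp.size:  # flat-pressure duplicates: average heights/times
        amp = np.bincount(inverse, weights=amp) / counts
        t = np.bincount(inverse, weights=t) / counts
        cp = uniq
    if cp.size < 4:
        raise ValueError("fewer than four distinct cuff pressures after merging")
    return OWE(cp_knots=cp, amp_knots=amp, t_knots=t)


def fit_spline(owe: OWE) -> OWE:
    """Fit a natural interpolating cubic spline through the knots and locate
    the envelope maximum.

    Returns the same object with ``spline``, ``ma``, ``map`` and the
    truncation flag filled in.
    """
    if owe.cp_knots.size < 4:
        raise ValueError("spline fitting needs at least four knots")
    if np.any(np.diff(owe.cp_knots) <= 0):
        raise ValueError("coincident cuff-pressure knots after merging")
    owe.spline = CubicSpline(owe.cp_knots, owe.amp_knots, bc_type="natural")
    owe.map, owe.ma = locate_map(owe)
    return owe


def locate_map(owe: OWE) -> tuple[float, float]:
    """Cuff pressure and amplitude of the envelope's global maximum.

    A 0.1 mmHg grid scan is refined by bounded local maximization to
    0.01 mmHg.  Between equal local maxima the one at higher cuff pressure is
    returned.  A maximum at a domain endpoint sets ``owe.truncated`` and
    emits :class:`EnvelopeTruncatedWarning`.
    """
    if owe.spline is None:
        raise ValueError("fit the spline before locating the maximum")
    lo, hi = owe.cp_min, owe.cp_max
    grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    grid[-1] = hi
    vals = owe.spline(grid)
    vmax = vals.max()
    # tie-break: among (near-)equal maxima pick the highest cuff pressure
    best = grid[np.flatnonzero(vals >= vmax - 1e-9 * max(1.0, abs(vmax)))[-1]]

    res = minimize_scalar(
        lambda c: -owe.spline(c),
        bounds=(max(lo, best - GRID_STEP), min(hi, best + GRID_STEP)),
        method="bounded",
        options={"xatol": MAP_TOL / 2},
    )
    map_, ma = float(res.x), float(-res.fun)
    if map_ - lo < 2 * GRID_STEP or hi - map_ < 2 * GRID_STEP:
        owe.truncated = True
        warnings.warn(
            "envelope maximum at domain endpoint; deflation may not span MAP",
            EnvelopeTruncatedWarning,
            stacklevel=2,
        )
    return map_, ma


def fit_envelope(clean_pulses: Sequence[Pulse], amplitude_mode: str = "pk2bt_mean") -> OWE:
    """Convenience: :func:`build_owe` followed by :func:`fit_spline`."""
    return fit_spline(build_owe(clean_pulses, amplitude_mode=amplitude_mode))
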