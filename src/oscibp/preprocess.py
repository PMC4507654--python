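"""Cuff-pressure preprocessing: detrending, baseline extraction, beat segmentation.

The raw cuff-pressure signal recorded during linear deflation is the sum of a
slow deflation ramp and small heart-beat-locked oscillometric pulses.  Two
zero-phase filters separate these components:

* a first-order 0.5-5 Hz Butterworth band-pass (applied forward-backward)
  isolates the pulsatile oscillometric waveform (OMW), and
* a low-pass (0.3 Hz by default) recovers the deflation baseline used as the
  pressure axis of the envelope.

Beats are delimited by consecutive ECG R-peaks; each beat yields one
:class:`Pulse` carrying the four per-pulse height measurements screened by the
outlier detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal


@dataclass
class CuffRecording:
    """A single cuff-deflation recording.

    Parameters
    ----------
    cp : ndarray
        Cuff pressure in mmHg sampled at ``fs``.
    fs : float
        Sampling rate in Hz.
    r_peaks : ndarray of int
        Sample indices of ECG R-peaks (strictly increasing, in bounds).
    reference_sbp, reference_dbp : float, optional
        Reference-scoring systolic/diastolic pressures (mmHg), when known.
    ecg : ndarray, optional
        Toy ECG trace for I/O round-trips; the pipeline only uses ``r_peaks``.
    meta : dict
        Identifiers and artifact provenance (``meta["artifacts"]`` is a list of
        ``{"kind", "t0", "t1", "magnitude"}`` dicts).
    """

    cp: np.ndarray
    fs: float
    r_peaks: np.ndarray
    reference_sbp: Optional[float] = None
    reference_dbp: Optional[float] = None
    ecg: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cp = np.asarray(self.cp, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.cp)):
            raise ValueError("cuff pressure contains non-finite samples")
        if self.r_peaks.size:
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            if self.r_peaks[0] < 0 or self.r_peaks[-1] >= self.cp.size:
                raise ValueError("r_peaks outside signal bounds")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.cp.size / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.cp.size) / self.fs

    def copy(self) -> "CuffRecording":
        return CuffRecording(
            cp=self.cp.copy(),
            fs=self.fs,
            r_peaks=self.r_peaks.copy(),
            reference_sbp=self.reference_sbp,
            reference_dbp=self.reference_dbp,
            ecg=None if self.ecg is None else np.asarray(self.ecg).copy(),
            meta={**self.meta, "artifacts": list(self.meta.get("artifacts", []))},
        )


@dataclass(frozen=True)
class Pulse:
    """One cardiac-cycle oscillometric pulse.

    ``span`` is the half-open sample interval ``[start, end)`` between two
    consecutive R-peaks.  Heights are measured on the detrended OMW:
    ``peak_value``/``bottom_value`` are the extrema inside the span and
    ``pk2bt_prev``/``pk2bt_next`` the peak height above the preceding and
    following troughs.  ``cp_at_peak`` is read from the low-passed deflation
    baseline at the peak instant.
    """

    start: int
    end: int
    peak_value: float
    bottom_value: float
    pk2bt_prev: float
    pk2bt_next: float
    cp_at_peak: float
    t_peak: float
    outlier: bool = False
    outlier_reasons: tuple = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("pulse span must satisfy start < end")
        if self.bottom_value > self.peak_value + 1e-12:
            raise ValueError("bottom_value exceeds peak_value")

    @property
    def amplitude(self) -> float:
        """Mean peak-to-trough amplitude (envelope knot height)."""
        return 0.5 * (self.pk2bt_prev + self.pk2bt_next)

    def flagged(self, reasons: Sequence[str]) -> "Pulse":
        return replace(self, outlier=True, outlier_reasons=tuple(reasons))


def _zero_phase(b: np.ndarray, a: np.ndarray, x: np.ndarray, padlen: int) -> np.ndarray:
    if x.size <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering: {x.size} samples, "
            f"need more than {padlen}"
        )
    return signal.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def detrend_oscillometric(
    cp: np.ndarray, fs: float, band: tuple[float, float] = (0.5, 5.0)
) -> np.ndarray:
    """Band-pass the cuff pressure into the pulsatile oscillometric waveform.

    A first-order Butterworth band-pass (0.5-5 Hz by default) is applied
    forward-backward, giving a zero-phase response with the squared magnitude
    of the one-pass filter.  Edge transients are handled by odd-reflection
    padding spanning three time constants of the low corner.

    Parameters
    ----------
    cp : ndarray
        Raw cuff pressure, mmHg.
    fs : float
        Sampling rate, Hz; must exceed 10 Hz.

    Returns
    -------
    ndarray
        Zero-mean oscillometric waveform, same length as ``cp``.
    """
    cp = np.asarray(cp, dtype=float)
    if fs <= 10:
        raise ValueError("fs must exceed 10 Hz for the 0.5-5 Hz band")
    b, a = signal.butter(1, band, btype="bandpass", fs=fs)
    padlen = int(3 * fs / (2 * np.pi * band[0]))
    return _zero_phase(b, a, cp, padlen)


def lowpass_cuff_baseline(
    cp: np.ndarray, fs: float, cutoff: float = 0.3, order: int = 2
) -> np.ndarray:
    """Zero-phase low-pass estimate of the deflation trend.

    The default 0.3 Hz cutoff keeps the ramp and slow pressure excursions
    while attenuating heart-rate oscillations by well over an order of
    magnitude.
    """
    cp = np.asarray(cp, dtype=float)
    if fs <= 4 * cutoff:
        raise ValueError("fs too low for the requested cutoff")
    b, a = signal.butter(order, cutoff, btype="lowpass", fs=fs)
    padlen = int(3 * fs / (2 * np.pi * cutoff))
    return _zero_phase(b, a, cp, padlen)


def bandpass_gain(f: float, band: tuple[float, float] = (0.5, 5.0)) -> float:
    """Analytic forward-backward gain of the first-order band-pass at ``f`` Hz.

    The one-pass first-order Butterworth band-pass has
    ``|H(f)|^2 = 1 / (1 + Q^2 (f/f0 - f0/f)^2)`` with centre ``f0`` the
    geometric mean of the corners and ``Q = f0 / bandwidth``; the
    forward-backward cascade applies the squared magnitude.
    """
    f0 = float(np.sqrt(band[0] * band[1]))
    q = f0 / (band[1] - band[0])
    return 1.0 / (1.0 + q**2 * (f / f0 - f0 / f) ** 2)


def segment_pulses(
    omw: np.ndarray,
    rec: CuffRecording,
    baseline: Optional[np.ndarray] = None,
    cp_source: str = "baseline",
) -> list[Pulse]:
    """Split the OMW into per-beat pulses using consecutive R-peak pairs.

    Parameters
    ----------
    omw : ndarray
        Detrended oscillometric waveform from :func:`detrend_oscillometric`.
    rec : CuffRecording
        Source recording supplying ``r_peaks``, ``fs`` and the raw pressure.
    baseline : ndarray, optional
        Precomputed deflation baseline; computed on demand otherwise.
    cp_source : {"baseline", "raw"}
        Whether ``cp_at_peak`` reads the low-passed baseline (default) or the
        raw cuff pressure.

    Returns
    -------
    list of Pulse
        One pulse per R-peak pair, in time order; spans tile
        ``[r_peaks[0], r_peaks[-1])`` exactly.
    """
    omw = np.asarray(omw, dtype=float)
    if omw.shape != rec.cp.shape:
        raise ValueError("omw and recording length mismatch")
    if rec.r_peaks.size < 2:
        raise ValueError("need at least two R-peaks to delimit a pulse")
    if cp_source not in ("baseline", "raw"):
        raise ValueError(f"unknown cp_source {cp_source!r}")
    if cp_source == "baseline":
        if baseline is None:
            baseline = lowpass_cuff_baseline(rec.cp, rec.fs)
        pressure = np.asarray(baseline, dtype=float)
    else:
        pressure = rec.cp

    pulses: list[Pulse] = []
    for start, end in zip(rec.r_peaks[:-1], rec.r_peaks[1:]):
        seg = omw[start:end]
        peak_off = int(np.argmax(seg))
        peak = float(seg[peak_off])
        bottom = float(seg.min())
        trough_prev = float(seg[: peak_off + 1].min())
        trough_next = float(seg[peak_off:].min())
        idx = start + peak_off
        pulses.append(
            Pulse(
                start=int(start),
                end=int(end),
                peak_value=peak,
                bottom_value=bottom,
                pk2bt_prev=peak - trough_prev,
                pk2bt_next=peak - trough_next,
                cp_at_peak=float(pressure[idx]),
                t_peak=idx / rec.fs,
            )
        )
    return pulses


def detect_r_peaks(ecg: np.ndarray, fs: float, min_rr: float = 0.4) -> np.ndarray:
    """Naive threshold R-peak detector (convenience only; annotations are the
    expected input).

    Finds local maxima above half the signal's 99th percentile separated by at
    least ``min_rr`` seconds.
    """
    ecg = np.asarray(ecg, dtype=float)
    thresh = 0.5 * np.percentile(ecg, 99)
    peaks, _ = signal.find_peaks(ecg, height=thresh, distance=int(min_rr * fs))
    return peaks.astype(int)
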