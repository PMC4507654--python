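"""Seedable simulator of cuff-deflation recordings with known ground truth.

Each recording emulates the standard oscillometric acquisition protocol: the
cuff pressure deflates linearly from about 180 mmHg to about 40 mmHg at
2-3 mmHg/s while heart-beat-locked oscillometric pulses ride on the ramp.
Pulse amplitudes follow a two-sided generalized-Gaussian envelope over cuff
pressure that peaks at the mean arterial pressure (MAP), with independent
widths on the high- (systolic) and low-pressure (diastolic) sides.

The generator draws SBP/DBP from configured ranges, sets
``MAP = DBP + (SBP - DBP)/3`` (the standard clinical estimate), draws the
characteristic ratios (SBPR, DBPR) from a linear link on a latent asymmetry
variable plus Gaussian noise, and then *solves* the envelope widths so that
the envelope evaluated at the true SBP and DBP equals ``SBPR * MA`` and
``DBPR * MA`` exactly.  The envelope therefore encodes the drawn ratios, and
area/shape features extracted downstream carry recoverable regression signal.

Movement artifacts of four signal-level archetypes (pressure-bump,
amplitude-spike, burst-oscillation, cuff-release) can be injected; all are
scaled so that magnitude 0 is a no-op, and samples outside the declared
interval are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .preprocess import CuffRecording

ARTIFACT_KINDS = ("pressure-bump", "amplitude-spike", "burst-oscillation", "cuff-release")

#: Default artifact interval lengths in seconds.  Arm movements last seconds;
#: the 3 s pressure-bump default keeps its energy below the 0.3 Hz baseline
#: low-pass so the sudden-pressure-rise detector can see it.
DEFAULT_ARTIFACT_DURATION = {
    "pressure-bump": 3.0,
    "amplitude-spike": None,  # one cardiac cycle
    "burst-oscillation": 1.0,
    "cuff-release": 2.0,
}


class ConfigurationError(ValueError):
    """Raised when a simulator configuration is infeasible."""


def envelope_amplitude(
    cp: np.ndarray | float,
    ma: float,
    map_: float,
    width_low: float,
    width_high: float,
    shape: float = 2.0,
) -> np.ndarray | float:
    """Two-sided generalized-Gaussian oscillation envelope.

    ``amplitude(cp) = ma * exp(-|(cp - map_)/w|^shape)`` with ``w =
    width_high`` above MAP (systolic side) and ``width_low`` below it.
    """
    cp = np.asarray(cp, dtype=float)
    w = np.where(cp >= map_, width_high, width_low)
    out = ma * np.exp(-np.abs((cp - map_) / w) ** shape)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RatioLink:
    """Linear link tying (SBPR, DBPR) to the latent envelope asymmetry.

    ``sbpr = sbpr_intercept + sbpr_slope * a + noise`` (likewise for DBPR)
    with ``a`` the latent asymmetry draw and independent Gaussian noise of
    standard deviation ``noise_sd`` on each ratio.
    """

    sbpr_intercept: float = 0.55
    sbpr_slope: float = 0.12
    dbpr_intercept: float = 0.72
    dbpr_slope: float = -0.08
    noise_sd: float = 0.02

    def draw(self, a: float, rng: np.random.Generator) -> tuple[float, float]:
        sbpr = self.sbpr_intercept + self.sbpr_slope * a
        dbpr = self.dbpr_intercept + self.dbpr_slope * a
        if self.noise_sd > 0:
            sbpr += rng.normal(0.0, self.noise_sd)
            dbpr += rng.normal(0.0, self.noise_sd)
        return float(np.clip(sbpr, 0.30, 0.95)), float(np.clip(dbpr, 0.40, 0.95))


@dataclass(frozen=True)
class SynthConfig:
    """Simulator configuration; defaults mirror the acquisition protocol."""

    n_recordings: int = 10
    sbp_range: tuple[float, float] = (70.0, 133.0)
    dbp_range: tuple[float, float] = (42.0, 88.0)
    #: population mean/SD of the pressure draws (truncated normals over the
    #: ranges above, matching the reported cohort summary)
    sbp_mean_sd: tuple[float, float] = (107.0, 13.0)
    dbp_mean_sd: tuple[float, float] = (62.0, 9.0)
    hr_range: tuple[float, float] = (60.0, 95.0)
    deflation_rate_range: tuple[float, float] = (2.0, 3.0)
    cp_start: float = 180.0
    cp_end: float = 40.0
    fs: float = 1000.0
    ma_range: tuple[float, float] = (1.5, 3.5)
    envelope_shape: float = 2.0
    asymmetry_range: tuple[float, float] = (-1.0, 1.0)
    ratio_link: RatioLink = RatioLink()
    sensor_noise_sd: float = 0.05
    pulse_pressure_range: tuple[float, float] = (20.0, 70.0)
    artifact_spec: tuple = ()
    render_ecg: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recordings < 1:
            raise ConfigurationError("n_recordings must be >= 1")
        if self.cp_start <= self.sbp_range[1]:
            raise ConfigurationError("cp_start must exceed the SBP range maximum")
        if self.cp_end >= self.dbp_range[0]:
            raise ConfigurationError("cp_end must lie below the DBP range minimum")
        if self.fs <= 2.0 * self.hr_range[1] / 60.0:
            raise ConfigurationError("fs must exceed twice the maximum heart rate")
        for lo, hi in (
            self.sbp_range,
            self.dbp_range,
            self.hr_range,
            self.deflation_rate_range,
            self.ma_range,
            self.pulse_pressure_range,
        ):
            if lo > hi:
                raise ConfigurationError("range lower bound exceeds upper bound")
        for kind, _, _ in self.artifact_spec:
            if kind not in ARTIFACT_KINDS:
                raise ConfigurationError(f"unknown artifact kind {kind!r}")


@dataclass
class GroundTruth:
    """True blood-pressure values and envelope parameters for one recording."""

    sbp: float
    dbp: float
    map: float
    sbpr: float
    dbpr: float
    ma: float
    width_low: float
    width_high: float
    shape: float
    hr: float
    deflation_rate: float
    pulse_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.dbp < self.map < self.sbp):
            raise ValueError("ground truth must satisfy dbp < map < sbp")
        if not (0.0 < self.sbpr <= 1.0 and 0.0 < self.dbpr <= 1.0):
            raise ValueError("characteristic ratios must lie in (0, 1]")

    def envelope(self, cp: np.ndarray | float) -> np.ndarray | float:
        """Ground-truth envelope amplitude at cuff pressure ``cp``."""
        return envelope_amplitude(
            cp, self.ma, self.map, self.width_low, self.width_high, self.shape
        )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(rng.uniform(lo, hi))  # pathological bounds: fall back flat


def _draw_pressures(cfg: SynthConfig, rng: np.random.Generator) -> tuple[float, float]:
    sbp = _truncated_normal(rng, *cfg.sbp_mean_sd, *cfg.sbp_range)
    lo = max(cfg.dbp_range[0], sbp - cfg.pulse_pressure_range[1])
    hi = min(cfg.dbp_range[1], sbp - cfg.pulse_pressure_range[0])
    if lo > hi:
        raise ConfigurationError(
            "dbp_range and pulse_pressure_range leave no feasible DBP draw"
        )
    dbp = _truncated_normal(rng, *cfg.dbp_mean_sd, lo, hi)
    return float(sbp), float(dbp)


def generate_recording(
    cfg: SynthConfig, draw_index: int = 0
) -> tuple[CuffRecording, GroundTruth]:
    """Simulate one cuff-deflation recording.

    Deterministic given ``(cfg.seed, draw_index)``.  Returns the recording
    (with reference SBP/DBP filled in) and its ground truth.
    """
    rng = np.random.default_rng([cfg.seed, draw_index])

    sbp, dbp = _draw_pressures(cfg, rng)
    map_ = dbp + (sbp - dbp) / 3.0
    a = rng.uniform(*cfg.asymmetry_range)
    sbpr, dbpr = cfg.ratio_link.draw(a, rng)
    ma = rng.uniform(*cfg.ma_range)
    hr = rng.uniform(*cfg.hr_range)
    rate = rng.uniform(*cfg.deflation_rate_range)

    p = cfg.envelope_shape
    width_high = (sbp - map_) / (-np.log(sbpr)) ** (1.0 / p)
    width_low = (map_ - dbp) / (-np.log(dbpr)) ** (1.0 / p)

    duration = (cfg.cp_start - cfg.cp_end) / rate
    if duration <= 2.0 * 60.0 / hr:
        raise ConfigurationError("deflation window too short to span SBP to DBP")
    n = int(round(duration * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs
    cp = cfg.cp_start - rate * t

    rr = 60.0 / hr
    r_peaks = np.round(np.arange(0.0, t[-1], rr) * cfg.fs).astype(int)
    r_peaks = r_peaks[r_peaks < n]

    osc = np.zeros(n)
    apex_times = []
    for s, e in zip(r_peaks[:-1], r_peaks[1:]):
        apex = (s + e) // 2
        amp = envelope_amplitude(cp[apex], ma, map_, width_low, width_high, p)
        phase = np.arange(e - s) / (e - s)
        # raised-cosine beat, mean-removed so the deflation baseline is unbiased
        osc[s:e] = -0.5 * amp * np.cos(2.0 * np.pi * phase)
        apex_times.append(apex / cfg.fs)
    cp = cp + osc
    if cfg.sensor_noise_sd > 0:
        cp = cp + rng.normal(0.0, cfg.sensor_noise_sd, n)

    ecg = None
    if cfg.render_ecg:
        ecg = np.zeros(n)
        half = max(1, int(0.01 * cfg.fs))
        spike = np.exp(-0.5 * (np.arange(-half, half + 1) / (half / 2.5)) ** 2)
        for idx in r_peaks:
            lo, hi = max(0, idx - half), min(n, idx + half + 1)
            ecg[lo:hi] = np.maximum(ecg[lo:hi], spike[lo - (idx - half) : hi - (idx - half)])

    rec = CuffRecording(
        cp=cp,
        fs=cfg.fs,
        r_peaks=r_peaks,
        reference_sbp=sbp,
        reference_dbp=dbp,
        ecg=ecg,
        meta={
            "id": f"rec{draw_index:04d}",
            "subject": f"subj{draw_index // 4:03d}",
            "artifacts": [],
        },
    )
    gt = GroundTruth(
        sbp=sbp,
        dbp=dbp,
        map=map_,
        sbpr=sbpr,
        dbpr=dbpr,
        ma=ma,
        width_low=width_low,
        width_high=width_high,
        shape=p,
        hr=hr,
        deflation_rate=rate,
        pulse_times=np.asarray(apex_times),
    )

    for k, (kind, at, magnitude) in enumerate(cfg.artifact_spec):
        rec = inject_artifact(rec, kind, at, magnitude, seed=1000 * draw_index + k)
    gt.artifact_intervals = list(rec.meta.get("artifacts", []))
    return rec, gt


def generate_cohort(cfg: SynthConfig) -> list[tuple[CuffRecording, GroundTruth]]:
    """Simulate ``cfg.n_recordings`` recordings (four per synthetic subject)."""
    return [generate_recording(cfg, i) for i in range(cfg.n_recordings)]


def _interval_indices(
    rec: CuffRecording, at: float, dur: float
) -> tuple[int, int, float, float]:
    n = rec.cp.size
    i0 = int(round(at * rec.fs))
    i1 = min(n, i0 + int(round(dur * rec.fs)))
    if not (0 <= i0 < n):
        raise ValueError("artifact time outside recording")
    return i0, i1, i0 / rec.fs, i1 / rec.fs


def inject_artifact(
    rec: CuffRecording,
    kind: str,
    at: float,
    magnitude: float,
    seed: int = 0,
    duration: Optional[float] = None,
) -> CuffRecording:
    """Return a copy of ``rec`` with one movement artifact injected.

    Archetypes (all additive in ``magnitude``, so ``magnitude == 0`` is a
    strict no-op; samples outside the artifact interval are bit-identical):

    ``pressure-bump``
        Smooth transient cuff-pressure rise of ``magnitude`` mmHg.
    ``amplitude-spike``
        The oscillometric pulse of the beat containing ``at`` is multiplied
        by ``1 + magnitude`` (deviation from the beat's linear ramp chord).
    ``burst-oscillation``
        Band-limited (1-8 Hz) noise of RMS ``magnitude`` mmHg, Tukey-windowed.
    ``cuff-release``
        Transient pressure collapse of depth ``magnitude`` mmHg.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    out = rec.copy()
    if magnitude == 0:
        return out
    dur = duration if duration is not None else DEFAULT_ARTIFACT_DURATION[kind]

    if kind == "amplitude-spike":
        i0 = int(round(at * rec.fs))
        k = int(np.searchsorted(rec.r_peaks, i0, side="right")) - 1
        if k < 0 or k >= rec.r_peaks.size - 1:
            raise ValueError("amplitude-spike time not inside a cardiac cycle")
        s, e = int(rec.r_peaks[k]), int(rec.r_peaks[k + 1])
        chord = np.linspace(out.cp[s], out.cp[e - 1], e - s)
        out.cp[s:e] += magnitude * (out.cp[s:e] - chord)
        t0, t1 = s / rec.fs, e / rec.fs
    else:
        i0, i1, t0, t1 = _interval_indices(rec, at, dur)
        m = i1 - i0
        if kind == "pressure-bump":
            phase = np.arange(m) / m
            out.cp[i0:i1] += magnitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        elif kind == "burst-oscillation":
            rng = np.random.default_rng(seed)
            noise = rng.normal(0.0, 1.0, m)
            b, a = _signal.butter(2, [1.0, 8.0], btype="bandpass", fs=rec.fs)
            noise = _signal.filtfilt(b, a, noise, padtype="odd", padlen=min(m - 1, 3 * int(rec.fs)))
            noise *= _signal.windows.tukey(m, alpha=0.5)
            rms = np.sqrt(np.mean(noise**2))
            if rms > 0:
                out.cp[i0:i1] += magnitude * noise / rms
        elif kind == "cuff-release":
            out.cp[i0:i1] -= magnitude * _signal.windows.tukey(m, alpha=0.25)

    out.meta.setdefault("artifacts", []).append(
        {"kind": kind, "t0": float(t0), "t1": float(t1), "magnitude": float(magnitude)}
    )
    return out
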