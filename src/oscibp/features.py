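"""The ten envelope features and the reference characteristic ratios.

Feature classes: amplitude (Amp1 = MA), duration (Dur1 = time from envelope
onset to the maximum, Dur2 = total envelope duration), area (Area1 = area
under the envelope, split at the maximum into Area2 before and Area3 after),
shape ratios (Ratio1 = Dur1/Dur2, Ratio2 = Area2/Area1, Ratio3 =
Area3/Area1), and the MAP estimate of the maximum amplitude algorithm.

Durations and areas are measured on the time axis (deflation is near-linear,
so the pressure axis would be proportional; a pressure-domain mode is
available).  Areas integrate the piecewise-linear knot envelope by the
trapezoid rule, split exactly at the interpolated time of the maximum, so
``area1 == area2 + area3`` holds by construction.

The reference characteristic ratios divide the spline amplitude at the
reference-scoring SBP and DBP by the maximum amplitude:
``SBPR = SBPA / MA`` and ``DBPR = DBPA / MA``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .envelope import OWE

FEATURE_NAMES = (
    "amp1",
    "dur1",
    "dur2",
    "area1",
    "area2",
    "area3",
    "ratio1",
    "ratio2",
    "ratio3",
    "map",
)


@dataclass(frozen=True)
class FeatureVector:
    """The ten envelope features (mmHg, s, mmHg*s and dimensionless)."""

    amp1: float
    dur1: float
    dur2: float
    area1: float
    area2: float
    area3: float
    ratio1: float
    ratio2: float
    ratio3: float
    map: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


@dataclass(frozen=True)
class RatioPair:
    """Systolic and diastolic characteristic ratios (dimensionless)."""

    sbpr: float
    dbpr: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sbpr <= 1.0 and 0.0 < self.dbpr <= 1.0):
            raise ValueError("characteristic ratios must lie in (0, 1]")


def _split_areas(ts: np.ndarray, amps: np.ndarray, t_split: float) -> tuple[float, float]:
    """Trapezoid areas of the piecewise-linear envelope before/after ``t_split``."""
    a_split = float(np.interp(t_split, ts, amps))
    left_mask = ts < t_split
    t_left = np.concatenate([ts[left_mask], [t_split]])
    a_left = np.concatenate([amps[left_mask], [a_split]])
    t_right = np.concatenate([[t_split], ts[~left_mask]])
    a_right = np.concatenate([[a_split], amps[~left_mask]])
    return float(np.trapezoid(a_left, t_left)), float(np.trapezoid(a_right, t_right))


def extract_features(owe: OWE, domain: str = "time") -> FeatureVector:
    """Compute the ten features from a fitted envelope.

    ``domain`` selects the integration/duration axis: ``"time"`` (default)
    uses the per-knot acquisition times; ``"pressure"`` uses cuff pressure
    (descending order of deflation), in which case durations are in mmHg and
    areas in mmHg^2.
    """
    if owe.spline is None:
        raise ValueError("envelope must be fitted before feature extraction")
    if domain == "time":
        order = np.argsort(owe.t_knots, kind="stable")
        xs = owe.t_knots[order]
        amps = owe.amp_knots[order]
        x_map = owe.t_of_cp(owe.map)
    elif domain == "pressure":
        # deflation runs high -> low pressure; negate so the axis increases
        xs = -owe.cp_knots[::-1]
        amps = owe.amp_knots[::-1]
        x_map = -owe.map
    else:
        raise ValueError(f"unknown domain {domain!r}")

    dur2 = float(xs[-1] - xs[0])
    if dur2 <= 0:
        raise ValueError("degenerate envelope: zero duration")
    dur1 = float(np.clip(x_map - xs[0], 0.0, dur2))
    area2, area3 = _split_areas(xs, amps, float(np.clip(x_map, xs[0], xs[-1])))
    area1 = area2 + area3
    if area1 <= 0:
        raise ValueError("degenerate envelope: zero area")
    return FeatureVector(
        amp1=float(owe.ma),
        dur1=dur1,
        dur2=dur2,
        area1=area1,
        area2=area2,
        area3=area3,
        ratio1=dur1 / dur2,
        ratio2=area2 / area1,
        ratio3=area3 / area1,
        map=float(owe.map),
    )


def reference_ratios(owe: OWE, rs_sbp: float, rs_dbp: float) -> RatioPair:
    """Characteristic ratios implied by the reference SBP/DBP on this envelope.

    Requires ``rs_dbp < MAP < rs_sbp`` with both pressures inside the spline
    domain; returns ``(spline(rs_sbp)/MA, spline(rs_dbp)/MA)``.
    """
    if owe.spline is None:
        raise ValueError("envelope must be fitted")
    if not (rs_dbp < owe.map <= rs_sbp + 1e-9):
        raise ValueError(
            f"reference ordering violated: need DBP < MAP < SBP, got "
            f"{rs_dbp:.1f}, {owe.map:.1f}, {rs_sbp:.1f} mmHg"
        )
    sbpa = owe(rs_sbp)  # raises outside the domain
    dbpa = owe(rs_dbp)
    return RatioPair(
        sbpr=float(np.clip(sbpa / owe.ma, 1e-9, 1.0)),
        dbpr=float(np.clip(dbpa / owe.ma, 1e-9, 1.0)),
    )


def feature_matrix(
    vectors: list[FeatureVector] | list[Mapping[str, float]],
    names: tuple[str, ...],
) -> np.ndarray:
    """Stack selected features into an ``(n, len(names))`` design matrix."""
    rows = []
    for v in vectors:
        if isinstance(v, FeatureVector):
            rows.append([getattr(v, n) for n in names])
        else:
            rows.append([v[n] for n in names])
    return np.asarray(rows, dtype=float)
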