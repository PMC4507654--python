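"""Agreement statistics and device-grading protocols.

Estimates are scored against reference pressures with Bland-Altman
statistics (mean and n-1 SD of paired differences, sign convention
``reference - estimate``), the BHS cumulative-percentage grades (fractions
of absolute differences within 5/10/15 mmHg) and the AAMI criterion (mean
difference within +/-5 mmHg and SD under a mean-dependent tabulated limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

#: BHS grade thresholds: minimum cumulative percentages within 5/10/15 mmHg
BHS_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

#: AAMI upper SD limit (mmHg) per absolute mean difference in 0.5 mmHg steps
AAMI_SD_LIMITS = {
    0.0: 6.95,
    0.5: 6.93,
    1.0: 6.87,
    1.5: 6.78,
    2.0: 6.65,
    2.5: 6.47,
    3.0: 6.25,
    3.5: 5.97,
    4.0: 5.64,
    4.5: 5.24,
    5.0: 4.81,
}


@dataclass(frozen=True)
class EvalReport:
    """Agreement summary for one estimator/pressure pair."""

    n: int
    mean_diff: float
    sd_diff: float
    pct5: float
    pct10: float
    pct15: float
    bhs_grade: str
    aami_pass: bool
    aami_sd_limit: float

    def as_dict(self) -> dict:
        return asdict(self)


def _diffs(est: Sequence[float], ref: Sequence[float]) -> np.ndarray:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimate and reference lists must have equal length")
    return ref - est


def bland_altman(est: Sequence[float], ref: Sequence[float]) -> tuple[float, float]:
    """Mean and n-1 sample SD of the paired differences ``ref - est``."""
    d = _diffs(est, ref)
    if d.size < 2:
        raise ValueError("need at least two paired readings")
    return float(d.mean()), float(d.std(ddof=1))


def cumulative_percentages(
    est: Sequence[float], ref: Sequence[float]
) -> tuple[float, float, float]:
    """Percentages of absolute differences within 5, 10 and 15 mmHg
    (boundaries inclusive)."""
    d = np.abs(_diffs(est, ref))
    if d.size < 1:
        raise ValueError("need at least one paired reading")
    return tuple(float(100.0 * np.mean(d <= thr)) for thr in (5.0, 10.0, 15.0))


def bhs_grade(pct5: float, pct10: float, pct15: float) -> str:
    """BHS grade: best of A/B/C whose three thresholds are all met, else D."""
    pcts = (pct5, pct10, pct15)
    if any(not (0.0 <= p <= 100.0) for p in pcts):
        raise ValueError("percentages must lie in [0, 100]")
    for grade, mins in BHS_TABLE.items():
        if all(p >= m for p, m in zip(pcts, mins)):
            return grade
    return "D"


def aami_check(mean_diff: float, sd_diff: float) -> tuple[bool, float]:
    """AAMI verdict: |mean| within 5 mmHg and SD under the tabulated limit.

    The tabulated limit at the absolute mean difference rounded *up* to the
    next 0.5 mmHg step is used (conservative; the table states no
    interpolation rule).  Returns ``(pass, sd_limit)``; an out-of-range mean
    fails with ``sd_limit = nan``.
    """
    if not (math.isfinite(mean_diff) and math.isfinite(sd_diff)):
        raise ValueError("mean and SD must be finite")
    m = abs(mean_diff)
    if m > 5.0:
        return False, float("nan")
    step = math.ceil(round(m / 0.5, 9)) * 0.5
    limit = AAMI_SD_LIMITS[round(step, 1)]
    return sd_diff <= limit, limit


def evaluate(est: Sequence[float], ref: Sequence[float]) -> EvalReport:
    """Full agreement report for paired estimate/reference readings."""
    mean_diff, sd_diff = bland_altman(est, ref)
    pct5, pct10, pct15 = cumulative_percentages(est, ref)
    passed, limit = aami_check(mean_diff, sd_diff)
    return EvalReport(
        n=len(est),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        pct5=pct5,
        pct10=pct10,
        pct15=pct15,
        bhs_grade=bhs_grade(pct5, pct10, pct15),
        aami_pass=passed,
        aami_sd_limit=limit,
    )
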