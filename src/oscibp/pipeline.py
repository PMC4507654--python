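"""End-to-end orchestration: recording -> envelope -> features -> estimates.

:func:`process_recording` runs the signal chain for one recording
(detrending, baseline extraction, beat segmentation, optional outlier
removal, envelope fitting, feature extraction, reference-ratio computation)
and returns a :class:`ProcessedRecording`.  :func:`run_pipeline` drives a
whole cohort through a chosen estimator under cross-validation and writes
machine-readable reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .artifacts import OutlierConfig, flag_outlier_pulses, flag_pressure_rises, remove_outliers
from .envelope import OWE, fit_envelope
from .evaluation import EvalReport, evaluate
from .features import FEATURE_NAMES, FeatureVector, RatioPair, extract_features, feature_matrix, reference_ratios
from .models import (
    BPEstimate,
    clip_ratio,
    estimate_bp_from_ratios,
    make_estimator,
)
from .preprocess import CuffRecording, detrend_oscillometric, lowpass_cuff_baseline, segment_pulses

logger = logging.getLogger(__name__)


@dataclass
class ProcessedRecording:
    """One recording after the signal chain, ready for model fitting."""

    rec_id: str
    subject: str
    owe: OWE
    features: FeatureVector
    ref_sbp: Optional[float] = None
    ref_dbp: Optional[float] = None
    ref_ratios: Optional[RatioPair] = None
    n_pulses: int = 0
    n_removed: int = 0
    flags: list = field(default_factory=list)
    rise_intervals: list = field(default_factory=list)


def process_recording(
    rec: CuffRecording,
    remove_artifacts: bool = True,
    outlier_cfg: OutlierConfig = OutlierConfig(),
    amplitude_mode: str = "pk2bt_mean",
    cp_source: str = "baseline",
) -> ProcessedRecording:
    """Run the per-recording signal chain.

    With ``remove_artifacts`` off, all pulses enter the envelope fit — the
    "before outlier removal" condition of the artifact-robustness experiment.
    Reference ratios are computed whenever the recording carries reference
    SBP/DBP inside the envelope domain.
    """
    omw = detrend_oscillometric(rec.cp, rec.fs)
    baseline = lowpass_cuff_baseline(rec.cp, rec.fs)
    pulses = segment_pulses(omw, rec, baseline=baseline, cp_source=cp_source)

    flags: list = []
    rises: list = []
    clean = pulses
    if remove_artifacts:
        flags = flag_outlier_pulses(pulses, outlier_cfg)
        rises = flag_pressure_rises(baseline, rec.fs, outlier_cfg)
        clean = remove_outliers(pulses, flags, rises)

    owe = fit_envelope(clean, amplitude_mode=amplitude_mode)
    feats = extract_features(owe)

    ref_ratios = None
    if rec.reference_sbp is not None and rec.reference_dbp is not None:
        try:
            ref_ratios = reference_ratios(owe, rec.reference_sbp, rec.reference_dbp)
        except ValueError as exc:
            logger.warning("reference ratios unavailable for %s: %s", rec.meta.get("id"), exc)

    return ProcessedRecording(
        rec_id=str(rec.meta.get("id", "rec")),
        subject=str(rec.meta.get("subject", rec.meta.get("id", "rec"))),
        owe=owe,
        features=feats,
        ref_sbp=rec.reference_sbp,
        ref_dbp=rec.reference_dbp,
        ref_ratios=ref_ratios,
        n_pulses=len(pulses),
        n_removed=len(pulses) - len(clean),
        flags=list(flags),
        rise_intervals=list(rises),
    )


def process_cohort(
    recordings: Sequence[CuffRecording],
    remove_artifacts: bool = True,
    outlier_cfg: OutlierConfig = OutlierConfig(),
) -> tuple[list[ProcessedRecording], list[tuple[str, str]]]:
    """Process a cohort; failures are logged and returned, not raised."""
    processed: list[ProcessedRecording] = []
    failures: list[tuple[str, str]] = []
    for rec in recordings:
        rid = str(rec.meta.get("id", f"rec{len(processed)}"))
        try:
            processed.append(
                process_recording(rec, remove_artifacts=remove_artifacts, outlier_cfg=outlier_cfg)
            )
        except Exception as exc:  # noqa: BLE001 - per-recording isolation
            logger.warning("recording %s failed: %s", rid, exc)
            failures.append((rid, str(exc)))
    return processed, failures


def predict_cohort(
    train: Sequence[ProcessedRecording],
    test: Sequence[ProcessedRecording],
    estimator_kind: str,
    feature_names: Sequence[str],
    **estimator_kwargs,
) -> list[tuple[ProcessedRecording, Optional[BPEstimate], Optional[str]]]:
    """Fit ratio models on ``train`` and invert predictions on ``test``.

    Separate models are fitted for SBPR and DBPR.  Returns one
    ``(record, estimate, error)`` triple per test record; estimation
    failures (e.g. truncated envelopes) yield ``estimate=None`` with the
    reason in ``error``.
    """
    usable = [r for r in train if r.ref_ratios is not None]
    if not usable:
        raise ValueError("no training recordings with reference ratios")
    Xtr = feature_matrix([r.features for r in usable], tuple(feature_names))
    y_s = np.array([r.ref_ratios.sbpr for r in usable])
    y_d = np.array([r.ref_ratios.dbpr for r in usable])
    model_s = make_estimator(estimator_kind, **estimator_kwargs).fit(Xtr, y_s)
    model_d = make_estimator(estimator_kind, **estimator_kwargs).fit(Xtr, y_d)

    out = []
    Xte = feature_matrix([r.features for r in test], tuple(feature_names))
    pred_s = model_s.predict(Xte)
    pred_d = model_d.predict(Xte)
    for rec, ps, pd_ in zip(test, pred_s, pred_d):
        try:
            ratios = RatioPair(sbpr=clip_ratio(float(ps)), dbpr=clip_ratio(float(pd_)))
            est = estimate_bp_from_ratios(rec.owe, ratios, method=estimator_kind)
            out.append((rec, est, None))
        except ValueError as exc:
            logger.warning("estimation failed for %s: %s", rec.rec_id, exc)
            out.append((rec, None, str(exc)))
    return out


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`."""

    estimator: str = "mlr"
    feature_names: tuple[str, ...] = ("ratio2", "area3")
    remove_artifacts: bool = True
    k_folds: int = 4
    grouping: str = "by_subject"
    seed: int = 0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.estimator not in ("maa", "mlr", "nusvr"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        unknown = set(self.feature_names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")


def run_pipeline(
    recordings: Sequence[CuffRecording], cfg: RunConfig
) -> dict:
    """Process a cohort and score an estimator under k-fold cross-validation.

    Returns a JSON-serializable report with per-pressure
    :class:`~oscibp.evaluation.EvalReport` sections and per-recording
    estimates; writes ``report.json`` and ``estimates.csv`` when
    ``cfg.out_dir`` is set.
    """
    from .selection import CVPlan, kfold_split  # local import avoids a cycle

    processed, failures = process_cohort(recordings, remove_artifacts=cfg.remove_artifacts)
    scored = [r for r in processed if r.ref_ratios is not None]
    if len(scored) < cfg.k_folds:
        raise ValueError("too few scorable recordings for the requested folds")

    plan = kfold_split(scored, CVPlan(k=cfg.k_folds, grouping=cfg.grouping, seed=cfg.seed))
    rows = []
    est_errors: list[tuple[str, str]] = []
    for fold in range(plan.k):
        train = [r for r in scored if plan.assignments[r.rec_id] != fold]
        test = [r for r in scored if plan.assignments[r.rec_id] == fold]
        for rec, est, err in predict_cohort(train, test, cfg.estimator, cfg.feature_names):
            if est is None:
                est_errors.append((rec.rec_id, err))
                continue
            rows.append(
                {
                    "recording_id": rec.rec_id,
                    "subject": rec.subject,
                    "fold": fold,
                    "sbp_est": est.sbp,
                    "dbp_est": est.dbp,
                    "map_est": est.map,
                    "sbp_ref": rec.ref_sbp,
                    "dbp_ref": rec.ref_dbp,
                }
            )
    estimates = pd.DataFrame(rows).sort_values("recording_id").reset_index(drop=True)
    report = {
        "config": {
            "estimator": cfg.estimator,
            "features": list(cfg.feature_names),
            "remove_artifacts": cfg.remove_artifacts,
            "k_folds": cfg.k_folds,
            "grouping": cfg.grouping,
            "seed": cfg.seed,
        },
        "version": __version__,
        "n_recordings": len(recordings),
        "n_processed": len(processed),
        "n_scored": len(estimates),
        "processing_failures": failures,
        "estimation_failures": est_errors,
        "sbp": evaluate(estimates["sbp_est"], estimates["sbp_ref"]).as_dict(),
        "dbp": evaluate(estimates["dbp_est"], estimates["dbp_ref"]).as_dict(),
    }
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        estimates.to_csv(out / "estimates.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
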