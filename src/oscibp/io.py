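"""Reading and writing recordings: CSV trace + JSON sidecar.

A recording is stored as ``<stem>.csv`` with columns ``time_s``,
``cuff_pressure_mmHg`` and optionally ``ecg``, plus ``<stem>.json`` holding
the sampling rate, R-peak indices, reference pressures, artifact provenance
and (for synthetic data) the ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import CuffRecording
from .synthgen import GroundTruth


def write_recording(
    rec: CuffRecording, stem: Path | str, ground_truth: Optional[GroundTruth] = None
) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` and ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_s": rec.time, "cuff_pressure_mmHg": rec.cp}
    if rec.ecg is not None:
        cols["ecg"] = rec.ecg
    csv_path = stem.with_suffix(".csv")
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.6f")

    sidecar: dict = {
        "fs": rec.fs,
        "r_peak_indices": rec.r_peaks.tolist(),
        "reference_sbp": rec.reference_sbp,
        "reference_dbp": rec.reference_dbp,
        "meta": {k: v for k, v in rec.meta.items() if k != "artifacts"},
        "artifact_intervals": rec.meta.get("artifacts", []),
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = {
            "sbp": ground_truth.sbp,
            "dbp": ground_truth.dbp,
            "map": ground_truth.map,
            "sbpr": ground_truth.sbpr,
            "dbpr": ground_truth.dbpr,
            "ma": ground_truth.ma,
            "width_low": ground_truth.width_low,
            "width_high": ground_truth.width_high,
            "shape": ground_truth.shape,
            "hr": ground_truth.hr,
            "deflation_rate": ground_truth.deflation_rate,
            "pulse_times": np.asarray(ground_truth.pulse_times).tolist(),
        }
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def read_recording(stem: Path | str) -> tuple[CuffRecording, Optional[GroundTruth]]:
    """Read a recording written by :func:`write_recording`.

    ``stem`` may be the bare stem or either file's path.
    """
    stem = Path(stem)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    df = pd.read_csv(stem.with_suffix(".csv"))
    sidecar = json.loads(stem.with_suffix(".json").read_text())

    meta = dict(sidecar.get("meta", {}))
    meta["artifacts"] = sidecar.get("artifact_intervals", [])
    rec = CuffRecording(
        cp=df["cuff_pressure_mmHg"].to_numpy(),
        fs=float(sidecar["fs"]),
        r_peaks=np.asarray(sidecar["r_peak_indices"], dtype=int),
        reference_sbp=sidecar.get("reference_sbp"),
        reference_dbp=sidecar.get("reference_dbp"),
        ecg=df["ecg"].to_numpy() if "ecg" in df.columns else None,
        meta=meta,
    )
    gt = None
    if "ground_truth" in sidecar:
        g = sidecar["ground_truth"]
        gt = GroundTruth(
            sbp=g["sbp"], dbp=g["dbp"], map=g["map"], sbpr=g["sbpr"], dbpr=g["dbpr"],
            ma=g["ma"], width_low=g["width_low"], width_high=g["width_high"],
            shape=g["shape"], hr=g["hr"], deflation_rate=g["deflation_rate"],
            pulse_times=np.asarray(g.get("pulse_times", [])),
            artifact_intervals=meta["artifacts"],
        )
    return rec, gt


def list_recordings(directory: Path | str) -> list[Path]:
    """Stems of all recordings (csv+json pairs) in ``directory``."""
    directory = Path(directory)
    stems = []
    for csv_path in sorted(directory.glob("*.csv")):
        if csv_path.with_suffix(".json").exists():
            stems.append(csv_path.with_suffix(""))
    return stems
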