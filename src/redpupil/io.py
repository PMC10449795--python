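"""Readers and writers for the pipeline's interchange formats.

Frame sequences are zero-padded numbered PNG files plus a delimited-text
manifest; traces and summary tables are plain CSV.  Everything is codec-free
and bit-exact so runs are reproducible byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .agreement import AgreementResult, ValidationSummary
from .plr import PupilTrace
from .simulate import GroundTruthTrace

__all__ = [
    "write_frames",
    "read_frames",
    "read_manifest",
    "write_trace",
    "read_trace",
    "write_agreement_report",
    "write_cross_device_summary",
]

MANIFEST_NAME = "manifest.csv"


def write_frames(frames: np.ndarray, truth: GroundTruthTrace, outdir: str | Path) -> Path:
    """Write frames as ``frame_NNNNNN.png`` plus a ground-truth manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:06d}.png", frame)
    manifest = pd.DataFrame(
        {
            "frame_index": np.arange(len(truth)),
            "time_s": truth.timestamps_s,
            "true_diameter_px": truth.diameter_px,
            "blink_flag": truth.blink_flag.astype(int),
            "center_row": truth.center_px[:, 0],
            "center_col": truth.center_px[:, 1],
        }
    )
    manifest.to_csv(outdir / MANIFEST_NAME, index=False)
    return outdir / MANIFEST_NAME


def read_frames(indir: str | Path) -> list[np.ndarray]:
    """Read every ``frame_*.png`` of a directory in index order."""
    indir = Path(indir)
    paths = sorted(indir.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {indir}")
    return [iio.imread(p) for p in paths]


def read_manifest(indir_or_file: str | Path) -> GroundTruthTrace:
    """Load a simulator manifest back into a ground-truth trace."""
    path = Path(indir_or_file)
    if path.is_dir():
        path = path / MANIFEST_NAME
    df = pd.read_csv(path)
    return GroundTruthTrace(
        timestamps_s=df["time_s"].to_numpy(float),
        diameter_px=df["true_diameter_px"].to_numpy(float),
        blink_flag=df["blink_flag"].to_numpy() > 0,
        center_px=df[["center_row", "center_col"]].to_numpy(float),
    )


def write_trace(trace: PupilTrace, path: str | Path) -> Path:
    """Write a trace as CSV: time_s, diameter, unit, blink_flag (+ extras)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "time_s": trace.timestamps_s,
        "diameter": trace.diameter,
        "unit": trace.unit,
        "blink_flag": trace.blink.astype(int),
    }
    if trace.confidence is not None:
        data["confidence"] = trace.confidence
    if trace.center is not None:
        data["center_row"] = trace.center[:, 0]
        data["center_col"] = trace.center[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_trace(path: str | Path) -> PupilTrace:
    """Read a trace CSV (tolerates ``diameter_px``/``diameter_mm`` column names)."""
    df = pd.read_csv(path)
    diameter_col = next(
        (c for c in ("diameter", "diameter_px", "diameter_mm") if c in df.columns), None
    )
    if diameter_col is None or "time_s" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s and diameter")
    unit = "px"
    if "unit" in df.columns and len(df):
        unit = str(df["unit"].iloc[0])
    elif diameter_col.endswith("_mm"):
        unit = "mm"
    blink = df["blink_flag"].to_numpy() > 0 if "blink_flag" in df.columns else np.zeros(len(df), bool)
    return PupilTrace(
        timestamps_s=df["time_s"].to_numpy(float),
        diameter=df[diameter_col].to_numpy(float),
        blink=blink,
        unit=unit,
    )


def write_agreement_report(results: ValidationSummary | AgreementResult, path: str | Path) -> Path:
    """Write per-subject agreement rows plus a cohort footer row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, AgreementResult):
        from .agreement import summarize_cohort

        results = summarize_cohort([results])
    rows = [
        {
            "subject_id": i + 1,
            "n_samples": r.n_samples,
            "mae_pct": r.mae_pct,
            "pearson_r": r.pearson_r,
            "ba_bias": r.bland_altman_bias,
            "ba_loa_low": r.loa_low,
            "ba_loa_high": r.loa_high,
        }
        for i, r in enumerate(results.per_subject)
    ]
    rows.append(
        {
            "subject_id": "cohort",
            "n_samples": sum(r.n_samples for r in results.per_subject),
            "mae_pct": results.cohort_mean_mae_pct,
            "pearson_r": results.cohort_mean_pearson_r,
            "ba_bias": np.nan,
            "ba_loa_low": np.nan,
            "ba_loa_high": np.nan,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_cross_device_summary(summary, path: str | Path) -> Path:
    """Write the per-participant cross-device table with grand-mean footers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = summary.per_participant.copy()
    table.to_csv(path)
    with open(path, "a") as fh:
        fh.write(f"# grand_mean,{summary.grand_mean():.6f}\n")
        for label in sorted(set(table["eye_color"]) - {""}):
            fh.write(f"# grand_mean[{label}],{summary.grand_mean(label):.6f}\n")
    return path
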