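"""WAV, call-manifest and feature-table I/O.

Formats are deliberately plain: PCM16/float32 WAV for audio, a UTF-8 CSV
with fixed columns (call_id,file,start_s,end_s,call_type,individual_id,sex)
for manifests, and CSV + JSON sidecar for feature tables. All I/O is
deterministic and round-trip stable; loaders report rejected rows instead of
silently dropping them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .core import CallRecord, FeatureMatrix, Manifest, Waveform

MANIFEST_COLUMNS = ["call_id", "file", "start_s", "end_s", "call_type",
                    "individual_id", "sex"]
LABEL_COLUMNS = ["individual_id", "sex", "call_type"]

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_wav(path, expected_rate_hz: int | None = None) -> Waveform:
    """Read a PCM/float WAV as a [-1, 1] waveform.

    If ``expected_rate_hz`` differs from the file's rate the signal is
    polyphase-resampled to the expected rate (duration preserved to within
    one sample) and a warning is issued.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file named
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path} contains no samples")
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    samples = np.clip(samples, -1.0, 1.0)
    if expected_rate_hz is not None and expected_rate_hz != rate:
        warnings.warn(
            f"{path}: file rate {rate} Hz differs from expected "
            f"{expected_rate_hz} Hz; resampling",
            stacklevel=2,
        )
        ratio = Fraction(int(expected_rate_hz), int(rate))
        samples = resample_poly(samples, ratio.numerator, ratio.denominator)
        peak = np.max(np.abs(samples))
        if peak > 1.0:
            samples = samples / peak
        rate = expected_rate_hz
    return Waveform(samples=samples, rate_hz=int(rate))


def write_wav(path, waveform: Waveform, encoding: str = "float32") -> None:
    """Write a waveform as PCM16 or float32 WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if encoding == "pcm16":
        data = np.clip(waveform.samples, -1.0, 1.0)
        wavfile.write(path, waveform.rate_hz, (data * 32767.0).astype(np.int16))
    elif encoding == "float32":
        wavfile.write(path, waveform.rate_hz, waveform.samples.astype(np.float32))
    else:
        raise ValueError(f"unknown encoding {encoding!r}; use 'pcm16' or 'float32'")


@dataclass
class RejectionReport:
    """Rows a loader refused, with their CSV row numbers and reasons."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.rows)


def read_manifest(
    path, check_files: bool = False
) -> tuple[Manifest, RejectionReport]:
    """Load and validate a manifest CSV.

    Rows violating record invariants are collected in the rejection report
    (with 1-based data row numbers) rather than silently dropped; the counts
    always satisfy loaded + rejected = rows on disk.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"call_id": str, "file": str,
                                  "individual_id": str, "sex": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required column(s): {missing}")
    records: list[CallRecord] = []
    rejected = RejectionReport()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = CallRecord(
                call_id=str(row.call_id),
                file="" if pd.isna(row.file) else str(row.file),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                call_type=str(row.call_type),
                individual_id=str(row.individual_id),
                sex=str(row.sex),
            )
            if check_files and rec.file:
                f = Path(rec.file)
                if not f.is_absolute():
                    f = path.parent / f
                if not f.exists():
                    raise ValueError(f"referenced file {f} does not exist")
            records.append(rec)
        except (ValueError, TypeError) as exc:
            rejected.rows.append((i, str(exc)))
    if not records:
        raise ValueError(f"manifest {path}: no valid rows ({len(rejected.rows)} rejected)")
    rate = 62_500
    return Manifest(records=records, sample_rate_hz=rate,
                    provenance=f"loaded from {path.name}"), rejected


def write_manifest(manifest: Manifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_frame()[MANIFEST_COLUMNS].to_csv(path, index=False)


def write_colony(waveforms, records, out_dir, encoding: str = "pcm16",
                 sample_rate_hz: int = 62_500) -> Path:
    """Write one WAV per call plus the manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    audio_dir = out_dir / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    new_records = []
    for w, r in zip(waveforms, records):
        rel = f"audio/{r.call_id}.wav"
        write_wav(out_dir / rel, w, encoding=encoding)
        new_records.append(
            CallRecord(call_id=r.call_id, file=rel, start_s=0.0,
                       end_s=w.duration_s, call_type=r.call_type,
                       individual_id=r.individual_id, sex=r.sex)
        )
    manifest = Manifest(records=new_records, sample_rate_hz=sample_rate_hz,
                        provenance="synthetic colony")
    mpath = out_dir / "manifest.csv"
    write_manifest(manifest, mpath)
    return mpath


def write_feature_table(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as CSV (+ JSON sidecar).

    Feature columns are stored in canonical (lexicographic) order; the
    sidecar records the bank version and filtering provenance.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    feat_order = sorted(matrix.feature_names)
    df = pd.concat([matrix.labels[LABEL_COLUMNS], matrix.values[feat_order]], axis=1)
    df.index.name = "call_id"
    df.to_csv(path, float_format="%.12g")
    sidecar = {
        "bank_version": matrix.bank_version,
        "n_calls": matrix.n_calls,
        "n_features": len(feat_order),
        "feature_names": feat_order,
        "provenance": matrix.provenance,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_feature_table(
    path, allow_nonfinite: bool = False, expected_bank_version: str | None = None
) -> FeatureMatrix:
    """Read a feature table written by :func:`write_feature_table`.

    Feature columns are restored to canonical order by name regardless of
    their on-disk order. Filtered tables must be all-finite; reading a
    non-finite cell is an error unless ``allow_nonfinite`` is set.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col="call_id")
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing label column(s): {missing}")
    feat_cols = sorted(c for c in df.columns if c not in LABEL_COLUMNS)
    values = df[feat_cols].astype(np.float64)
    if not allow_nonfinite and not np.isfinite(values.to_numpy()).all():
        bad = [c for c in feat_cols if not np.isfinite(values[c].to_numpy()).all()]
        raise ValueError(
            f"feature table {path} contains non-finite values in {bad[:5]}...; "
            "filtered tables must be finite (pass allow_nonfinite=True for raw tables)"
        )
    bank_version, provenance = "", {}
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        bank_version = sidecar.get("bank_version", "")
        provenance = sidecar.get("provenance", {})
        if expected_bank_version and bank_version != expected_bank_version:
            warnings.warn(
                f"{path}: table bank version {bank_version!r} differs from "
                f"library bank {expected_bank_version!r}",
                stacklevel=2,
            )
    return FeatureMatrix(
        values=values,
        labels=df[LABEL_COLUMNS].astype(str),
        bank_version=bank_version,
        provenance=provenance if isinstance(provenance, dict) else {"note": provenance},
    )
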