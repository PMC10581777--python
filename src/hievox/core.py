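"""Shared domain containers.

The pipeline moves data through three containers: :class:`Waveform` (one
segmented call as a pressure time series), :class:`CallRecord`/:class:`Manifest`
(per-call labels: where the audio lives plus call type, individual and sex),
and :class:`FeatureMatrix` (calls x named acoustic features with the labels
kept row-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CALL_TYPES = ("trill", "phee", "food_call")
SEXES = ("F", "M")


@dataclass(frozen=True)
class Waveform:
    """A sampled pressure series in [-1, 1] with its sampling rate."""

    samples: np.ndarray
    rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("waveform must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("waveform amplitude exceeds [-1, 1]")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, Waveform):
            return NotImplemented
        return self.rate_hz == other.rate_hz and np.array_equal(
            self.samples, other.samples
        )


@dataclass(frozen=True)
class CallRecord:
    """One manually segmented call with its labels.

    Times are seconds into ``file`` over the half-open interval
    ``[start_s, end_s)``. ``file`` may be empty for in-memory synthetic calls.
    """

    call_id: str
    file: str
    start_s: float
    end_s: float
    call_type: str
    individual_id: str
    sex: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"call {self.call_id!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )
        if self.start_s < 0:
            raise ValueError(f"call {self.call_id!r}: start_s must be >= 0")
        if self.call_type not in CALL_TYPES:
            raise ValueError(
                f"call {self.call_id!r}: unknown call_type {self.call_type!r}; "
                f"expected one of {CALL_TYPES}"
            )
        if self.sex not in SEXES:
            raise ValueError(
                f"call {self.call_id!r}: sex must be one of {SEXES}, "
                f"got {self.sex!r}"
            )


@dataclass
class Manifest:
    """A validated list of call records plus recording metadata."""

    records: list[CallRecord]
    sample_rate_hz: int = 62_500
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("manifest must contain at least one record")
        ids = [r.call_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate call_id(s) in manifest: {dupes}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "call_id": r.call_id,
                    "file": r.file,
                    "start_s": r.start_s,
                    "end_s": r.end_s,
                    "call_type": r.call_type,
                    "individual_id": r.individual_id,
                    "sex": r.sex,
                }
                for r in self.records
            ]
        )


LABEL_COLUMNS = ("individual_id", "sex", "call_type")


@dataclass
class FeatureMatrix:
    """Calls x features with row-aligned labels.

    ``values`` is indexed by call_id with one named column per feature;
    ``labels`` shares the index and carries individual_id, sex and call_type.
    Before common-feature filtering cells may be non-finite.
    """

    values: pd.DataFrame
    labels: pd.DataFrame
    bank_version: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share the same call index")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"labels missing column(s): {missing}")

    @property
    def call_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_calls(self) -> int:
        return len(self.values)

    def subset(self, mask_or_index) -> "FeatureMatrix":
        """Row subset keeping labels aligned."""
        vals = self.values.loc[mask_or_index]
        return FeatureMatrix(
            values=vals,
            labels=self.labels.loc[vals.index],
            bank_version=self.bank_version,
            provenance=dict(self.provenance),
        )

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values.to_numpy()).all())


def check_labels(labels: Sequence, name: str = "labels") -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    return arr
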