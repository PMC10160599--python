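"""CPSC-2018-style record and label I/O.

Each record is a MATLAB v5 ``.mat`` file holding a struct ``ECG`` with fields
``data`` (12-lead signal matrix in millivolts), ``sex`` and ``age``; rhythm
labels live in a separate ``REFERENCE.csv`` with up to three labels per
record. Records are 500 Hz, 6-60 s. Sample indices are 0-based throughout
the package; times are in seconds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .errors import DataError, FormatError, VocabularyError

#: Standard 12-lead order used by CPSC-2018.
LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

DEFAULT_FS = 500.0
UNKNOWN_AGE = -1


class RhythmLabel(enum.Enum):
    """The 9 rhythm classes, ordinals 1-8 for the abnormal classes, 0 normal."""

    NORMAL = ("Normal", 0)
    AF = ("AF", 1)            # atrial fibrillation: irregular RR, absent P
    IAVB = ("I-AVB", 2)       # first-degree AV block: prolonged PR
    LBBB = ("LBBB", 3)        # left bundle branch block: wide QRS
    RBBB = ("RBBB", 4)        # right bundle branch block: wide QRS
    PAC = ("PAC", 5)          # premature atrial contraction
    PVC = ("PVC", 6)          # premature ventricular contraction
    STD = ("STD", 7)          # ST-segment depression
    STE = ("STE", 8)          # ST-segment elevation

    def __init__(self, code: str, ordinal: int):
        self.code = code
        self.ordinal = ordinal

    @classmethod
    def from_code(cls, code: str) -> "RhythmLabel":
        for member in cls:
            if member.code == code:
                return member
        raise VocabularyError(f"unknown rhythm label code: {code!r}")

    @classmethod
    def from_ordinal(cls, ordinal: int) -> "RhythmLabel":
        for member in cls:
            if member.ordinal == ordinal:
                return member
        raise VocabularyError(f"unknown rhythm ordinal: {ordinal!r}")


@dataclass
class ECGRecord:
    """A multi-lead ECG with metadata; the unit every stage consumes.

    ``signal`` is oriented leads x samples, in millivolts.
    """

    record_id: str
    signal: np.ndarray
    fs: float = DEFAULT_FS
    lead_names: tuple = LEAD_NAMES
    sex: str = "Unknown"
    age: int = UNKNOWN_AGE
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.size == 0:
            raise DataError(
                f"{self.record_id}: signal must be a non-empty 2-D matrix"
            )
        if self.fs <= 0:
            raise DataError(f"{self.record_id}: fs must be positive")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, index: int) -> np.ndarray:
        return self.signal[index]


class LabelTable(dict):
    """record_id -> list of RhythmLabel; the first entry is the primary label."""

    def primary(self, record_id: str) -> RhythmLabel:
        return self[record_id][0]


def _orient(signal: np.ndarray) -> np.ndarray:
    # Longer axis = samples: durations (>= 6 s at 500 Hz) always exceed the
    # lead count, so a tall matrix was stored samples x leads.
    if signal.shape[0] > signal.shape[1]:
        return signal.T
    return signal


def read_record(path, fs: float = DEFAULT_FS) -> ECGRecord:
    """Read a CPSC-dialect ``.mat`` record.

    The signal is normalized to leads x samples regardless of the stored
    orientation. ``fs`` defaults to the CPSC sampling rate of 500 Hz.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such record file: {path}")
    try:
        container = loadmat(path, squeeze_me=False)
    except Exception as exc:  # scipy raises a mix of ValueError/NotImplementedError
        raise FormatError(f"{path} is not a readable MATLAB v5 file: {exc}") from exc
    if "ECG" not in container:
        raise FormatError(f"{path}: missing 'ECG' struct")
    ecg = container["ECG"][0, 0]
    try:
        data = np.asarray(ecg["data"], dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: signal matrix is not numeric") from exc
    sex = str(np.atleast_1d(ecg["sex"]).ravel()[0]) if "sex" in ecg.dtype.names else "Unknown"
    if "age" in ecg.dtype.names:
        age_raw = np.asarray(ecg["age"]).ravel()
        age = int(age_raw[0]) if age_raw.size and np.isfinite(float(age_raw[0])) else UNKNOWN_AGE
    else:
        age = UNKNOWN_AGE
    return ECGRecord(
        record_id=path.stem,
        signal=_orient(data),
        fs=fs,
        sex=sex or "Unknown",
        age=age,
    )


def write_fixture(record: ECGRecord, path) -> Path:
    """Write a record in the same ``.mat`` dialect ``read_record`` consumes.

    Numeric round-trip is lossless (float64 storage).
    """
    path = Path(path)
    payload = {
        "ECG": {
            "sex": record.sex,
            "age": np.array([[record.age]]),
            "data": np.asarray(record.signal, dtype=np.float64),
        }
    }
    try:
        savemat(path, payload)
    except OSError as exc:
        raise OSError(f"cannot write fixture to {path}: {exc}") from exc
    return path


def read_labels(path) -> LabelTable:
    """Parse a ``REFERENCE.csv`` (header ``Recording,First_label,...``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such label table: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: need a record-id column and >= 1 label column")
    table = LabelTable()
    id_col = frame.columns[0]
    label_cols = frame.columns[1:4]
    for _, row in frame.iterrows():
        labels = [
            RhythmLabel.from_code(row[c].strip())
            for c in label_cols
            if str(row[c]).strip()
        ]
        if not labels:
            raise VocabularyError(f"{path}: record {row[id_col]} has no labels")
        table[str(row[id_col])] = labels
    return table


def write_labels(table: LabelTable, path) -> Path:
    """Write a LabelTable back out in REFERENCE.csv dialect."""
    path = Path(path)
    rows = []
    for record_id, labels in table.items():
        codes = [lab.code for lab in labels] + ["", "", ""]
        rows.append([record_id] + codes[:3])
    frame = pd.DataFrame(
        rows, columns=["Recording", "First_label", "Second_label", "Third_label"]
    )
    frame.to_csv(path, index=False)
    return path


def binarize(labels) -> int:
    """Collapse a label list to the screening target: 0 normal, 1 abnormal.

    A record is normal only if every label is Normal; any abnormal rhythm
    anywhere in the list makes it abnormal.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot binarize an empty label list")
    return int(any(lab is not RhythmLabel.NORMAL for lab in labels))
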