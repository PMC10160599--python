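"""Beat segmentation and feature extraction.

Each detected R-peak yields one fixed-length beat window (250 ms before to
400 ms after the peak by default, covering P-QRS-T at normal rates); beats
whose window crosses a record edge are dropped. The base feature vector per
beat is the level-4 sym8 approximation coefficient block of the decimated
DWT of the window — a smooth, ~16x shorter morphological summary of the
beat. Optionally three RR-interval context features are appended: the
preceding RR, the following RR, and the ratio of the preceding RR to the
local 8-beat mean RR (all in seconds / dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError
from .records import ECGRecord
from .rpeaks import RPeakSeries
from .wavelets import dwt_multilevel

RR_FEATURE_NAMES = ("rr_prev_s", "rr_next_s", "rr_local_ratio")


@dataclass(frozen=True)
class BeatWindow:
    pre_ms: float = 250.0
    post_ms: float = 400.0

    def __post_init__(self):
        if self.pre_ms <= 0 or self.post_ms <= 0:
            raise ValueError("window extents must be positive")

    def n_samples(self, fs: float) -> int:
        return int(round(fs * (self.pre_ms + self.post_ms) / 1000.0))

    def pre_samples(self, fs: float) -> int:
        return int(round(fs * self.pre_ms / 1000.0))


@dataclass
class FeatureMatrix:
    """Per-beat feature vectors with labels and (optional) fitted scaling."""

    X: np.ndarray
    y: np.ndarray | None = None
    feature_names: tuple = ()
    normalization: dict | None = None        # {"mean": ..., "sd": ...}
    record_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if np.any(~np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if len(self.y) != len(self.X):
                raise ValueError("labels must align with feature rows")

    @property
    def n_beats(self) -> int:
        return self.X.shape[0]

    def take(self, idx) -> "FeatureMatrix":
        ids = [self.record_ids[i] for i in idx] if self.record_ids else []
        return FeatureMatrix(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            feature_names=self.feature_names,
            normalization=self.normalization,
            record_ids=ids,
        )


def segment_beats(record: ECGRecord, peaks: RPeakSeries,
                  window: BeatWindow = BeatWindow(), lead: int = 0):
    """One fixed-length row per R-peak whose full window fits in the record.

    Returns ``(beats, kept, n_dropped)`` where ``kept`` holds, for each row,
    the index of its peak within ``peaks.indices``.
    """
    if len(peaks) < 1:
        raise ValueError("need at least one detected R-peak")
    fs = record.fs
    pre = window.pre_samples(fs)
    total = window.n_samples(fs)
    x = record.lead(lead)
    rows, kept = [], []
    for k, c in enumerate(peaks.indices):
        lo = c - pre
        hi = lo + total
        if lo < 0 or hi > len(x):
            continue
        rows.append(x[lo:hi])
        kept.append(k)
    n_dropped = len(peaks) - len(rows)
    beats = np.vstack(rows) if rows else np.empty((0, total))
    return beats, np.asarray(kept, dtype=int), n_dropped


def rr_context(peaks: RPeakSeries, kept) -> np.ndarray:
    """(rr_prev, rr_next, ratio-to-local-8-beat-mean) per kept beat.

    Edge beats reuse the available neighbour; a record with fewer than two
    peaks has no RR at all and gets zeros.
    """
    kept = np.asarray(kept, dtype=int)
    rr = peaks.rr_s
    out = np.zeros((len(kept), 3))
    if rr.size == 0:
        return out
    for row, k in enumerate(kept):
        prev = rr[k - 1] if k >= 1 else rr[min(k, rr.size - 1)]
        nxt = rr[k] if k < rr.size else rr[-1]
        lo, hi = max(0, k - 4), min(rr.size, k + 4)
        local = float(np.mean(rr[lo:hi])) if hi > lo else prev
        out[row] = (prev, nxt, prev / local if local > 0 else 1.0)
    return out


def approx_length(n: int, wavelet: str = "sym8", level: int = 4,
                  boundary: str = "symmetric") -> int:
    """Length of the level-``level`` approximation block for an input of
    length ``n`` — taken from the transform itself, the single source of
    truth for coefficient-sequence lengths."""
    d = dwt_multilevel(np.zeros(n), wavelet, level, boundary)
    return len(d.approx)


class WaveletFeatureExtractor:
    """sklearn-style transformer: beat rows -> level-4 approximation blocks."""

    def __init__(self, wavelet: str = "sym8", level: int = 4,
                 boundary: str = "symmetric"):
        self.wavelet = wavelet
        self.level = level
        self.boundary = boundary

    def fit(self, X=None, y=None):
        return self

    def transform(self, beats: np.ndarray) -> np.ndarray:
        beats = np.atleast_2d(np.asarray(beats, dtype=float))
        if beats.shape[1] <= 2 ** self.level:
            raise ValueError(
                f"beats of length {beats.shape[1]} too short for level {self.level}"
            )
        return np.vstack([
            dwt_multilevel(row, self.wavelet, self.level, self.boundary).approx
            for row in beats
        ])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"wavelet": self.wavelet, "level": self.level,
                "boundary": self.boundary}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self


def extract_features(beats: np.ndarray, rr: np.ndarray | None = None,
                     include_rr: bool = True, wavelet: str = "sym8",
                     level: int = 4) -> FeatureMatrix:
    """Build the per-beat feature matrix.

    ``rr`` is the aligned (n_beats, 3) RR-context block from
    :func:`rr_context`; required when ``include_rr`` is true.
    """
    extractor = WaveletFeatureExtractor(wavelet=wavelet, level=level)
    base = extractor.transform(beats)
    names = [f"ca{level}_{i}" for i in range(base.shape[1])]
    if include_rr:
        if rr is None:
            raise ValueError("include_rr=True requires the RR-context block")
        rr = np.asarray(rr, dtype=float)
        if rr.shape != (base.shape[0], 3):
            raise SchemaError(
                f"RR context shape {rr.shape} does not align with {base.shape[0]} beats"
            )
        base = np.hstack([base, rr])
        names += list(RR_FEATURE_NAMES)
    return FeatureMatrix(X=base, feature_names=tuple(names))


class BeatNormalizer:
    """Z-scoring with train-fitted mean/sd; zero-variance features pass
    through unscaled and are flagged in ``zero_variance_mask_``."""

    def __init__(self):
        pass

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.zero_variance_mask_ = sd == 0
        self.scale_ = np.where(self.zero_variance_mask_, 1.0, sd)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        out = X.copy()
        live = ~self.zero_variance_mask_
        out[:, live] = (X[:, live] - self.mean_[live]) / self.scale_[live]
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError("BeatNormalizer has no parameters")
        return self


def fit_apply_normalization(train: FeatureMatrix, test: FeatureMatrix):
    """Z-score both partitions with statistics fitted on the train split only."""
    if train.feature_names != test.feature_names:
        raise SchemaError("train/test feature schemas differ")
    scaler = BeatNormalizer().fit(train.X)
    norm = {"mean": scaler.mean_.copy(), "sd": scaler.scale_.copy()}
    train_out = FeatureMatrix(scaler.transform(train.X), train.y,
                              train.feature_names, norm, train.record_ids)
    test_out = FeatureMatrix(scaler.transform(test.X), test.y,
                             test.feature_names, norm, test.record_ids)
    return train_out, test_out
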