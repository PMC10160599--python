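"""End-to-end orchestration: load/generate -> denoise -> detect -> segment ->
extract -> split -> grid search -> fit -> predict -> report.

Every stochastic step derives from the single ``seed`` in
:class:`PipelineConfig`; re-running the same config is bit-identical in all
numeric outputs, and the written ``manifest.json`` records everything needed
to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (GridSpec, RbfSvmClassifier, SVMConfig, fit_svm,
                       grid_search_cv, predict, stratified_split)
from .features import (BeatWindow, FeatureMatrix, extract_features,
                       fit_apply_normalization, rr_context, segment_beats)
from .metrics import ClassificationReport, ConfusionMatrix, ROCCurve, confusion, report, roc
from .records import ECGRecord, LabelTable, binarize, read_labels, read_record
from .rpeaks import ModwtPeakDetector
from .synth import SynthConfig, generate_dataset
from .wavelets import denoise as wavelet_denoise


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries stage and record context."""

    def __init__(self, stage: str, record_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on record {record_id!r}: {cause}")
        self.stage = stage
        self.record_id = record_id
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    source: str = "synthetic"            # "synthetic" | path to a CPSC-style dir
    classes: tuple = ("Normal", "AF")
    n_per_class: int = 100
    synth: SynthConfig = field(default_factory=SynthConfig)
    detector: dict = field(default_factory=dict)      # ModwtPeakDetector kwargs
    window: BeatWindow = field(default_factory=BeatWindow)
    include_rr: bool = True
    denoise: bool = True
    grid: GridSpec = field(default_factory=GridSpec)
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie strictly between 0 and 1")
        ModwtPeakDetector(**self.detector)   # validate eagerly

    def to_manifest(self) -> dict:
        out = dataclasses.asdict(self)
        out["classes"] = [getattr(c, "code", c) for c in self.classes]
        out["synth"]["rhythm"] = self.synth.rhythm.code
        return out


def load_directory(path) -> list:
    """Read every ``*.mat`` record in a CPSC-style directory and attach its
    labels from ``REFERENCE.csv``."""
    path = Path(path)
    table = read_labels(path / "REFERENCE.csv")
    records = []
    for mat in sorted(path.glob("*.mat")):
        rec = read_record(mat)
        rec.labels = table.get(rec.record_id, [])
        records.append(rec)
    return records


def record_to_beats(record: ECGRecord, detector: ModwtPeakDetector,
                    window: BeatWindow, include_rr: bool, denoise: bool):
    """Denoise (detection lead), detect, segment and extract one record.

    Returns a FeatureMatrix (unlabelled) or None if no complete beat fits.
    """
    lead = detector.lead
    work = record
    if denoise:
        signal = record.signal.copy()
        signal[lead] = wavelet_denoise(signal[lead])
        work = dataclasses.replace(record, signal=signal)
    peaks = detector.detect(work)
    if len(peaks) == 0:
        return None
    beats, kept, _ = segment_beats(work, peaks, window, lead=lead)
    if beats.shape[0] == 0:
        return None
    rr = rr_context(peaks, kept) if include_rr else None
    fm = extract_features(beats, rr, include_rr=include_rr)
    fm.record_ids = [record.record_id] * fm.n_beats
    return fm


def build_feature_matrix(records, config: PipelineConfig) -> FeatureMatrix:
    """Run the per-record beat path over a record list and stack the result
    with binarized record-level labels broadcast to every beat."""
    detector = ModwtPeakDetector(**config.detector)
    blocks, labels, ids = [], [], []
    for rec in records:
        try:
            fm = record_to_beats(rec, detector, config.window,
                                 config.include_rr, config.denoise)
        except Exception as exc:
            raise StageError("features", rec.record_id, exc)
        if fm is None:
            continue
        blocks.append(fm.X)
        labels.extend([binarize(rec.labels)] * fm.n_beats)
        ids.extend(fm.record_ids)
        names = fm.feature_names
    if not blocks:
        raise ValueError("no record yielded any complete beat")
    return FeatureMatrix(X=np.vstack(blocks), y=np.asarray(labels, dtype=int),
                         feature_names=names, record_ids=ids)


@dataclass
class PipelineResult:
    accuracy: float
    report: ClassificationReport
    cm: ConfusionMatrix
    roc_curve: ROCCurve
    best_config: SVMConfig
    cv_results: pd.DataFrame
    model: RbfSvmClassifier
    n_beats_train: int
    n_beats_test: int


def run_pipeline(config: PipelineConfig, out_dir=None, resume: bool = False) -> PipelineResult:
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.json"
        if resume and manifest_path.exists() and (out_dir / "report.json").exists():
            previous = json.loads(manifest_path.read_text())
            wanted = json.loads(json.dumps(config.to_manifest()))
            if previous.get("config") == wanted:
                return _load_result(out_dir)

    if config.source == "synthetic":
        synth_records, _ = generate_dataset(
            config.n_per_class, config.classes, config.synth, seed=config.seed
        )
        records = [sr.record for sr in synth_records]
    else:
        records = load_directory(config.source)

    features = build_feature_matrix(records, config)
    train, test = stratified_split(features, config.test_fraction, seed=config.seed)
    train, test = fit_apply_normalization(train, test)
    grid = dataclasses.replace(config.grid, seed=config.seed)
    best, cv_results = grid_search_cv(train, grid)
    model = fit_svm(train, best)
    y_pred, scores = predict(model, test)
    cm = confusion(test.y, y_pred)
    rep = report(cm)
    curve = roc(test.y, scores)

    result = PipelineResult(
        accuracy=rep.accuracy, report=rep, cm=cm, roc_curve=curve,
        best_config=best, cv_results=cv_results, model=model,
        n_beats_train=train.n_beats, n_beats_test=test.n_beats,
    )
    if out_dir is not None:
        _write_result(out_dir, config, result)
    return result


def _write_result(out_dir: Path, config: PipelineConfig, result: PipelineResult):
    (out_dir / "report.json").write_text(result.report.to_json())
    pd.DataFrame(result.cm.counts,
                 index=["true_0", "true_1"],
                 columns=["pred_0", "pred_1"]).to_csv(out_dir / "confusion.csv")
    pd.DataFrame({
        "threshold": result.roc_curve.thresholds,
        "fpr": result.roc_curve.fpr,
        "tpr": result.roc_curve.tpr,
    }).to_csv(out_dir / "roc.csv", index=False)
    result.cv_results.to_csv(out_dir / "cv_results.csv", index=False)
    result.model.save(out_dir / "model.joblib")
    import scipy
    import sklearn
    import pywt
    manifest = {
        "config": config.to_manifest(),
        "best": dataclasses.asdict(result.best_config),
        "auc": result.roc_curve.auc,
        "versions": {
            "wavebeat": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "pywavelets": pywt.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_result(out_dir: Path) -> PipelineResult:
    rep_dict = json.loads((out_dir / "report.json").read_text())
    cm = ConfusionMatrix(
        pd.read_csv(out_dir / "confusion.csv", index_col=0).to_numpy()
    )
    rep = report(cm)
    roc_frame = pd.read_csv(out_dir / "roc.csv")
    manifest = json.loads((out_dir / "manifest.json").read_text())
    curve = ROCCurve(
        thresholds=roc_frame["threshold"].to_numpy(),
        fpr=roc_frame["fpr"].to_numpy(),
        tpr=roc_frame["tpr"].to_numpy(),
        auc=float(manifest["auc"]),
    )
    cv_results = pd.read_csv(out_dir / "cv_results.csv")
    best = SVMConfig(**{k: v for k, v in manifest["best"].items()})
    model = RbfSvmClassifier.load(out_dir / "model.joblib")
    return PipelineResult(
        accuracy=float(rep_dict["accuracy"]), report=rep, cm=cm,
        roc_curve=curve, best_config=best, cv_results=cv_results, model=model,
        n_beats_train=-1, n_beats_test=cm.total,
    )
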