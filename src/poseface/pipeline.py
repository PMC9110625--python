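"""End-to-end expression-recognition pipeline.

Chains the stages: track the anchor points across a sequence with pyramidal
optical flow, extract Gabor magnitude descriptors from patches centered on
the tracked (visible) points of the apex frame, select discriminative
features with stump-mode AdaBoost, and classify with one-vs-rest Ada-AdaSVM
under leave-one-subject-out cross-validation.

The classifier stage selects K features before fitting: raw point-centered
Gabor descriptors are thousands-dimensional, where an RBF kernel at the
default scale schedule would operate in its memorization regime; boosting's
own feature selection is the dimensionality-reduction step of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gabor, synthetic, tracking
from .ensemble import (
    AnnealSchedule,
    CVReport,
    LabeledDataset,
    MulticlassAdaSVM,
    losocv,
    select_features,
)
from .errors import InvalidInputError

__all__ = [
    "ExtractionConfig",
    "ClassifierConfig",
    "extract_sequence_features",
    "features_from_scenes",
    "evaluate_losocv",
    "run_expression_benchmark",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Patch-based Gabor extraction parameters."""

    patch_size: int = 48  # must exceed the largest kernel support (41 px default bank)
    bank: gabor.BankConfig = field(default_factory=gabor.BankConfig)
    apex_frame: int = -1  # frame index whose patches are described


@dataclass(frozen=True)
class ClassifierConfig:
    """Feature-selection + Ada-AdaSVM parameters."""

    n_features: int = 64  # K selected before classification; 0 disables selection
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    C: float = 1.0
    T: int = 5
    selection_weak: str = "stump"
    seed: int = 42


def _extract_patch(frame: np.ndarray, center: tuple[float, float], size: int) -> np.ndarray | None:
    """Square patch around ``center`` (rounded), None if it leaves the frame."""
    h, w = frame.shape
    half = size // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, y0 = cx - half, cy - half
    if x0 < 0 or y0 < 0 or x0 + size > w or y0 + size > h:
        return None
    return frame[y0 : y0 + size, x0 : x0 + size]


def extract_sequence_features(
    frames: list[np.ndarray],
    tracks: list[tracking.FeatureTrack],
    bank: gabor.GaborBank,
    config: ExtractionConfig | None = None,
) -> np.ndarray:
    """Concatenated Gabor descriptor of one sequence.

    One patch per anchor, centered on its tracked position in the apex frame;
    anchors that were lost, or whose patch leaves the frame, contribute zeros
    (a fixed-dimension descriptor keeps sequences comparable).
    """
    cfg = config or ExtractionConfig()
    apex = cfg.apex_frame % len(frames)
    frame = np.asarray(getattr(frames[apex], "pixels", frames[apex]), dtype=float)
    per_patch = gabor.feature_dimension(bank, (cfg.patch_size, cfg.patch_size))
    parts = []
    for tr in tracks:
        patch = None
        if tr.is_live or len(tr.positions) > apex:
            if len(tr.positions) > apex:
                patch = _extract_patch(frame, tr.positions[apex], cfg.patch_size)
        if patch is None:
            parts.append(np.zeros(per_patch))
        else:
            parts.append(gabor.feature_vector(patch, bank).values)
    return np.concatenate(parts)


def features_from_scenes(
    scenes: list[synthetic.SyntheticScene],
    extraction: ExtractionConfig | None = None,
    tracking_config: tracking.TrackingConfig | None = None,
):
    """Render, track and describe every scene.

    Tracking starts from the ground-truth anchor projections of frame 0 (the
    initial landmarks are an input to the method, not something it detects).
    Returns (X, y, subjects).
    """
    cfg = extraction or ExtractionConfig()
    bank = gabor.make_bank(cfg.bank)
    tcfg = tracking_config or tracking.TrackingConfig()
    X, y, subjects = [], [], []
    for scene in scenes:
        frames, truth = synthetic.render_sequence(scene)
        initial = truth.tracks[0]
        tracks = tracking.track_sequence(frames, initial, tcfg)
        X.append(extract_sequence_features(frames, tracks, bank, cfg))
        y.append(scene.label)
        subjects.append(scene.subject)
    return np.vstack(X), np.asarray(y), np.asarray(subjects)


def evaluate_losocv(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    config: ClassifierConfig | None = None,
) -> CVReport:
    """LOSOCV of the select-then-classify stage.

    Feature selection runs inside each fold (on training data only) to avoid
    leaking held-out subjects into the feature ranking.
    """
    cfg = config or ClassifierConfig()

    def fit_predict(X_tr, y_tr, subj_tr, X_te):
        cols = np.arange(X_tr.shape[1])
        if cfg.n_features and cfg.n_features < X_tr.shape[1]:
            classes = np.unique(y_tr)
            if len(classes) < 2:
                raise InvalidInputError("training fold has a single class")
            # one-vs-rest union of per-class selections
            per = max(1, cfg.n_features // len(classes))
            chosen: list[int] = []
            for c in classes:
                data = LabeledDataset(X_tr, np.where(y_tr == c, 1, -1), subj_tr)
                for f in select_features(
                    data, per, schedule=cfg.schedule, seed=cfg.seed,
                    C=cfg.C, weak=cfg.selection_weak,
                ):
                    if f not in chosen:
                        chosen.append(f)
            cols = np.array(sorted(chosen[: cfg.n_features]))
        model = MulticlassAdaSVM(
            X_tr[:, cols], y_tr, subj_tr, schedule=cfg.schedule, C=cfg.C, T=cfg.T
        )
        res = model.fit(seed=cfg.seed)
        return res.predict(X_te[:, cols])

    return losocv(X, y, subjects, fit_predict)


def run_expression_benchmark(
    n_classes: int = 3,
    n_subjects: int = 5,
    reps: int = 2,
    n_frames: int = 5,
    deformation_amplitude: float = 0.6,
    frame_shape: tuple[int, int] = (128, 128),
    seed: int = 42,
    extraction: ExtractionConfig | None = None,
    classifier: ClassifierConfig | None = None,
) -> CVReport:
    """Full synthetic benchmark: render -> track -> extract -> select/classify."""
    scenes = synthetic.make_expression_sequences(
        n_classes=n_classes, n_subjects=n_subjects, reps=reps, n_frames=n_frames,
        deformation_amplitude=deformation_amplitude, frame_shape=frame_shape,
        seed=seed,
    )
    X, y, subjects = features_from_scenes(scenes, extraction)
    cfg = classifier or ClassifierConfig(seed=seed)
    return evaluate_losocv(X, y, subjects, cfg)
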