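"""Early-learning-stopped training and self-learning label recruitment.

Networks trained on noisy labels fit the cleanly labelled structure first
and memorize label noise later; training is therefore stopped at the elbow
(curvature maximum) of the validation soft-Dice loss curve, and the stopped
model's own QC-filtered predictions are recruited as labels for the next
round.  :func:`run_view_pipeline` chains the per-view staged recipes:

* A2C — blood-pool weak labels -> early-stopped training -> self-learning
  -> final training.
* A4C — two-chamber model inference (two ventricle + two atrium components)
  -> four-chamber relabelling -> RV apex stretch -> early-stopped training
  -> self-learning -> final training.
* SAX — Hough-circle labels -> edge-detector training -> filled edge maps
  -> first segmenter -> self-learning -> epi/endo label synthesis -> second
  segmenter.

Every training stage consumes only QC-passed labels, and the train /
validation split never lets a study id cross the boundary.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import skimage.measure
import skimage.morphology

from .datatypes import (
    Chamber,
    ChamberMaskSet,
    CineClip,
    Provenance,
    UltrasoundFrame,
    View,
)
from .errors import (
    DegenerateError,
    EmptyTrainSetError,
    InvalidInputError,
    NoElbowError,
    StageStarvedError,
    UnassignableError,
)
from .nets import (
    AugmentationPolicy,
    PixelSegmenter,
    SegmenterConfig,
    augment_pair,
    predict_masks,
)
from .qc import QCConfig, qc_gate
from .weak_label import (
    A2CWeakLabelConfig,
    a2c_weak_label,
    circle_to_mask,
    hough_circle_detect,
    edge_to_filled_mask,
    make_epi_endo_labels,
    reassign_a4c_labels,
    stretch_rv_apex,
)

__all__ = [
    "LossCurve",
    "RoundReport",
    "TrainingExample",
    "detect_elbow",
    "train_early_stop",
    "self_learning_round",
    "PipelineProfile",
    "PipelineResult",
    "run_view_pipeline",
]


@dataclass
class LossCurve:
    """Per-epoch validation loss."""

    epoch_index: np.ndarray
    validation_loss: np.ndarray

    def __post_init__(self) -> None:
        self.epoch_index = np.asarray(self.epoch_index, dtype=int)
        self.validation_loss = np.asarray(self.validation_loss, dtype=float)
        if self.epoch_index.shape != self.validation_loss.shape:
            raise ValueError("epoch_index and validation_loss must align")
        if self.epoch_index.size and (np.diff(self.epoch_index) <= 0).any():
            raise ValueError("epochs must be strictly increasing")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "validation_loss"])
            for e, l in zip(self.epoch_index, self.validation_loss):
                writer.writerow([int(e), float(l)])


@dataclass
class RoundReport:
    """Bookkeeping for one self-learning round."""

    round_id: int
    n_candidate_labels: int
    n_qc_passed: int
    stop_epoch: int = -1
    final_validation_loss: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_qc_passed > self.n_candidate_labels:
            raise ValueError("QC cannot pass more labels than were candidates")


@dataclass
class TrainingExample:
    """One QC-passed (frame, label) pair used for training."""

    study_id: str
    frame: UltrasoundFrame
    masks: ChamberMaskSet


def detect_elbow(curve: LossCurve, smoothing_window: int = 3) -> int:
    """Early-stopping epoch: the bend (maximal-curvature point) of the curve.

    Standard knee detection on the min-max normalized curve after a
    3-epoch running-median smoother: the elbow is the epoch where the curve
    lies furthest below the chord joining its endpoints.  The median
    smoother is the identity on monotone curves, so a noise-free
    piecewise-linear corner is recovered exactly; a run of numerically tied
    maxima resolves to its middle element.

    Raises
    ------
    NoElbowError
        If the curve is constant or straight (no bend anywhere), or bends
        the wrong way (never dips below its chord).
    """
    y = np.asarray(curve.validation_loss, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 epochs to locate an elbow")
    if np.ptp(y) < 1e-12:
        raise NoElbowError("constant loss curve")
    y = (y - y.min()) / np.ptp(y)
    if smoothing_window > 1:
        import scipy.ndimage

        y = scipy.ndimage.median_filter(y, size=smoothing_window, mode="nearest")
    x = np.linspace(0.0, 1.0, y.size)
    chord = y[0] + (y[-1] - y[0]) * x
    deviation = chord - y
    if deviation.max() < 1e-6:
        raise NoElbowError("straight-line loss curve (no bend below its chord)")
    tied = np.flatnonzero(deviation >= deviation.max() - 1e-12)
    mid = int(tied[len(tied) // 2])
    return int(curve.epoch_index[mid])


def _split_by_patient(
    examples: Sequence[TrainingExample], val_fraction: float, rng: np.random.Generator
) -> tuple[list[TrainingExample], list[TrainingExample]]:
    ids = sorted({ex.study_id for ex in examples})
    if len(ids) < 2:
        raise EmptyTrainSetError("need at least 2 patients to split by patient")
    order = rng.permutation(len(ids))
    n_val = max(1, int(round(val_fraction * len(ids))))
    n_val = min(n_val, len(ids) - 1)
    val_ids = {ids[i] for i in order[:n_val]}
    train = [ex for ex in examples if ex.study_id not in val_ids]
    val = [ex for ex in examples if ex.study_id in val_ids]
    return train, val


def _targets(example: TrainingExample, chambers: Sequence[Chamber]) -> np.ndarray:
    shape = example.frame.pixels.shape
    stack = np.zeros(shape + (len(chambers),), dtype=np.float64)
    for i, ch in enumerate(chambers):
        if ch in example.masks:
            stack[..., i] = example.masks[ch].astype(np.float64)
    return stack


def train_early_stop(
    model_config: SegmenterConfig,
    labeled_data: Sequence[TrainingExample],
    max_epochs: int = 20,
    val_fraction: float = 0.2,
    augmentation: Optional[AugmentationPolicy] = None,
    seed: int = 0,
) -> tuple[PixelSegmenter, LossCurve, int]:
    """Train a segmenter and rewind it to the validation-loss elbow.

    80/20 train/validation split by patient; the validation soft-Dice loss
    is recorded every epoch, the elbow epoch is detected post hoc, and the
    checkpoint from that epoch becomes the returned model.  When the curve
    has no elbow (short smooth descents), the epoch with the lowest
    validation loss is used instead.

    Raises
    ------
    EmptyTrainSetError
        No labels, labels without QC-passed provenance, or < 2 patients.
    """
    if not labeled_data:
        raise EmptyTrainSetError("no labeled examples")
    for ex in labeled_data:
        if ex.masks.provenance is not Provenance.QC_PASSED:
            raise EmptyTrainSetError(
                f"training label for {ex.study_id} lacks QC-passed provenance"
            )
    rng = np.random.default_rng([seed, 4021])
    train, val = _split_by_patient(labeled_data, val_fraction, rng)
    chambers = model_config.chambers

    def prepare(examples):
        images, targets = [], []
        for i, ex in enumerate(examples):
            frame, masks = ex.frame, ex.masks
            if augmentation is not None:
                frame, masks = augment_pair(
                    frame, masks, augmentation, seed=seed * 100003 + i
                )
                ex = TrainingExample(ex.study_id, frame, masks)
            images.append(frame.pixels)
            targets.append(_targets(ex, chambers))
        return images, targets

    train_images, train_targets = prepare(train)
    val_images, val_targets = prepare(val)
    model = PixelSegmenter(model_config)
    result = model.fit(
        train_images,
        train_targets,
        val_images,
        val_targets,
        epochs=max_epochs,
        seed=seed,
    )
    curve = LossCurve(np.arange(max_epochs), result.validation_loss)
    try:
        stop_epoch = detect_elbow(curve)
    except NoElbowError:
        stop_epoch = int(np.argmin(result.validation_loss))
    model.load_checkpoint(result.checkpoints[stop_epoch])
    return model, curve, stop_epoch


def self_learning_round(
    model: PixelSegmenter,
    all_clips: Sequence[CineClip],
    qc_config: QCConfig,
    round_id: int = 1,
    keep_components: int = 1,
) -> tuple[list[TrainingExample], RoundReport]:
    """Recruit the model's own QC-passed predictions as next-round labels.

    Inference runs on every frame of every available clip; predictions pass
    through the QC gate, and survivors (re-tagged ``qc_passed``) become the
    next round's training labels.
    """
    recruited: list[TrainingExample] = []
    n_candidates = 0
    for clip in all_clips:
        for frame in clip.frames:
            pred = predict_masks(model, frame, keep_components=keep_components)
            if not any(m.any() for m in pred.masks.values()):
                continue
            n_candidates += 1
            passed, _reasons = qc_gate(pred, qc_config)
            if passed:
                recruited.append(
                    TrainingExample(
                        clip.study_id, frame, pred.with_provenance(Provenance.QC_PASSED)
                    )
                )
    report = RoundReport(
        round_id=round_id,
        n_candidate_labels=n_candidates,
        n_qc_passed=len(recruited),
    )
    return recruited, report


# --------------------------------------------------------------------------
# per-view staged recipes
# --------------------------------------------------------------------------

@dataclass
class PipelineProfile:
    """Compute profile: model size, grid, and per-stage epoch caps.

    The ``tiny`` profile (64 px grid, 8 hidden units, raised learning rate)
    runs each stage in seconds on one CPU; ``full`` mirrors the standard
    profile (256 px, Adam 1e-4, batch 32).
    """

    input_size: int = 64
    hidden_width: int = 12
    learning_rate: float = 0.03
    batch_size: int = 8
    max_epochs: int = 60
    seed: int = 0
    wall_thickness_mm: float = 8.0
    endo_margin_mm: float = 1.0
    rv_length_ratio: float = 0.9
    hough_radius_range_mm: tuple[float, float] = (15.0, 45.0)
    a2c_weak_config: A2CWeakLabelConfig = field(default_factory=A2CWeakLabelConfig)
    augmentation: Optional[AugmentationPolicy] = None

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "PipelineProfile":
        # no endocardial margin on the 2 mm/px grid: a 1 mm margin rounds up
        # to a whole pixel and systematically shrinks the endo labels
        defaults = dict(seed=seed, endo_margin_mm=0.0)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def full(cls, seed: int = 0, **kw) -> "PipelineProfile":
        defaults = dict(
            input_size=256,
            hidden_width=16,
            learning_rate=1e-4,
            batch_size=32,
            max_epochs=50,
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)

    def segmenter_config(self, chambers, use_lateral=False) -> SegmenterConfig:
        return SegmenterConfig(
            chambers=tuple(chambers),
            input_size=self.input_size,
            hidden_width=self.hidden_width,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            use_lateral_feature=use_lateral,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    """Final model plus per-stage artifacts of one view's staged recipe."""

    view: View
    final_model: PixelSegmenter
    stage_models: dict[str, PixelSegmenter]
    loss_curves: dict[str, LossCurve]
    round_reports: list[RoundReport]
    stage_labels: dict[str, list[TrainingExample]]
    qc_log: list[dict] = field(default_factory=list)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, curve in self.loss_curves.items():
            curve.to_csv(out / f"loss_{name}.csv")
        with open(out / "round_reports.json", "w") as fh:
            json.dump(
                [report.__dict__ for report in self.round_reports], fh, indent=2
            )
        with open(out / "qc_log.jsonl", "w") as fh:
            for entry in self.qc_log:
                fh.write(json.dumps(entry) + "\n")
        self.final_model.save(out / "final_model")
        return out


def _gate_and_log(
    candidates: list[tuple[str, UltrasoundFrame, ChamberMaskSet]],
    qc_config: QCConfig,
    stage: str,
    qc_log: list[dict],
) -> list[TrainingExample]:
    survivors = []
    for study_id, frame, masks in candidates:
        passed, reasons = qc_gate(masks, qc_config)
        qc_log.append(
            {
                "stage": stage,
                "study_id": study_id,
                "frame_index": frame.frame_index,
                "passed": passed,
                "reasons": reasons,
            }
        )
        if passed:
            survivors.append(
                TrainingExample(study_id, frame, masks.with_provenance(Provenance.QC_PASSED))
            )
    return survivors


def _require(labels: list, stage: str) -> list:
    if not labels:
        raise StageStarvedError(f"stage {stage!r} produced zero QC-passed labels")
    return labels


def run_view_pipeline(
    view: View,
    clips: Sequence[CineClip],
    profile: Optional[PipelineProfile] = None,
    qc_config: Optional[QCConfig] = None,
    a2c_model: Optional[PixelSegmenter] = None,
    a4c_orientation: str = "LV_on_image_right",
) -> PipelineResult:
    """Run the staged self-supervised recipe for one view.

    Clips must already be standardized to the profile's grid.  The A4C
    recipe requires a trained two-chamber (A2C) model for its initial
    inference stage.
    """
    view = View(view)
    profile = profile or PipelineProfile.tiny()
    qc_config = qc_config or QCConfig.default(view)
    qc_log: list[dict] = []
    loss_curves: dict[str, LossCurve] = {}
    stage_models: dict[str, PixelSegmenter] = {}
    stage_labels: dict[str, list[TrainingExample]] = {}
    reports: list[RoundReport] = []
    seed = profile.seed

    if view is View.A2C:
        candidates = []
        for clip in clips:
            for frame in clip.frames:
                weak = a2c_weak_label(frame, profile.a2c_weak_config)
                if weak is not None:
                    candidates.append((clip.study_id, frame, weak))
        labels = _require(_gate_and_log(candidates, qc_config, "weak", qc_log), "weak")
        stage_labels["weak"] = labels
        cfg = profile.segmenter_config((Chamber.LV, Chamber.LA), use_lateral=False)
        model1, curve1, stop1 = train_early_stop(
            cfg, labels, profile.max_epochs, augmentation=profile.augmentation, seed=seed
        )
        loss_curves["train1"] = curve1
        stage_models["model1"] = model1
        recruited, report = self_learning_round(model1, clips, qc_config, round_id=1)
        report.stop_epoch = stop1
        report.final_validation_loss = float(curve1.validation_loss[stop1])
        reports.append(report)
        labels2 = _require(recruited, "self_learning")
        stage_labels["self_learning"] = labels2
        model2, curve2, stop2 = train_early_stop(
            cfg, labels2, profile.max_epochs, augmentation=profile.augmentation, seed=seed + 1
        )
        loss_curves["train2"] = curve2
        stage_models["model2"] = model2
        final = model2

    elif view is View.A4C:
        if a2c_model is None:
            raise ValueError("A4C recipe requires a trained A2C model")
        candidates = []
        for clip in clips:
            for frame in clip.frames:
                pred = predict_masks(a2c_model, frame, keep_components=2)
                try:
                    four = reassign_a4c_labels(pred, orientation=a4c_orientation)
                    stretched = stretch_rv_apex(
                        four[Chamber.RV],
                        four[Chamber.LV],
                        frame.pixel_spacing,
                        target_length_ratio=profile.rv_length_ratio,
                    )
                except (UnassignableError, DegenerateError, InvalidInputError):
                    continue
                masks = dict(four.masks)
                masks[Chamber.RV] = stretched.mask
                candidates.append(
                    (
                        clip.study_id,
                        frame,
                        ChamberMaskSet(
                            masks=masks,
                            pixel_spacing=frame.pixel_spacing,
                            provenance=Provenance.MODEL,
                            view=View.A4C,
                        ),
                    )
                )
        labels = _require(
            _gate_and_log(candidates, qc_config, "reassigned", qc_log), "reassigned"
        )
        stage_labels["reassigned"] = labels
        cfg = profile.segmenter_config(
            (Chamber.LV, Chamber.LA, Chamber.RV, Chamber.RA), use_lateral=True
        )
        model1, curve1, stop1 = train_early_stop(
            cfg, labels, profile.max_epochs, augmentation=profile.augmentation, seed=seed
        )
        loss_curves["train1"] = curve1
        stage_models["model1"] = model1
        recruited, report = self_learning_round(model1, clips, qc_config, round_id=1)
        report.stop_epoch = stop1
        report.final_validation_loss = float(curve1.validation_loss[stop1])
        reports.append(report)
        labels2 = _require(recruited, "self_learning")
        stage_labels["self_learning"] = labels2
        final, curve2, _stop2 = train_early_stop(
            cfg, labels2, profile.max_epochs, augmentation=profile.augmentation, seed=seed + 1
        )
        loss_curves["train2"] = curve2
        stage_models["model2"] = final

    elif view is View.SAX:
        # C1: Hough circle labels
        hough_candidates = []
        for clip in clips:
            for frame in clip.frames:
                hyps = hough_circle_detect(
                    frame, radius_range_mm=profile.hough_radius_range_mm, max_candidates=1
                )
                if not hyps:
                    continue
                disc = circle_to_mask(hyps[0], frame.shape)
                masks = ChamberMaskSet(
                    masks={Chamber.LV: disc},
                    pixel_spacing=frame.pixel_spacing,
                    provenance=Provenance.WEAK,
                    view=View.SAX,
                )
                hough_candidates.append((clip.study_id, frame, masks))
        hough_labels = _require(
            _gate_and_log(hough_candidates, qc_config, "hough", qc_log), "hough"
        )
        stage_labels["hough"] = hough_labels

        # C2: edge detector trained on circle outlines
        ring = skimage.morphology.disk(1)
        edge_examples = []
        for ex in hough_labels:
            lv = ex.masks[Chamber.LV]
            outline = skimage.morphology.dilation(lv, ring) & ~skimage.morphology.erosion(lv, ring)
            edge_examples.append(
                TrainingExample(
                    ex.study_id,
                    ex.frame,
                    ChamberMaskSet(
                        masks={Chamber.LV: outline},
                        pixel_spacing=ex.masks.pixel_spacing,
                        provenance=Provenance.QC_PASSED,
                        view=View.SAX,
                    ),
                )
            )
        edge_cfg = profile.segmenter_config((Chamber.LV,), use_lateral=False)
        edge_model, edge_curve, _ = train_early_stop(
            edge_cfg, edge_examples, profile.max_epochs, seed=seed
        )
        loss_curves["edge"] = edge_curve
        stage_models["edge"] = edge_model

        # C3: fill predicted edges -> first segmenter labels
        fill_candidates = []
        for clip in clips:
            for frame in clip.frames:
                proba = edge_model.predict_proba(frame.pixels)[..., 0]
                filled = edge_to_filled_mask(
                    proba, threshold=0.5, spacing=frame.pixel_spacing
                )
                if not filled.any():
                    continue
                fill_candidates.append(
                    (
                        clip.study_id,
                        frame,
                        ChamberMaskSet(
                            masks={Chamber.LV: filled},
                            pixel_spacing=frame.pixel_spacing,
                            provenance=Provenance.MODEL,
                            view=View.SAX,
                        ),
                    )
                )
        labels1 = _require(
            _gate_and_log(fill_candidates, qc_config, "edge_filled", qc_log), "edge_filled"
        )
        stage_labels["edge_filled"] = labels1
        seg_cfg = profile.segmenter_config((Chamber.LV,), use_lateral=False)
        model1, curve1, stop1 = train_early_stop(
            seg_cfg, labels1, profile.max_epochs, augmentation=profile.augmentation, seed=seed
        )
        loss_curves["train1"] = curve1
        stage_models["model1"] = model1
        recruited, report = self_learning_round(model1, clips, qc_config, round_id=1)
        report.stop_epoch = stop1
        report.final_validation_loss = float(curve1.validation_loss[stop1])
        reports.append(report)
        labels2 = _require(recruited, "self_learning")
        stage_labels["self_learning"] = labels2

        # epi/endo labels from round-2 predictions -> second segmenter
        epi_examples = []
        for ex in labels2:
            lv = ex.masks[Chamber.LV]
            try:
                epi, endo = make_epi_endo_labels(
                    lv,
                    ex.masks.pixel_spacing,
                    wall_thickness_mm=profile.wall_thickness_mm,
                    endo_margin_mm=profile.endo_margin_mm,
                )
            except Exception:
                continue
            epi_examples.append(
                TrainingExample(
                    ex.study_id,
                    ex.frame,
                    ChamberMaskSet(
                        masks={Chamber.LV: endo, Chamber.LV_EPI: epi},
                        pixel_spacing=ex.masks.pixel_spacing,
                        provenance=Provenance.QC_PASSED,
                        view=View.SAX,
                    ),
                )
            )
        epi_examples = _require(epi_examples, "epi_endo")
        stage_labels["epi_endo"] = epi_examples
        cfg2 = profile.segmenter_config((Chamber.LV, Chamber.LV_EPI), use_lateral=False)
        final, curve2, _ = train_early_stop(
            cfg2, epi_examples, profile.max_epochs, augmentation=profile.augmentation, seed=seed + 1
        )
        loss_curves["train2"] = curve2
        stage_models["model2"] = final
    else:
        raise ValueError(f"unknown view {view}")

    return PipelineResult(
        view=view,
        final_model=final,
        stage_models=stage_models,
        loss_curves=loss_curves,
        round_reports=reports,
        stage_labels=stage_labels,
        qc_log=qc_log,
    )
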