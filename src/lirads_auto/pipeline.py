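"""End-to-end orchestration: phantom -> segment -> characterize -> score ->
evaluate, plus the adaptive-learning ablation harness.

Stages hand off through files in the run directory (NIfTI volumes, npz
weights, CSV/JSON tables), so a rerun reuses whatever artifacts already
exist: delete only the downstream outputs and the cached upstream results are
loaded bit-identically.  Every source of randomness derives from the single
config seed, so an identical config reproduces identical scores.

The default configuration is desk-scale: small "easy" phantoms, a reduced
segmentation network, and a reduced characterizer, trained on one CPU in
minutes.  The segmentation stage runs on the delayed phase (the ROI-
extraction phase); a config switch widens it to all phases.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .characterization import (
    CharConfig,
    CharSample,
    CharTrainParams,
    LesionCrop,
    build_characterizer,
    crop_resize,
    predict_features,
    select_representative_slice,
    train_multitask,
)
from .evaluation import (
    EvalReport,
    confusion_and_accuracy,
    counts_from_masks,
    dice_from_counts,
    lesion_level_metrics,
    patient_level_metrics,
    pixel_metric_sweep,
)
from .losses import LossConfig
from .phantom import PHASES, PhantomSpec, generate_study
from .preprocessing import make_windows, normalize_intensity, split_folds, standardize
from .scoring import AmbiguityPolicy, infer_lirads, measure_lesion_size
from .segmentation import (
    SegModelConfig,
    TrainParams,
    binarize,
    build_model,
    extract_components,
    train_steps,
)


@dataclass
class RunConfig:
    """One pipeline run: data conditions, model sizes, training budgets."""

    out_dir: str = "runs/default"
    phantom: PhantomSpec = field(default_factory=PhantomSpec.easy)
    seg: SegModelConfig = field(
        default_factory=lambda: SegModelConfig(
            n_down=2, n_up=2, base_width=8, attention=True, input_size=(64, 64)
        )
    )
    char: CharConfig = field(default_factory=CharConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    seg_train: TrainParams = field(default_factory=lambda: TrainParams(steps=500, lr=2e-3))
    char_train: CharTrainParams = field(default_factory=CharTrainParams)
    n_folds: int = 4
    test_fold: int = 0
    threshold: float = 0.5
    call_threshold: float = 0.5
    min_component_voxels: int = 5
    policy: AmbiguityPolicy = AmbiguityPolicy.PREFER_WASHOUT_RULE
    segmentation_phase: str = "delayed"
    seed: int = 0

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, AmbiguityPolicy):
                return o.value
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)


def _preprocess_study(study, phase: str):
    vol = standardize(normalize_intensity(study.phases[phase]).voxels)
    wins = make_windows(vol, study.mask)
    x = np.stack([w.slices for w in wins])
    y = np.stack([w.label_slice for w in wins]).astype(float)
    return x, y


def _phase_crops(study, comp_mask: np.ndarray, lesion_id: str, crop_size: int):
    """One standardized crop per phase from a 3-D component mask."""
    rep = select_representative_slice(comp_mask)
    crops = []
    for ph in PHASES:
        vol = standardize(normalize_intensity(study.phases[ph]).voxels)
        img = crop_resize(vol[rep], comp_mask[rep], out_size=crop_size)
        crops.append(
            LesionCrop(image=img, phase_indicator=0 if ph == "arterial" else 1,
                       lesion_id=lesion_id, source_phase=ph)
        )
    return crops


def _gt_components(study, lesions):
    """Labelled ground-truth mask and {lesion_id: component label}."""
    labelled, kept = extract_components(study.mask, min_voxels=1)
    mapping = {}
    for les in lesions:
        lab = int(labelled[les.center_voxel])
        if lab == 0:  # centre rounding landed outside; take nearest component
            zz, yy, xx = np.nonzero(labelled)
            d = (zz - les.center_voxel[0]) ** 2 + (yy - les.center_voxel[1]) ** 2 + (xx - les.center_voxel[2]) ** 2
            lab = int(labelled[zz[d.argmin()], yy[d.argmin()], xx[d.argmin()]])
        mapping[les.lesion_id] = lab
    return labelled, mapping


def build_char_training_samples(studies, lesions_by_pid, crop_size: int,
                                adaptive: bool = True) -> list[CharSample]:
    """Characterizer training set from ground-truth masks and feature flags.

    Adaptive samples carry only the labels their phase can supervise; the
    non-adaptive arm attaches all three labels to every crop, including the
    ones the phase cannot show.
    """
    samples: list[CharSample] = []
    for pid, study in studies.items():
        lesions = lesions_by_pid[pid]
        if not lesions:
            continue
        labelled, mapping = _gt_components(study, lesions)
        for les in lesions:
            comp = labelled == mapping[les.lesion_id]
            crops = _phase_crops(study, comp, les.lesion_id, crop_size)
            flags = {"aphe": int(les.B1), "washout": int(les.B2), "capsule": int(les.B3)}
            for crop in crops:
                if adaptive:
                    labels = (
                        {"aphe": flags["aphe"]}
                        if crop.phase_indicator == 0
                        else {"washout": flags["washout"], "capsule": flags["capsule"]}
                    )
                else:
                    labels = dict(flags)
                samples.append(CharSample(image=crop.image, x=crop.phase_indicator, labels=labels))
    return samples


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return paths plus the in-memory results.

    Returns a dict with the scores table ("scores"), the evaluation report
    ("report"), per-patient DICE ("dice"), and artifact paths.  Each stage
    persists its artifacts and reuses them when already present.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    t0 = time.time()

    # -- stage 1: phantom data (in memory, deterministic per seed) ----------
    studies, lesions_by_pid = {}, {}
    for i in range(config.phantom.n_patients):
        study, lesions = generate_study(config.phantom, i)
        studies[study.patient_id] = study
        lesions_by_pid[study.patient_id] = lesions
    pids = sorted(studies)
    timings["phantom_s"] = round(time.time() - t0, 2)

    split = split_folds(pids, n_folds=config.n_folds, seed=config.seed)
    train_pids, test_pids = split.train_test(config.test_fold)

    # -- stage 2: segmentation training (cached as npz weights) -------------
    t0 = time.time()
    seg_model = build_model(config.seg)
    seg_path = out / "seg_model.npz"
    if seg_path.exists():
        seg_model.load(seg_path)
    else:
        xs, ys = [], []
        for pid in train_pids:
            x, y = _preprocess_study(studies[pid], config.segmentation_phase)
            xs.append(x)
            ys.append(y)
        train_steps(seg_model, np.concatenate(xs), np.concatenate(ys),
                    config.loss, config.seg_train)
        seg_model.save(seg_path)
    timings["segmentation_train_s"] = round(time.time() - t0, 2)

    # -- stage 3: characterizer training (ground-truth crops) ---------------
    t0 = time.time()
    char_model = build_characterizer(config.char)
    char_path = out / "char_model.npz"
    if char_path.exists():
        char_model.load(char_path)
    else:
        samples = build_char_training_samples(
            {p: studies[p] for p in train_pids},
            lesions_by_pid,
            config.char.input_size,
        )
        if samples:  # a lesion-free training set leaves the characterizer untrained
            train_multitask(char_model, samples, config.char_train, adaptive=True)
        char_model.save(char_path)
    timings["characterizer_train_s"] = round(time.time() - t0, 2)

    # -- stage 4: prediction + scoring on held-out patients ------------------
    t0 = time.time()
    import pandas as pd

    from .segmentation import predict_volume

    rows = []
    prob_by_pid = {}
    dice_by_pid = {}
    per_patient_counts = []
    detection_pairs = []
    matched_pairs = []  # (true category, predicted category) per matched lesion
    for pid in test_pids:
        study = studies[pid]
        prob = predict_volume(seg_model, study, config.segmentation_phase)
        prob_by_pid[pid] = prob
        mask = binarize(prob, config.threshold)
        labelled, kept = extract_components(mask, min_voxels=config.min_component_voxels)
        gt_labelled, gt_map = (
            _gt_components(study, lesions_by_pid[pid])
            if lesions_by_pid[pid]
            else (np.zeros_like(study.mask, dtype=int), {})
        )
        counts = counts_from_masks(labelled > 0, study.mask > 0)
        per_patient_counts.append(counts)
        # empty-vs-empty patient (no lesion, none predicted) counts as 1
        empty_both = (2 * counts.TP + counts.FP + counts.FN) == 0
        dice_by_pid[pid] = 1.0 if empty_both else dice_from_counts(counts)
        det = lesion_level_metrics(labelled, gt_labelled)
        detection_pairs.append((det, bool(lesions_by_pid[pid])))

        gt_by_label = {v: k for k, v in gt_map.items()}
        truth_by_id = {l.lesion_id: l for l in lesions_by_pid[pid]}
        for lab in kept:
            comp = labelled == lab
            size = measure_lesion_size(comp, study.spacing_mm)
            crops = _phase_crops(study, comp, f"{pid}_C{lab}", config.char.input_size)
            prof = predict_features(char_model, crops, size_mm=size,
                                    call_threshold=config.call_threshold)
            cat = infer_lirads(prof.B1, prof.B2, prof.B3, size, config.policy)
            overlap = np.bincount(gt_labelled[comp].ravel())
            gt_lab = int(overlap[1:].argmax()) + 1 if len(overlap) > 1 and overlap[1:].max() > 0 else 0
            matched_id = gt_by_label.get(gt_lab, "")
            rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": prof.lesion_id,
                    "matched_truth": matched_id,
                    "B1": int(prof.B1), "B2": int(prof.B2), "B3": int(prof.B3),
                    "p_aphe": round(prof.p_aphe, 4),
                    "p_washout": round(prof.p_washout, 4),
                    "p_capsule": round(prof.p_capsule, 4),
                    "size_mm": round(size, 2),
                    "category": cat.value.value,
                    "resolved": cat.resolved_value.value,
                }
            )
            if matched_id:
                truth = truth_by_id[matched_id]
                matched_pairs.append(
                    (truth.label.resolved_value.value, cat.resolved_value.value)
                )
    timings["predict_score_s"] = round(time.time() - t0, 2)

    scores = pd.DataFrame(
        rows,
        columns=["patient_id", "lesion_id", "matched_truth", "B1", "B2", "B3",
                 "p_aphe", "p_washout", "p_capsule", "size_mm", "category", "resolved"],
    )
    scores.to_csv(out / "scores.csv", index=False)

    # -- stage 5: evaluation --------------------------------------------------
    sweep = pixel_metric_sweep(
        [prob_by_pid[p] for p in test_pids],
        [studies[p].mask for p in test_pids],
        thresholds=np.round(np.arange(0.2, 0.81, 0.1), 2),
    )
    lesion_det = _pool_detections(detection_pairs)
    patient_det = patient_level_metrics(detection_pairs)
    confusion, accuracy = None, None
    if matched_pairs:
        confusion, accuracy, _ = confusion_and_accuracy(
            [p for _, p in matched_pairs], [t for t, _ in matched_pairs]
        )
    report = EvalReport(
        threshold_table=sweep,
        per_patient_dice=dice_by_pid,
        lesion_detection=lesion_det,
        patient_detection=patient_det,
        confusion=confusion,
        accuracy=accuracy,
    )
    (out / "eval_report.json").write_text(json.dumps(report.to_dict(), indent=2))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "timings": timings,
        "n_train_patients": len(train_pids),
        "n_test_patients": len(test_pids),
        "n_scored_lesions": len(scores),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "scores": scores,
        "report": report,
        "dice": dice_by_pid,
        "matched_pairs": matched_pairs,
        "out_dir": str(out),
    }


def _pool_detections(pairs):
    """Pool per-patient lesion-level results into one DetectionResult."""
    from .evaluation import DetectionResult

    tp = sum(r.TP for r, _ in pairs)
    fp = sum(r.FP for r, _ in pairs)
    fn = sum(r.FN for r, _ in pairs)
    n_pred = tp + fp
    n_true = tp + fn
    return DetectionResult(
        TP=tp, FP=fp, FN=fn,
        precision=tp / n_pred if n_pred else 1.0,
        recall=tp / n_true if n_true else 0.0,
        degenerate_precision=n_pred == 0,
    )


def run_ablation(config: RunConfig, variants=None) -> "pandas.DataFrame":
    """Train characterizer variants on one split and compare accuracies.

    Variants default to adaptive on/off at the configured backbone.  Each
    variant trains on identical ground-truth crops (same seed and split) and
    is evaluated on the held-out patients' ground-truth lesions: per-feature
    accuracy, their macro average, and LI-RADS accuracy from ground-truth
    sizes (isolating characterization from segmentation error).
    """
    import pandas as pd

    if variants is None:
        variants = [
            {"name": "adaptive", "adaptive": True},
            {"name": "non_adaptive", "adaptive": False},
        ]
    studies, lesions_by_pid = {}, {}
    for i in range(config.phantom.n_patients):
        study, lesions = generate_study(config.phantom, i)
        studies[study.patient_id] = study
        lesions_by_pid[study.patient_id] = lesions
    pids = sorted(studies)
    split = split_folds(pids, n_folds=config.n_folds, seed=config.seed)
    train_pids, test_pids = split.train_test(config.test_fold)

    rows = []
    for var in variants:
        char_cfg = var.get("char", config.char)
        model = build_characterizer(char_cfg)
        samples = build_char_training_samples(
            {p: studies[p] for p in train_pids}, lesions_by_pid,
            char_cfg.input_size, adaptive=var["adaptive"],
        )
        train_multitask(model, samples, config.char_train, adaptive=var["adaptive"])

        correct = {"aphe": 0, "washout": 0, "capsule": 0}
        n = 0
        cat_true, cat_pred = [], []
        for pid in test_pids:
            lesions = lesions_by_pid[pid]
            if not lesions:
                continue
            labelled, mapping = _gt_components(studies[pid], lesions)
            for les in lesions:
                comp = labelled == mapping[les.lesion_id]
                crops = _phase_crops(studies[pid], comp, les.lesion_id, char_cfg.input_size)
                prof = predict_features(model, crops, size_mm=les.diameter_mm,
                                        call_threshold=config.call_threshold)
                n += 1
                correct["aphe"] += int(prof.B1 == les.B1)
                correct["washout"] += int(prof.B2 == les.B2)
                correct["capsule"] += int(prof.B3 == les.B3)
                cat = infer_lirads(prof.B1, prof.B2, prof.B3, les.diameter_mm, config.policy)
                cat_pred.append(cat.resolved_value.value)
                cat_true.append(les.label.resolved_value.value)
        acc = {k: v / n for k, v in correct.items()} if n else {k: float("nan") for k in correct}
        _, lirads_acc, _ = confusion_and_accuracy(cat_pred, cat_true)
        rows.append(
            {
                "variant": var["name"],
                "adaptive": var["adaptive"],
                "n_lesions": n,
                "acc_aphe": acc["aphe"],
                "acc_washout": acc["washout"],
                "acc_capsule": acc["capsule"],
                "macro_accuracy": float(np.mean(list(acc.values()))),
                "lirads_accuracy": lirads_acc,
            }
        )
    table = pd.DataFrame(rows)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "ablation.csv", index=False)
    return table
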