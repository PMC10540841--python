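"""End-to-end orchestration: align -> crop -> segment -> HOG -> PCA -> SVM.

Two entry points:

* :func:`run_synthetic_experiment` renders a synthetic cohort in memory and
  pushes it through the full feature/classification pipeline (optionally
  bypassing the U-net with ground-truth masks).  This is the workhorse for
  signal-recovery experiments.
* :func:`run_pipeline` is the disk-based variant behind the CLI: it consumes
  a cohort directory (metadata CSV + PNGs), writes every intermediate
  artifact under an output directory and records a manifest of content
  hashes so reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nfio
from .classifier import SvmConfig, confusion, label_from_score, metrics, predict, train_svm
from .features import apply_mask, extract_hog_features, fit_pca, fit_standardizer
from .geometry import align, crop, crop_transform_mask
from .hog import HogParams
from .segmentation import SegTrainConfig, predict_mask, split_dataset, train_seg
from .stats import subgroup_report
from .synthetic import CohortSpec, records_from_metadata, render_face, sample_subject

logger = logging.getLogger("nutriface")

__all__ = [
    "PipelineConfig",
    "derive_seed",
    "prepare_sample",
    "run_synthetic_experiment",
    "run_pipeline",
]


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from one master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    metadata: Path
    out_dir: Path
    seg: SegTrainConfig = field(default_factory=SegTrainConfig)
    hog: HogParams = field(default_factory=HogParams)
    svm: SvmConfig = field(default_factory=SvmConfig)
    pca_k: int = 100
    use_true_masks: bool = False
    seed: int = 0
    log_level: str = "INFO"


def prepare_sample(image: np.ndarray, landmarks: np.ndarray, mask: np.ndarray):
    """Align and crop one face, carrying its mask through the same transforms.

    Returns ``(face300, landmarks300, mask300)`` in the canonical 300x300
    frame; the mask stays strictly {0,255}.
    """
    img_a, lm_a = align(image, landmarks)
    mask_a = align((np.asarray(mask) > 0).astype(np.float64), landmarks)[0]
    mask_a = np.where(mask_a >= 0.5, 255, 0).astype(np.uint8)
    face = crop(img_a, lm_a)
    mask_c = crop_transform_mask(mask_a, lm_a)
    return face.image, face.landmarks, mask_c


def _features_and_svm(train_rois, test_rois, train_labels, hog_params,
                      pca_k, svm_config):
    x_train = extract_hog_features(train_rois, hog_params)
    x_test = extract_hog_features(test_rois, hog_params)
    scaler = fit_standardizer(x_train)
    z_train = scaler.transform(x_train)
    z_test = scaler.transform(x_test)
    k = min(pca_k, *z_train.shape)
    pca = fit_pca(z_train, k=k, seed=svm_config.seed)
    f_train = pca.reduce(z_train)
    f_test = pca.reduce(z_test)
    model = train_svm(f_train, train_labels, svm_config)
    return model, f_train, f_test, scaler, pca


def run_synthetic_experiment(
    spec: CohortSpec,
    train_fraction: float = 381 / 515,
    use_true_masks: bool = True,
    seg_config: SegTrainConfig | None = None,
    hog_params: HogParams = HogParams(),
    pca_k: int = 100,
    svm_config: SvmConfig | None = None,
) -> dict:
    """Render a cohort in memory and classify it end to end.

    With ``use_true_masks`` the segmentation stage is bypassed and the
    ground-truth fat-pad masks (carried through the same geometric
    transforms) feed the feature extractor; otherwise a U-net is trained on
    the training split first.  Returns a dict with confusion counts, the
    four classification metrics and the three subgroup reports.
    """
    svm_config = svm_config or SvmConfig(seed=derive_seed(spec.seed, "svm"))
    subjects = [sample_subject(spec, i) for i in range(spec.n_subjects)]
    prepared = []
    for p in subjects:
        img, lm, mask = render_face(p, spec.canvas_size)
        face300, _, mask300 = prepare_sample(img, lm, mask)
        prepared.append((p, face300, mask300))

    idx = np.arange(spec.n_subjects)
    train_idx, test_idx = split_dataset(
        list(idx), fraction=train_fraction, seed=derive_seed(spec.seed, "split")
    )

    if use_true_masks:
        masks = {i: prepared[i][2] for i in idx}
    else:
        cfg = seg_config or SegTrainConfig(seed=derive_seed(spec.seed, "seg"))
        pairs = [(prepared[i][1], prepared[i][2]) for i in train_idx]
        seg_model, _ = train_seg(pairs, cfg)
        masks = {
            i: predict_mask(seg_model, prepared[i][1], cfg.threshold) for i in idx
        }

    rois = {i: apply_mask(prepared[i][1], masks[i]) for i in idx}
    labels = label_from_score([prepared[i][0].nrs_score for i in idx])
    model, f_train, f_test, _, _ = _features_and_svm(
        [rois[i] for i in train_idx],
        [rois[i] for i in test_idx],
        labels[train_idx],
        hog_params,
        pca_k,
        svm_config,
    )
    pred = predict(model, f_test)
    counts = confusion(labels[test_idx], pred)
    test_subjects = [prepared[i][0] for i in test_idx]
    reports = {
        attr: subgroup_report(test_subjects, pred, attr)
        for attr in ("age_group", "gender", "site")
    }
    return {
        "confusion": counts,
        "metrics": metrics(counts),
        "subgroups": reports,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Disk-based full run; every artifact lands under ``config.out_dir``.

    Stages: load cohort -> align/crop (writes aligned faces + transformed
    ground-truth masks) -> segmentation (trained, or bypassed with the true
    masks) -> ROI merge -> HOG -> standardize -> PCA -> SVM -> metrics and
    subgroup reports -> manifest with a content hash per output file.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    (out / "aligned").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    records = records_from_metadata(config.metadata)
    prepared = {}
    for rec in records:
        try:
            image = nfio.load_image(rec.image_path)
            mask = nfio.load_mask(rec.mask_path)
            face300, lm300, mask300 = prepare_sample(image, rec.landmarks, mask)
        except Exception as exc:  # noqa: BLE001 - abort naming the sample
            raise RuntimeError(
                f"stage=preprocess sample={rec.sample_id}: {exc}"
            ) from exc
        nfio.save_image(out / "aligned" / f"{rec.sample_id}.png", face300)
        prepared[rec.sample_id] = (face300, mask300)
        logger.debug("aligned %s", rec.sample_id)

    train_recs = [r for r in records if r.split == "train"]
    test_recs = [r for r in records if r.split == "test"]
    if not train_recs or not test_recs:
        raise RuntimeError("stage=split: cohort metadata lacks a train or test split")

    if config.use_true_masks:
        final_masks = {sid: m for sid, (_, m) in prepared.items()}
        seg_summary = {"bypassed": True}
    else:
        pairs = [
            (prepared[r.sample_id][0], prepared[r.sample_id][1]) for r in train_recs
        ]
        seg_model, history = train_seg(pairs, config.seg)
        seg_model.save(out / "seg_model.npz")
        final_masks = {
            sid: predict_mask(seg_model, face, config.seg.threshold)
            for sid, (face, _) in prepared.items()
        }
        seg_summary = {
            "bypassed": False,
            "epochs": config.seg.epochs,
            "final_loss": history[-1]["loss"],
        }
    for sid, m in final_masks.items():
        nfio.save_mask(out / "masks" / f"{sid}.png", m)

    rois = {
        sid: apply_mask(face, final_masks[sid])
        for sid, (face, _) in prepared.items()
    }
    labels_train = label_from_score([r.nrs_score for r in train_recs])
    labels_test = label_from_score([r.nrs_score for r in test_recs])
    model, f_train, f_test, _, _ = _features_and_svm(
        [rois[r.sample_id] for r in train_recs],
        [rois[r.sample_id] for r in test_recs],
        labels_train,
        config.hog,
        config.pca_k,
        config.svm,
    )
    pred = predict(model, f_test)
    counts = confusion(labels_test, pred)
    report = {
        "seed": config.seed,
        "n_train": len(train_recs),
        "n_test": len(test_recs),
        "segmentation": seg_summary,
        "confusion": {
            "TP": counts.tp, "TN": counts.tn, "FP": counts.fp, "FN": counts.fn
        },
        "metrics": {
            k: (None if v != v else v) for k, v in metrics(counts).items()
        },
        "subgroups": {
            attr: subgroup_report(test_recs, pred, attr)
            for attr in ("age_group", "gender", "site")
        },
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))

    manifest = {
        "seed": config.seed,
        "metadata": str(config.metadata),
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
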