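"""End-to-end pipeline: generate -> train -> identify -> evaluate.

Orchestrates the four stages over a shared on-disk layout (database CSV,
rendered PNGs + JSON annotations, model checkpoints, metrics files) with one
global seed propagated to every module.  Evaluation supports the two
ablations the system's design motivates: dropping the imprint-correction
model (score the raw detector string instead) and dropping individual score
terms (shape/color/form/imprint).

The default evaluation splits train and test by pill species: test pills are
never seen during training, which is exactly the regime a retrieval system —
unlike a per-class classifier — can handle, because new pills only need a
database row, not a retrained model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import retrieval
from ._vocab import SEPARATOR
from .feature_recognition import (FeatureModel, FeatureModelConfig,
                                  predict_features, train_features)
from .imprint_correction import (CorrectionPair, CorrectorConfig,
                                 CorrectorModel, correct_imprint,
                                 sort_detections, train_corrector)
from .imprint_detection import (CharDetection, DetectorConfig, DetectorModel,
                                detect_characters, normalize_orientation,
                                train_detector)
from .synthetic_data import (NoiseConfig, PillRecord, corrupt_detections,
                             generate_database, load_annotations,
                             load_database, load_image, render_pill,
                             save_annotations, save_database, save_image)

logger = logging.getLogger(__name__)

_ABLATIONS = ("corrector", "shape", "color", "form", "imprint")


@dataclass
class PipelineConfig:
    """Paths, per-module configs and global knobs for one pipeline run."""

    workdir: str = "pillid_run"
    n_pills: int = 240
    image_size: int = 96
    train_fraction: float = 0.5
    corruptions_per_pill: int = 8
    seed: int = 0
    desk_scale: bool = True
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    features: FeatureModelConfig = field(default_factory=FeatureModelConfig)
    corrector: CorrectorConfig = field(default_factory=CorrectorConfig)
    noise: NoiseConfig = field(default_factory=lambda: NoiseConfig(
        confusion_rate=0.3, drop_rate=0.05, coord_jitter_sd=0.01, shuffle=True))

    def __post_init__(self):
        if self.desk_scale:
            # compact models and fewer epochs: minutes on one CPU core
            self.corrector.embedding_size = min(self.corrector.embedding_size, 32)
            self.corrector.hidden_size = min(self.corrector.hidden_size, 64)
            self.corrector.epochs = min(self.corrector.epochs, 40)
            self.corrector.learning_rate = max(self.corrector.learning_rate, 2e-3)
            self.detector.epochs = min(self.detector.epochs, 30)
            self.features.epochs = min(self.features.epochs, 40)

    # -- paths -------------------------------------------------------------

    @property
    def root(self) -> Path:
        return Path(self.workdir)

    @property
    def database_csv(self) -> Path:
        return self.root / "database.csv"

    @property
    def image_dir(self) -> Path:
        return self.root / "images"

    @property
    def checkpoint_dir(self) -> Path:
        return self.root / "checkpoints"

    @property
    def output_dir(self) -> Path:
        return self.root / "outputs"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = {"detector": DetectorConfig, "features": FeatureModelConfig,
               "corrector": CorrectorConfig, "noise": NoiseConfig}
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                if key == "features" and "loss_weights" in value:
                    value["loss_weights"] = tuple(value["loss_weights"])
                if key == "noise" and "confusion_pairs" in value:
                    value["confusion_pairs"] = tuple(
                        tuple(p) for p in value["confusion_pairs"])
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# --------------------------------------------------------------------------
# Stage: generate
# --------------------------------------------------------------------------


def run_generate(config: PipelineConfig) -> list[PillRecord]:
    """Generate the database and render one annotated image per pill."""
    config.image_dir.mkdir(parents=True, exist_ok=True)
    records = generate_database(config.n_pills, seed=config.seed)
    save_database(records, config.database_csv)
    for i, rec in enumerate(records):
        image, boxes = render_pill(rec, config.image_size,
                                   seed=config.seed * 100003 + i)
        save_image(image, config.image_dir / f"{rec.pill_id}.png")
        save_annotations(boxes, config.image_dir / f"{rec.pill_id}.json")
    logger.info("generated %d pills under %s", len(records), config.root)
    return records


def _load_dataset(config: PipelineConfig):
    records = load_database(config.database_csv)
    images, annotations = [], []
    for rec in records:
        images.append(load_image(config.image_dir / f"{rec.pill_id}.png"))
        annotations.append(load_annotations(config.image_dir / f"{rec.pill_id}.json"))
    return records, images, annotations


def _species_split(records, config: PipelineConfig):
    """Split by pill species: indices for training vs held-out pills."""
    rng = np.random.default_rng(config.seed + 17)
    order = rng.permutation(len(records))
    n_train = max(1, int(round(config.train_fraction * len(records))))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


# --------------------------------------------------------------------------
# Stage: train
# --------------------------------------------------------------------------


def run_train(config: PipelineConfig) -> dict[str, object]:
    """Train detector, feature classifier and corrector; save checkpoints.

    The detector and feature model train on the training species only.  The
    corrector trains on noisy copies of the *database* imprints (the full
    inventory), which mirrors fitting the character language model to the
    pill database the system retrieves from.
    """
    records, images, annotations = _load_dataset(config)
    train_idx, _ = _species_split(records, config)
    config.checkpoint_dir.mkdir(parents=True, exist_ok=True)

    tr_imgs = [images[i] for i in train_idx]
    detector = train_detector(tr_imgs, [annotations[i] for i in train_idx],
                              config.detector)
    detector.save(config.checkpoint_dir / "detector.npz")

    features = train_features(tr_imgs,
                              [records[i].features for i in train_idx],
                              config.features, oversample=True)
    features.save(config.checkpoint_dir / "features.npz")

    pairs, context = [], []
    for i, rec in enumerate(records):
        for d in range(config.corruptions_per_pill):
            noise = dataclasses.replace(
                config.noise, seed=config.seed + i * 1009 + d)
            dets = corrupt_detections(annotations[i], noise)
            pairs.append(CorrectionPair(source=tuple(dets), target=rec.imprint))
            context.append(rec.features)
    corrector = train_corrector(
        pairs,
        feature_context=context if config.corrector.context_mode == "features" else None,
        config=config.corrector)
    corrector.save(config.checkpoint_dir / "corrector.npz")
    return {"detector": detector, "features": features, "corrector": corrector}


def load_models(config: PipelineConfig) -> dict[str, object]:
    models = {}
    for name, cls in (("detector", DetectorModel), ("features", FeatureModel),
                      ("corrector", CorrectorModel)):
        path = config.checkpoint_dir / f"{name}.npz"
        if not path.exists():
            raise FileNotFoundError(
                f"missing checkpoint for stage '{name}': {path} — run "
                f"`pillid train` first")
        models[name] = cls.load(path)
    return models


# --------------------------------------------------------------------------
# Stage: identify
# --------------------------------------------------------------------------


def detections_to_string(detections: list[CharDetection]) -> str:
    """Raw detector string (the without-correction baseline): reading-order
    characters with "_" between the front (left) and back (right) halves."""
    s = sort_detections(detections)
    front = "".join(d.char for d in s if d.x < 0.5)
    back = "".join(d.char for d in s if d.x >= 0.5)
    return front + SEPARATOR + back


def identify(
    models: dict[str, object],
    database: list[PillRecord],
    image: np.ndarray,
    top_k: int = 3,
    ablate: set[str] | None = None,
    detections: list[CharDetection] | None = None,
) -> dict[str, object]:
    """Run the recognition + retrieval pipeline on one composite image.

    Stages: per-face orientation normalization -> character detection ->
    feature prediction -> imprint correction -> similarity ranking.
    ``detections`` overrides the detector output (used to evaluate on
    simulated detector noise).  Returns a JSON-serializable result.
    """
    ablate = set(ablate or ())
    unknown = ablate - set(_ABLATIONS)
    if unknown:
        raise ValueError(f"unknown ablation(s) {sorted(unknown)}; "
                         f"choose from {_ABLATIONS}")
    s = image.shape[0]
    halves = []
    for half in (image[:, :s], image[:, s:2 * s]):
        try:
            norm, _ = normalize_orientation(half)
        except ValueError:
            norm = half
        halves.append(norm)
    image = np.hstack(halves)

    if detections is None:
        detections = detect_characters(models["detector"], image)
    pred = predict_features(models["features"], image)
    raw = detections_to_string(detections)
    if "corrector" in ablate:
        imprint = raw
    else:
        imprint = correct_imprint(
            models["corrector"], detections,
            features=pred.labels)
    ranked = retrieval.rank_database(pred.labels, imprint, database, k=top_k,
                                     ablate=ablate & {"shape", "color", "form", "imprint"})
    return {
        "features": {"shape": pred.shape_label, "color": pred.color_label,
                     "form": pred.form_label},
        "raw_detection": raw,
        "imprint": imprint,
        "low_confidence": len(detections) == 0,
        "candidates": [
            {"pill_id": c.pill_id, "rank": c.rank,
             "total": float(c.breakdown.total), "terms": c.breakdown.as_dict()}
            for c in ranked
        ],
    }


def run_identify(config: PipelineConfig, image_path: str | Path,
                 top_k: int = 3, ablate: set[str] | None = None) -> dict[str, object]:
    models = load_models(config)
    database = load_database(config.database_csv)
    image = load_image(image_path)
    result = identify(models, database, image, top_k=top_k, ablate=ablate)
    result["image"] = str(image_path)
    return result


# --------------------------------------------------------------------------
# Stage: evaluate
# --------------------------------------------------------------------------


def run_evaluate(
    config: PipelineConfig,
    models: dict[str, object] | None = None,
    ablate: set[str] | None = None,
    unseen_split: bool = True,
    top_k: int = 3,
) -> dict[str, object]:
    """Identify every evaluation pill against the full database.

    With ``unseen_split`` (default) only held-out species are queried,
    mirroring identification of pills never seen in training.  Writes
    metrics JSON and a per-query CSV under the output directory and returns
    the metrics.
    """
    models = models or load_models(config)
    records, images, _ = _load_dataset(config)
    _, test_idx = _species_split(records, config)
    query_idx = test_idx if unseen_split else np.arange(len(records))
    if len(query_idx) == 0:
        raise ValueError("empty evaluation manifest")

    ranked_lists, rows = [], []
    for i in query_idx:
        result = identify(models, records, images[i], top_k=top_k,
                          ablate=ablate)
        cands = result["candidates"]
        ranked_lists.append([
            retrieval.RankedCandidate(
                pill_id=c["pill_id"],
                breakdown=None, rank=c["rank"])  # type: ignore[arg-type]
            for c in cands])
        top = cands[0]
        rows.append({
            "query_id": records[i].pill_id, "truth_imprint": records[i].imprint,
            "pred_imprint": result["imprint"], "top1_id": top["pill_id"],
            "top1_total": top["total"],
            "hit1": top["pill_id"] == records[i].pill_id,
        })
    truth = [records[i].pill_id for i in query_idx]
    acc = retrieval.evaluate_topk(ranked_lists, truth, ks=(1, 3))
    metrics = {"top1": acc[1], "top3": acc[3], "n_queries": len(query_idx),
               "ablate": sorted(ablate) if ablate else []}

    config.output_dir.mkdir(parents=True, exist_ok=True)
    tag = "_".join(sorted(ablate)) if ablate else "full"
    (config.output_dir / f"metrics_{tag}.json").write_text(json.dumps(metrics, indent=2))
    import pandas as pd
    pd.DataFrame(rows).to_csv(config.output_dir / f"queries_{tag}.csv", index=False)
    return metrics
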