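"""Shared fixtures: one synthetic study dataset and session-scoped trained
models, so the expensive trainings run once for the whole suite.

Study conditions (fixed once): 460 pills with NLM-like marginals, 96 px
faces, species split 400 train / 60 held out; detector-noise benchmark at
confusion 0.3, drop 0.05, coordinate jitter 0.01, shuffle on.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pillid import synthetic_data as sd
from pillid.feature_recognition import FeatureModelConfig, train_features
from pillid.imprint_correction import (CorrectionPair, CorrectorConfig,
                                       train_corrector)
from pillid.imprint_detection import DetectorConfig, train_detector

N_PILLS = 460
N_TRAIN = 400
IMAGE_SIZE = 96
DB_SEED = 101
RENDER_SEED = 500

BENCH_NOISE = sd.NoiseConfig(confusion_rate=0.3, drop_rate=0.05,
                             coord_jitter_sd=0.01, shuffle=True)


@pytest.fixture(scope="session")
def dataset():
    """Database + rendered images + ground-truth boxes, split by species."""
    db = sd.generate_database(N_PILLS, seed=DB_SEED)
    images, boxes = [], []
    for i, rec in enumerate(db):
        img, bxs = sd.render_pill(rec, IMAGE_SIZE, seed=RENDER_SEED + i)
        images.append(img)
        boxes.append(bxs)
    return {
        "db": db, "images": images, "boxes": boxes,
        "train": np.arange(N_TRAIN), "test": np.arange(N_TRAIN, N_PILLS),
    }


@pytest.fixture(scope="session")
def detector_model(dataset):
    cfg = DetectorConfig(epochs=80, hidden_dim=160, seed=0)
    tr = dataset["train"]
    return train_detector([dataset["images"][i] for i in tr],
                          [dataset["boxes"][i] for i in tr], cfg)


@pytest.fixture(scope="session")
def feature_model(dataset):
    cfg = FeatureModelConfig(epochs=40, seed=0)
    tr = dataset["train"]
    return train_features([dataset["images"][i] for i in tr],
                          [dataset["db"][i].features for i in tr], cfg)


def corruption_pairs(dataset, noise, indices, n_draws, seed0):
    """Corruption benchmark pairs for the given pills, deterministic."""
    pairs, recs = [], []
    for i in indices:
        rec = dataset["db"][i]
        for d in range(n_draws):
            cfg = dataclasses.replace(noise, seed=seed0 + int(i) * 1009 + d)
            dets = sd.corrupt_detections(dataset["boxes"][i], cfg)
            pairs.append(CorrectionPair(source=tuple(dets), target=rec.imprint))
            recs.append(rec)
    return pairs, recs


@pytest.fixture(scope="session")
def corrector_model(dataset):
    """Main corrector: trained on drop/confusion/shuffle corruptions of the
    full database inventory (the deployment regime: the lexicon is known)."""
    pairs, _ = corruption_pairs(dataset, BENCH_NOISE,
                                range(N_PILLS), n_draws=6, seed0=0)
    cfg = CorrectorConfig(embedding_size=32, hidden_size=64, epochs=40,
                          batch_size=50, learning_rate=2e-3, seed=0)
    return train_corrector(pairs, config=cfg)


@pytest.fixture(scope="session")
def models(detector_model, feature_model, corrector_model):
    return {"detector": detector_model, "features": feature_model,
            "corrector": corrector_model}
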