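"""Imprint correction: coordinate encoding, seq2seq training, decoding."""

import numpy as np
import pytest

from pillid import synthetic_data as sd
from pillid._vocab import SEPARATOR, VOCAB_TOKENS
from pillid.imprint_correction import (CorrectionPair, CorrectorConfig,
                                       CorrectorModel, EncodedChar,
                                       correct_imprint, encode_sequence,
                                       sort_detections, train_corrector)
from pillid.imprint_detection import CharDetection


class TestEncodeSequence:
    def test_empty(self):
        assert encode_sequence([]) == []

    def test_single_detection_layout(self):
        (enc,) = encode_sequence([CharDetection("M", 0.2, 0.5, 0.9)])
        v = enc.vector
        assert v.shape == (len(VOCAB_TOKENS) + 2,)
        assert v[VOCAB_TOKENS.index("M")] == 1.0
        assert v[:len(VOCAB_TOKENS)].sum() == 1.0
        assert (v[-2], v[-1]) == (np.float32(0.2), np.float32(0.5))

    def test_roundtrip_over_whole_vocabulary(self):
        dets = [CharDetection(t, 0.5, 0.5, 1.0) for t in VOCAB_TOKENS]
        for det, enc in zip(dets, encode_sequence(dets)):
            onehot = enc.vector[:len(VOCAB_TOKENS)]
            assert VOCAB_TOKENS[int(onehot.argmax())] == det.char

    def test_out_of_vocabulary_named_in_error(self):
        with pytest.raises(ValueError, match="'b'"):
            encode_sequence([CharDetection("b", 0.1, 0.1, 0.5)])

    def test_order_preserved(self):
        dets = [CharDetection("A", 0.9, 0.9, 1.0),
                CharDetection("B", 0.1, 0.1, 1.0)]
        enc = encode_sequence(dets)
        assert enc[0].vector[VOCAB_TOKENS.index("A")] == 1.0

    def test_encoded_char_dimension_validated(self):
        with pytest.raises(ValueError):
            EncodedChar(np.zeros(3, dtype=np.float32))


class TestSortDetections:
    def test_face_then_row_then_x(self):
        dets = [CharDetection("C", 0.7, 0.4, 1.0),   # back
                CharDetection("B", 0.3, 0.52, 1.0),  # front, lower row
                CharDetection("A", 0.2, 0.25, 1.0)]  # front, upper row
        assert [d.char for d in sort_detections(dets)] == ["A", "B", "C"]

    def test_jitter_within_a_row_does_not_scramble(self):
        dets = [CharDetection("B", 0.3, 0.505, 1.0),
                CharDetection("A", 0.2, 0.515, 1.0)]
        assert [d.char for d in sort_detections(dets)] == ["A", "B"]


class TestTraining:
    def test_copy_task_near_perfect(self):
        db = sd.generate_database(60, seed=21, imprint_length_range=(2, 5))
        pairs = []
        for i, r in enumerate(db):
            boxes = sd.render_pill(r, 96, seed=i)[1]
            dets = sd.corrupt_detections(boxes, sd.NoiseConfig(seed=i))
            pairs.append(CorrectionPair(source=tuple(dets), target=r.imprint))
        cfg = CorrectorConfig(embedding_size=24, hidden_size=48, epochs=250,
                              batch_size=20, learning_rate=2e-3, seed=0)
        model = train_corrector(pairs, config=cfg)
        exact = np.mean([correct_imprint(model, list(p.source)) == p.target
                         for p in pairs])
        assert exact >= 0.98

    def test_deterministic_given_seed(self):
        pairs = [CorrectionPair(
            source=(CharDetection("A", 0.2, 0.5, 1.0),), target="A")] * 8
        cfg = CorrectorConfig(embedding_size=8, hidden_size=12, epochs=3,
                              batch_size=4, seed=3)
        a = train_corrector(pairs, config=cfg)
        b = train_corrector(pairs, config=cfg)
        assert a.loss_history == b.loss_history

    def test_overlong_target_rejected_at_load(self):
        pairs = [CorrectionPair(source=(), target="A" * 30)]
        with pytest.raises(ValueError, match="max_target_len"):
            train_corrector(pairs, config=CorrectorConfig(epochs=1))

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_corrector([], config=CorrectorConfig())

    def test_context_requires_per_pair_features(self):
        pairs = [CorrectionPair(source=(), target="A")]
        cfg = CorrectorConfig(context_mode="features", epochs=1)
        with pytest.raises(ValueError, match="feature"):
            train_corrector(pairs, feature_context=None, config=cfg)

    def test_likelihood_nonincreasing_late_in_training(self, corrector_model):
        tail = corrector_model.loss_history[-10:]
        for prev, cur in zip(tail, tail[1:]):
            assert cur <= prev * 1.05


@pytest.fixture(scope="module")
def nodrop_setup():
    """Corrector trained on confusion+shuffle corruptions (no drops)."""
    db = sd.generate_database(200, seed=33)
    boxes = {r.pill_id: sd.render_pill(r, 96, seed=9000 + i)[1]
             for i, r in enumerate(db)}
    noise = sd.NoiseConfig(confusion_rate=0.3, coord_jitter_sd=0.01,
                           shuffle=True)
    import dataclasses

    def draws(seed0, n):
        out = []
        for i, r in enumerate(db):
            for d in range(n):
                cfg = dataclasses.replace(noise, seed=seed0 + i * 1000 + d)
                dets = sd.corrupt_detections(boxes[r.pill_id], cfg)
                out.append(CorrectionPair(source=tuple(dets),
                                          target=r.imprint))
        return out

    train_pairs = draws(0, 10)
    test_pairs = draws(777_777, 1)
    cfg = CorrectorConfig(embedding_size=32, hidden_size=64, epochs=35,
                          batch_size=50, learning_rate=2e-3, seed=0)
    return train_corrector(train_pairs, config=cfg), test_pairs


class TestHeldOutCorrection:
    def test_heldout_exact_match_at_least_080(self, nodrop_setup):
        model, test_pairs = nodrop_setup
        exact = np.mean([correct_imprint(model, list(p.source)) == p.target
                         for p in test_pairs])
        assert exact >= 0.80


class TestWorkedExample:
    def test_scrambled_confused_ikoim_decodes_to_m10_ki(self):
        """The flagship correction: detector output IKOIM (confusions O<->0,
        I<->1, order scrambled) with true coordinates -> "M10_KI"."""
        target = sd.PillRecord("W", "square", "orange", "tablet", "M10_KI")
        db = [target] + sd.generate_database(39, seed=51)
        boxes = {r.pill_id: sd.render_pill(r, 96, seed=100 + i)[1]
                 for i, r in enumerate(db)}
        import dataclasses
        noise = sd.NoiseConfig(confusion_rate=0.5, shuffle=True)
        pairs = []
        for i, r in enumerate(db):
            for d in range(12):
                cfg = dataclasses.replace(noise, seed=i * 1000 + d)
                dets = sd.corrupt_detections(boxes[r.pill_id], cfg)
                pairs.append(CorrectionPair(source=tuple(dets),
                                            target=r.imprint))
        model = train_corrector(pairs, config=CorrectorConfig(
            embedding_size=32, hidden_size=48, epochs=80, batch_size=50,
            learning_rate=2e-3, seed=0))
        # build IKOIM by hand: true coordinates, confused characters, scrambled
        confuse = {"1": "I", "0": "O"}
        dets = [CharDetection(confuse.get(b.char, b.char), b.x_center,
                              b.y_center, 0.9)
                for b in boxes[target.pill_id]]
        order = np.random.default_rng(5).permutation(len(dets))
        scrambled = [dets[i] for i in order]
        assert sorted(d.char for d in scrambled) == sorted("IKOIM")
        assert correct_imprint(model, scrambled) == "M10_KI"


class TestDecodeContract:
    def test_empty_input_empty_output(self, corrector_model):
        assert correct_imprint(corrector_model, []) == ""

    def test_max_length_and_single_separator(self, corrector_model):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(1, 15)
            dets = [CharDetection(VOCAB_TOKENS[rng.integers(0, 37)],
                                  float(rng.random()), float(rng.random()),
                                  1.0)
                    for _ in range(n)]
            out = correct_imprint(corrector_model, dets)
            assert out.count(SEPARATOR) <= 1
            from pillid._vocab import tokenize
            assert len(tokenize(out)) <= corrector_model.config.max_target_len

    def test_save_load_roundtrip(self, corrector_model, tmp_path):
        path = tmp_path / "corr.npz"
        corrector_model.save(path)
        loaded = CorrectorModel.load(path)
        dets = [CharDetection("M", 0.2, 0.5, 0.9),
                CharDetection("1", 0.3, 0.5, 0.9)]
        assert (correct_imprint(loaded, dets)
                == correct_imprint(corrector_model, dets))


class TestAblations:
    def _anagram_corpus(self, n_families=30, n_draws=7):
        """Pills sharing a character multiset but differing in order and
        face split: the character bag alone cannot identify them, so the
        ordering information must come from the coordinates."""
        rng = np.random.default_rng(81)
        records = []
        k = 0
        while len(records) < 3 * n_families:
            chars = ([chr(ord("A") + rng.integers(0, 26)) for _ in range(2)]
                     + [str(rng.integers(0, 10)) for _ in range(3)])
            perms: set[str] = set()
            tries = 0
            while len(perms) < 3 and tries < 50:
                p = rng.permutation(5)
                tries += 1
                cut = int(rng.integers(1, 5))
                toks = [chars[i] for i in p]
                perms.add("".join(toks[:cut]) + "_" + "".join(toks[cut:]))
            if len(perms) < 3:
                continue
            for imp in sorted(perms):
                records.append(sd.PillRecord(f"P{k:04d}", "round", "white",
                                             "tablet", imp))
                k += 1
        import dataclasses
        noise = sd.NoiseConfig(confusion_rate=0.2, coord_jitter_sd=0.01,
                               shuffle=True)
        train, test = [], []
        for i, r in enumerate(records):
            boxes = sd.render_pill(r, 96, seed=300 + i)[1]
            for d in range(n_draws):
                cfg = dataclasses.replace(noise, seed=i * 997 + d)
                dets = sd.corrupt_detections(boxes, cfg)
                pair = CorrectionPair(source=tuple(dets), target=r.imprint)
                (test if d >= n_draws - 1 else train).append(pair)
        return train, test

    def test_coordinates_matter_on_shuffled_inputs(self):
        """Zeroing (x, y) at train and test (and skipping the coordinate
        pre-sort) must strictly reduce exact match on anagram pills."""
        train, test = self._anagram_corpus()
        cfg = CorrectorConfig(embedding_size=24, hidden_size=48, epochs=60,
                              batch_size=50, learning_rate=2e-3, seed=0)
        with_xy = train_corrector(train, config=cfg)
        without_xy = train_corrector(train, config=cfg, zero_coords=True)
        exact_with = np.mean([
            correct_imprint(with_xy, list(p.source)) == p.target
            for p in test])
        exact_without = np.mean([
            correct_imprint(without_xy, list(p.source), zero_coords=True)
            == p.target for p in test])
        assert exact_with > exact_without


class TestFeatureContext:
    def test_feature_context_resolves_confusable_imprints(self):
        """Pills whose imprints differ only in a confusable character but
        correlate with color: conditioning on features must not hurt and
        should resolve the ambiguity."""
        rng = np.random.default_rng(71)
        records = []
        for k in range(30):
            stem = "".join(chr(ord("A") + rng.integers(0, 26))
                           for _ in range(3))
            tail = str(rng.integers(10, 99))
            records.append(sd.PillRecord(
                f"O{k}", "round", "red", "tablet", f"{stem}O_{tail}"))
            records.append(sd.PillRecord(
                f"Z{k}", "round", "blue", "tablet", f"{stem}0_{tail}"))
        boxes = {r.pill_id: sd.render_pill(r, 96, seed=700 + i)[1]
                 for i, r in enumerate(records)}
        import dataclasses
        noise = sd.NoiseConfig(confusion_rate=0.5,
                               confusion_pairs=(("O", "0"),), shuffle=True)
        train, test, train_ctx, test_ctx = [], [], [], []
        for i, r in enumerate(records):
            for d in range(8):
                cfg = dataclasses.replace(noise, seed=i * 991 + d)
                dets = sd.corrupt_detections(boxes[r.pill_id], cfg)
                pair = CorrectionPair(source=tuple(dets), target=r.imprint)
                if d >= 6:
                    test.append((pair, r.features))
                else:
                    train.append(pair)
                    train_ctx.append(r.features)
        base_cfg = dict(embedding_size=24, hidden_size=48, epochs=35,
                        batch_size=50, learning_rate=2e-3, seed=0)
        plain = train_corrector(train,
                                config=CorrectorConfig(**base_cfg))
        context = train_corrector(
            train, feature_context=train_ctx,
            config=CorrectorConfig(context_mode="features", **base_cfg))
        exact_plain = np.mean([
            correct_imprint(plain, list(p.source)) == p.target
            for p, _ in test])
        exact_ctx = np.mean([
            correct_imprint(context, list(p.source), features=f) == p.target
            for p, f in test])
        assert exact_ctx >= exact_plain
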