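"""Hierarchical attention network: losses, inference rules, and learning."""

import numpy as np
import pytest

from autoicd.han import (
    CodeProbabilities,
    EmptyDocumentError,
    HanConfig,
    HanModel,
    bce_loss,
    infer_codes,
    train_han,
)
from autoicd.icd import CodeSet
from autoicd.metrics import micro_prf
from autoicd.preprocess import make_document

TINY_HAN = dict(
    embed_dim=24, word_hidden=12, sent_hidden=12, batch_size=8, lr=5e-3
)


# -- bce_loss ---------------------------------------------------------------


def test_bce_loss_perfect_prediction_is_zero():
    gold = CodeSet.from_strings("I10", ["E785"])
    probs = {"I10": 1.0, "E785": 1.0, "N179": 0.0}
    assert bce_loss(probs, gold) == pytest.approx(0.0, abs=1e-9)


def test_bce_loss_uniform_two_codes():
    gold = CodeSet.from_strings("I10")
    probs = {"I10": 0.5, "E785": 0.5}
    assert bce_loss(probs, gold) == pytest.approx(2 * np.log(2), abs=1e-12)


def test_bce_loss_monotone_toward_label():
    gold = CodeSet.from_strings("I10")
    lo = bce_loss({"I10": 0.6, "E785": 0.3}, gold)
    hi = bce_loss({"I10": 0.5, "E785": 0.3}, gold)
    assert lo < hi


def test_bce_loss_rejects_out_of_inventory_gold():
    with pytest.raises(ValueError):
        bce_loss({"I10": 0.5}, CodeSet.from_strings("J189"))


def test_bce_loss_matches_per_code_loop_oracle():
    rng = np.random.default_rng(0)
    codes = ["A000", "B180", "C340", "E119", "I10"]
    for _ in range(200):
        probs = {c: float(rng.uniform(0.01, 0.99)) for c in codes}
        gold_codes = list(rng.choice(codes, size=rng.integers(1, 4), replace=False))
        gold = CodeSet.from_strings(gold_codes[0], gold_codes[1:])
        expected = 0.0
        for c in codes:
            y = 1.0 if c in gold.all_codes() else 0.0
            p = probs[c]
            expected -= y * np.log(p) + (1 - y) * np.log(1 - p)
        assert bce_loss(probs, gold) == pytest.approx(expected, abs=1e-9)


# -- infer_codes ------------------------------------------------------------


def test_infer_codes_threshold_and_argmax():
    cs = infer_codes({"I10": 0.9, "E785": 0.6, "N179": 0.4}, t=0.5)
    assert cs.main_code.code == "I10"
    assert [c.code for c in cs.other_codes] == ["E785"]


def test_infer_codes_main_emitted_below_threshold():
    cs = infer_codes({"I10": 0.3, "E785": 0.2}, t=0.5)
    assert cs.main_code.code == "I10"
    assert cs.other_codes == ()


def test_infer_codes_tie_breaks_lexicographically():
    cs = infer_codes({"A000": 0.7, "B000": 0.7}, t=0.5)
    assert cs.main_code.code == "A000"
    assert [c.code for c in cs.other_codes] == ["B000"]


def test_infer_codes_monotone_in_threshold():
    rng = np.random.default_rng(1)
    probs = {c: float(p) for c, p in zip(
        ["A000", "B180", "C340", "E119", "I10", "J189"], rng.uniform(size=6)
    )}
    previous: set[str] = set()
    for t in (0.9, 0.7, 0.5, 0.3, 0.1):
        others = {c.code for c in infer_codes(probs, t).other_codes}
        assert previous <= others  # lowering t never removes codes
        previous = others


def test_infer_codes_empty_rejected():
    with pytest.raises(ValueError):
        infer_codes({}, t=0.5)


# -- model forward / training ----------------------------------------------


@pytest.fixture(scope="module")
def overfit_model(tiny_train):
    docs = tiny_train[:5]
    config = HanConfig(max_epochs=250, patience=250, seed=2, **TINY_HAN)
    model, log = train_han(docs, docs, config)
    return model, log, docs


def test_forward_probabilities_shape_and_determinism(overfit_model):
    model, _, docs = overfit_model
    p1 = model.forward(docs[0].document)
    p2 = model.forward(docs[0].document)
    assert len(p1) == model.config.num_codes
    assert all(0.0 <= v <= 1.0 for _, v in p1.items())
    assert dict(p1.items()) == dict(p2.items())


def test_empty_document_rejected(overfit_model):
    model, _, _ = overfit_model
    with pytest.raises(EmptyDocumentError):
        model.forward(make_document("empty", ""))


def test_overfit_reaches_perfect_validation_f(overfit_model):
    """With train == val, a small network memorizes five summaries."""
    model, log, docs = overfit_model
    assert max(row["val_f"] for row in log) == pytest.approx(1.0)
    for rec in docs:
        probs = model.forward(rec.document)
        for code in rec.gold.all_codes():
            assert probs[code] > 0.9


def test_training_is_deterministic(tiny_train):
    docs = tiny_train[:6]
    config = HanConfig(max_epochs=5, patience=5, seed=4, **TINY_HAN)
    _, log1 = train_han(docs, docs, config)
    _, log2 = train_han(docs, docs, config)
    assert log1 == log2


def test_patience_zero_stops_at_first_plateau(tiny_train):
    """With a frozen model nothing improves after epoch one."""
    docs = tiny_train[:6]
    frozen = {**TINY_HAN, "lr": 0.0}
    config = HanConfig(max_epochs=100, patience=0, seed=4, **frozen)
    _, log = train_han(docs, docs, config)
    assert len(log) == 2  # epoch 1 sets the baseline; epoch 2 trips patience 0
    config = HanConfig(max_epochs=100, patience=3, seed=4, **frozen)
    _, log = train_han(docs, docs, config)
    assert len(log) == 5


def test_empty_corpus_rejected():
    with pytest.raises(ValueError):
        train_han([], [], HanConfig(**TINY_HAN))


# -- attention --------------------------------------------------------------


def test_attention_weights_normalized(overfit_model):
    model, _, docs = overfit_model
    aw = model.attention_weights(docs[0].document)
    assert sum(aw.sentence_weights) == pytest.approx(1.0, abs=1e-6)
    for sent_w, sent in zip(aw.word_weights, docs[0].document.sentences):
        assert len(sent_w) == min(len(sent), model.config.max_words)
        assert sum(sent_w) == pytest.approx(1.0, abs=1e-6)


def test_single_sentence_document_gets_unit_sentence_weight(overfit_model):
    model, _, _ = overfit_model
    aw = model.attention_weights(make_document("one", "Chest pain today."))
    assert aw.sentence_weights == pytest.approx((1.0,))


def test_attention_highlights_trigger_keyword(tiny_splits, overfit_model):
    """After overfitting, a gold code's trigger word out-attends filler."""
    _, codebook = tiny_splits
    model, _, docs = overfit_model
    keywords = {
        w for e in codebook.entries for p in e.keywords for w in p.split()
    }
    hits = total = 0
    for rec in docs:
        aw = model.attention_weights(rec.document)
        for sent, weights in zip(rec.document.sentences, aw.word_weights):
            kw_idx = [i for i, tok in enumerate(sent) if tok in keywords]
            if kw_idx and len(kw_idx) < len(sent):
                total += 1
                best = int(np.argmax(weights))
                if best in kw_idx:
                    hits += 1
    assert total > 0
    assert hits / total > 0.5


# -- persistence ------------------------------------------------------------


def test_checkpoint_round_trip(tmp_path, overfit_model):
    model, _, docs = overfit_model
    path = tmp_path / "han.npz"
    model.save(path)
    loaded = HanModel.load(path)
    assert loaded.config == model.config
    assert loaded.vocab == model.vocab
    assert loaded.codes == model.codes
    p1 = model.forward(docs[0].document)
    p2 = loaded.forward(docs[0].document)
    assert dict(p1.items()) == dict(p2.items())


def test_synthetic_recovery_beats_majority_baseline(tiny_train, tiny_val):
    """Trained HAN clearly outperforms always-predicting the head code."""
    config = HanConfig(max_epochs=40, patience=10, seed=1, **TINY_HAN)
    model, _ = train_han(tiny_train, tiny_val, config)
    golds = [r.gold for r in tiny_val]
    preds = [model.predict(r.document) for r in tiny_val]
    freq: dict[str, int] = {}
    for r in tiny_train:
        for c in r.gold.all_codes():
            freq[c] = freq.get(c, 0) + 1
    majority = max(freq, key=freq.get)
    base = micro_prf([CodeSet.from_strings(majority)] * len(golds), golds)
    model_f = micro_prf(preds, golds).f_measure
    assert model_f - base.f_measure >= 0.3
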