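"""Hierarchical attention network (HAN) for multi-label ICD coding.

Words are embedded and encoded by a bidirectional GRU; a word-level
attention layer pools each sentence into a vector; a second bidirectional
GRU plus sentence-level attention pools the document; a fully connected
layer followed by a sigmoid yields one independent probability per code in
the inventory.  Training minimizes the summed binary cross-entropy over
labels (mean over the batch) with Adam and early stopping on the validation
micro-F / loss.

Inference: the highest-probability code is always emitted as the main code
(argmax carries no threshold); every other code with probability >= t
(default 0.5) is emitted as a secondary code, in descending-probability
order with lexicographic tie-breaks.

The attention distributions are exposed for interpretability: they indicate
which words and sentences the classifier weighted when assigning codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .icd import CodeSet, parse_code
from .metrics import micro_prf
from .preprocess import CorpusRecord, Document

__all__ = [
    "HanConfig",
    "CodeProbabilities",
    "AttentionWeights",
    "HanModel",
    "EmptyDocumentError",
    "bce_loss",
    "infer_codes",
    "train_han",
]


class EmptyDocumentError(ValueError):
    """Raised when a document has no tokens after preprocessing."""


@dataclass(frozen=True)
class HanConfig:
    """Hyper-parameters; training defaults follow the study configuration."""

    vocab_size: int = 0  # filled when the vocabulary is built
    embed_dim: int = 300
    word_hidden: int = 50  # per direction
    sent_hidden: int = 50  # per direction
    num_codes: int = 0  # filled when the inventory is built
    threshold_t: float = 0.5
    lr: float = 1e-3
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 50
    seed: int = 0
    max_sentences: int = 64
    max_words: int = 64

    def __post_init__(self):
        if not 0.0 < self.threshold_t < 1.0:
            raise ValueError(f"threshold_t must lie in (0, 1), got {self.threshold_t}")


@dataclass(frozen=True)
class CodeProbabilities:
    """Per-code confidences in [0, 1], iterated lexicographically by code."""

    probs: dict[str, float]

    def __post_init__(self):
        ordered = {c: float(p) for c, p in sorted(self.probs.items())}
        for c, p in ordered.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {c} outside [0, 1]: {p}")
        object.__setattr__(self, "probs", ordered)

    def __getitem__(self, code: str) -> float:
        return self.probs[code]

    def __len__(self) -> int:
        return len(self.probs)

    def items(self):
        return self.probs.items()


@dataclass(frozen=True)
class AttentionWeights:
    """Normalized sentence- and per-sentence word-attention distributions."""

    sentence_weights: tuple[float, ...]
    word_weights: tuple[tuple[float, ...], ...]


# ---------------------------------------------------------------------------
# decision rules independent of the network
# ---------------------------------------------------------------------------


def bce_loss(probs, gold: CodeSet, eps: float = 1e-12) -> float:
    """Summed binary cross-entropy of a probability map against gold labels.

    ``probs`` maps every inventory code to a probability; gold codes must be
    a subset of the inventory.  Probabilities are clamped to [eps, 1-eps].
    """
    if isinstance(probs, CodeProbabilities):
        probs = probs.probs
    gold_codes = gold.all_codes()
    missing = gold_codes - set(probs)
    if missing:
        raise ValueError(f"gold codes outside inventory: {sorted(missing)}")
    total = 0.0
    for code, p in probs.items():
        p = min(max(float(p), eps), 1.0 - eps)
        y = 1.0 if code in gold_codes else 0.0
        total -= y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(total)


def infer_codes(probs, t: float) -> CodeSet:
    """Decode a probability map into a main code plus thresholded others.

    The argmax code is always the main code regardless of ``t``; remaining
    codes with probability >= t follow in descending-probability order.
    Ties prefer the lexicographically smaller code.
    """
    if isinstance(probs, CodeProbabilities):
        probs = probs.probs
    if not probs:
        raise ValueError("empty probability map")
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    ranked = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
    main = ranked[0][0]
    others = [c for c, p in ranked[1:] if p >= t]
    return CodeSet.from_strings(main, others)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


DTYPE = np.float32  # model arithmetic; public probabilities are float64


def _uniform(rng: np.random.Generator, scale: float, shape) -> np.ndarray:
    return rng.uniform(-scale, scale, shape).astype(DTYPE)


def _gru_params(rng: np.random.Generator, in_dim: int, hid: int, scale: float):
    # gate matmuls are fused: W packs z|r|n on the input, U packs z|r
    return {
        "W": ag.parameter(_uniform(rng, scale, (in_dim, 3 * hid))),
        "U": ag.parameter(_uniform(rng, scale, (hid, 2 * hid))),
        "Un": ag.parameter(_uniform(rng, scale, (hid, hid))),
        "b": ag.parameter(np.zeros(3 * hid, dtype=DTYPE)),
    }


def _gru_step(p, xw: Tensor, h: Tensor, m: Tensor, hid: int) -> Tensor:
    """One GRU step; `xw` is the precomputed input projection x @ W + b."""
    hu = h @ p["U"]
    z = ag.sigmoid(xw[:, :hid] + hu[:, :hid])
    r = ag.sigmoid(xw[:, hid : 2 * hid] + hu[:, hid:])
    n = ag.tanh(xw[:, 2 * hid :] + (r * h) @ p["Un"])
    h_new = (1.0 - z) * n + z * h
    return m * h_new + (1.0 - m) * h


def _bigru(p_fwd, p_bwd, x: Tensor, mask: np.ndarray, hid: int) -> Tensor:
    """Bidirectional GRU over x (N, T, in); returns states (N, T, 2h).

    The input projections of all time steps are hoisted into one matmul per
    direction; only the hidden-to-hidden recurrence runs stepwise.
    """
    n, t, din = x.shape
    flat = ag.reshape(x, (n * t, din))
    masks = [Tensor(mask[:, i : i + 1]) for i in range(t)]
    outs = []
    for p, order in ((p_fwd, range(t)), (p_bwd, range(t - 1, -1, -1))):
        xw = ag.reshape(flat @ p["W"] + p["b"], (n, t, 3 * hid))
        h = Tensor(np.zeros((n, hid), dtype=DTYPE))
        states: list[Optional[Tensor]] = [None] * t
        for i in order:
            h = _gru_step(p, ag.reshape(xw[:, i, :], (n, 3 * hid)), h, masks[i], hid)
            states[i] = ag.reshape(h, (n, 1, hid))
        outs.append(ag.concat(states, axis=1))
    return ag.concat(outs, axis=2)


def _attention(pa, h: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Additive attention over h (N, T, D); returns (context (N,D), alphas (N,T))."""
    n, t, d = h.shape
    flat = ag.reshape(h, (n * t, d))
    u = ag.tanh(flat @ pa["W"] + pa["b"])
    scores = ag.reshape(u @ pa["u"], (n, t))
    scores = scores + Tensor((mask - 1.0) * 1e9)
    alphas = ag.softmax(scores, axis=1)
    ctx = ag.sum_(ag.reshape(alphas, (n, t, 1)) * h, axis=1)
    return ctx, alphas


class HanModel:
    """A trained (or freshly initialized) hierarchical attention network."""

    def __init__(
        self,
        config: HanConfig,
        vocab: Mapping[str, int],
        codes: Sequence[str],
    ):
        if config.num_codes < 1:
            raise ValueError("num_codes must be >= 1")
        self.config = config
        self.vocab = dict(vocab)
        self.codes = tuple(sorted(codes))
        self._code_objs = {c: parse_code(c) for c in self.codes}
        rng = np.random.default_rng(config.seed)
        c = config
        self.params: dict[str, Tensor] = {"emb": ag.parameter(
            _uniform(rng, 0.1, (c.vocab_size, c.embed_dim))
        )}
        scale_w = 1.0 / np.sqrt(c.embed_dim)
        scale_s = 1.0 / np.sqrt(2 * c.word_hidden)
        for name, pset in (
            ("wf", _gru_params(rng, c.embed_dim, c.word_hidden, scale_w)),
            ("wb", _gru_params(rng, c.embed_dim, c.word_hidden, scale_w)),
            ("sf", _gru_params(rng, 2 * c.word_hidden, c.sent_hidden, scale_s)),
            ("sb", _gru_params(rng, 2 * c.word_hidden, c.sent_hidden, scale_s)),
        ):
            for k, v in pset.items():
                self.params[f"{name}.{k}"] = v
        for prefix, dim in (("wa", 2 * c.word_hidden), ("sa", 2 * c.sent_hidden)):
            scale = 1.0 / np.sqrt(dim)
            self.params[f"{prefix}.W"] = ag.parameter(_uniform(rng, scale, (dim, dim)))
            self.params[f"{prefix}.b"] = ag.parameter(np.zeros(dim, dtype=DTYPE))
            self.params[f"{prefix}.u"] = ag.parameter(_uniform(rng, scale, (dim, 1)))
        out_scale = 1.0 / np.sqrt(2 * c.sent_hidden)
        self.params["out.W"] = ag.parameter(
            _uniform(rng, out_scale, (2 * c.sent_hidden, c.num_codes))
        )
        self.params["out.b"] = ag.parameter(np.zeros(c.num_codes, dtype=DTYPE))

    # -- data plumbing -------------------------------------------------
    def load_pretrained_embeddings(self, path) -> int:
        """Overwrite embedding rows from a text file of `word v1 v2 ...` rows."""
        n_loaded = 0
        emb = self.params["emb"].data
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip().split(" ")
                word = parts[0]
                if word in self.vocab and len(parts) - 1 == self.config.embed_dim:
                    emb[self.vocab[word]] = np.asarray(parts[1:], dtype=float)
                    n_loaded += 1
        return n_loaded

    def encode_document(self, doc: Document) -> list[list[int]]:
        c = self.config
        sents = []
        for sent in doc.sentences[: c.max_sentences]:
            ids = [self.vocab.get(tok, 1) for tok in sent[: c.max_words]]
            if ids:
                sents.append(ids)
        if not sents:
            raise EmptyDocumentError(f"document {doc.doc_id!r} has no tokens")
        return sents

    def _batch_arrays(self, encoded: list[list[list[int]]]):
        b = len(encoded)
        s_max = max(len(d) for d in encoded)
        t_max = max(len(s) for d in encoded for s in d)
        ids = np.zeros((b, s_max, t_max), dtype=np.int64)
        wmask = np.zeros((b, s_max, t_max), dtype=DTYPE)
        smask = np.zeros((b, s_max), dtype=DTYPE)
        for i, doc in enumerate(encoded):
            for j, sent in enumerate(doc):
                ids[i, j, : len(sent)] = sent
                wmask[i, j, : len(sent)] = 1.0
                smask[i, j] = 1.0
        return ids, wmask, smask

    # -- forward -------------------------------------------------------
    def _forward_batch(self, ids, wmask, smask):
        """Returns (logits (B,L), word_alphas (B*S,T), sent_alphas (B,S))."""
        c = self.config
        b, s_max, t_max = ids.shape
        flat_ids = ids.reshape(b * s_max, t_max)
        flat_wmask = wmask.reshape(b * s_max, t_max)
        emb = ag.embedding(self.params["emb"], flat_ids)  # (BS, T, d)
        p = self.params
        wf = {k.split(".")[1]: v for k, v in p.items() if k.startswith("wf.")}
        wb = {k.split(".")[1]: v for k, v in p.items() if k.startswith("wb.")}
        sf = {k.split(".")[1]: v for k, v in p.items() if k.startswith("sf.")}
        sb = {k.split(".")[1]: v for k, v in p.items() if k.startswith("sb.")}
        wa = {k.split(".")[1]: v for k, v in p.items() if k.startswith("wa.")}
        sa = {k.split(".")[1]: v for k, v in p.items() if k.startswith("sa.")}

        hs = _bigru(wf, wb, emb, flat_wmask, c.word_hidden)
        sent_vecs, word_alphas = _attention(wa, hs, flat_wmask)
        # zero out padding sentences so they carry no signal upward
        sent_vecs = sent_vecs * Tensor(smask.reshape(b * s_max, 1))
        sent_mat = ag.reshape(sent_vecs, (b, s_max, 2 * c.word_hidden))
        hs2 = _bigru(sf, sb, sent_mat, smask, c.sent_hidden)
        doc_vec, sent_alphas = _attention(sa, hs2, smask)
        logits = doc_vec @ p["out.W"] + p["out.b"]
        return logits, word_alphas, sent_alphas

    def forward(self, doc: Document) -> CodeProbabilities:
        """Per-code probabilities for one document (deterministic)."""
        encoded = [self.encode_document(doc)]
        logits, _, _ = self._forward_batch(*self._batch_arrays(encoded))
        probs = 1.0 / (1.0 + np.exp(-logits.data[0].astype(np.float64)))
        return CodeProbabilities(dict(zip(self.codes, probs)))

    def predict(self, doc: Document, t: Optional[float] = None) -> CodeSet:
        return infer_codes(self.forward(doc), t if t is not None else self.config.threshold_t)

    def attention_weights(self, doc: Document) -> AttentionWeights:
        """Word- and sentence-level attention distributions for a document."""
        encoded = [self.encode_document(doc)]
        ids, wmask, smask = self._batch_arrays(encoded)
        _, word_alphas, sent_alphas = self._forward_batch(ids, wmask, smask)
        sents = encoded[0]
        sw = tuple(float(x) for x in sent_alphas.data[0, : len(sents)])
        ww = tuple(
            tuple(float(x) for x in word_alphas.data[j, : len(sent)])
            for j, sent in enumerate(sents)
        )
        return AttentionWeights(sentence_weights=sw, word_weights=ww)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "format": "autoicd-han-v1",
            "config": asdict(self.config),
            "vocab": self.vocab,
            "codes": list(self.codes),
        }
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path) -> "HanModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
            if meta.get("format") != "autoicd-han-v1":
                raise ValueError(f"not a HAN checkpoint: {path}")
            model = cls(HanConfig(**meta["config"]), meta["vocab"], meta["codes"])
            for k in model.params:
                model.params[k].data = archive[f"param:{k}"].copy()
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: Mapping[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Stable elementwise BCE from logits; gradient is sigmoid(z) - y."""
    z = logits.data
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))

    def bwd(g):
        return (g * (1.0 / (1.0 + np.exp(-z)) - y),)

    return Tensor(loss, (logits,), bwd)


def build_vocab(records: Sequence[CorpusRecord]) -> dict[str, int]:
    """Token vocabulary from training documents; 0 is PAD, 1 is UNK."""
    vocab = {"<pad>": 0, "<unk>": 1}
    for rec in records:
        for sent in rec.document.sentences:
            for tok in sent:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
    return vocab


def build_inventory(*record_lists: Sequence[CorpusRecord]) -> tuple[str, ...]:
    """Sorted union of all gold codes across the given corpora."""
    codes: set[str] = set()
    for records in record_lists:
        for rec in records:
            codes |= rec.gold.all_codes()
    return tuple(sorted(codes))


def train_han(
    train_records: Sequence[CorpusRecord],
    val_records: Sequence[CorpusRecord],
    config: HanConfig,
) -> tuple[HanModel, list[dict]]:
    """Train with Adam and early stopping; returns the best-validation-F model.

    The patience counter resets whenever either the validation micro-F or
    the validation loss improves; training also stops when the validation
    loss reaches zero or ``max_epochs`` is exhausted.  The returned log has
    one entry per epoch: train_loss, val_loss, val_f.
    """
    if not train_records or not val_records:
        raise ValueError("empty corpus")
    vocab = build_vocab(train_records)
    codes = build_inventory(train_records, val_records)
    config = replace(config, vocab_size=len(vocab), num_codes=len(codes))
    model = HanModel(config, vocab, codes)
    code_index = {c: i for i, c in enumerate(codes)}

    def encode_all(records):
        encoded, targets = [], []
        for rec in records:
            encoded.append(model.encode_document(rec.document))
            y = np.zeros(len(codes), dtype=DTYPE)
            for c in rec.gold.all_codes():
                y[code_index[c]] = 1.0
            targets.append(y)
        return encoded, np.array(targets, dtype=DTYPE)

    train_enc, train_y = encode_all(train_records)
    val_enc, val_y = encode_all(val_records)
    val_golds = [rec.gold for rec in val_records]

    # start the output layer at the label-prior logits so the early epochs
    # go into separating codes rather than learning base rates
    prior = np.clip(train_y.mean(axis=0), 1e-4, 1.0 - 1e-4)
    model.params["out.b"].data = np.log(prior / (1.0 - prior)).astype(DTYPE)

    rng = np.random.default_rng(config.seed + 1)
    opt = ag.Adam(model.params.values(), lr=config.lr)
    log: list[dict] = []
    best_f = -1.0
    best_loss = np.inf
    best_state_loss = np.inf
    best_state = model.state_copy()
    bad_epochs = 0

    def batches(n, size, order=None):
        order = np.arange(n) if order is None else order
        for i in range(0, n, size):
            yield order[i : i + size]

    for epoch in range(1, config.max_epochs + 1):
        opt.lr = config.lr * config.lr_decay ** (epoch - 1)
        order = rng.permutation(len(train_enc))
        train_loss = 0.0
        for batch in batches(len(train_enc), config.batch_size, order):
            enc = [train_enc[i] for i in batch]
            y = train_y[batch]
            logits, _, _ = model._forward_batch(*model._batch_arrays(enc))
            loss = ag.mean(ag.sum_(_bce_with_logits(logits, y), axis=1))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_loss += loss.item() * len(batch)
        train_loss /= len(train_enc)

        # validation pass
        val_loss = 0.0
        preds = []
        for batch in batches(len(val_enc), config.batch_size):
            enc = [val_enc[i] for i in batch]
            logits, _, _ = model._forward_batch(*model._batch_arrays(enc))
            loss = ag.mean(ag.sum_(_bce_with_logits(logits, val_y[batch]), axis=1))
            val_loss += loss.item() * len(batch)
            probs = 1.0 / (1.0 + np.exp(-logits.data))
            for row in probs:
                preds.append(
                    infer_codes(dict(zip(codes, row)), config.threshold_t)
                )
        val_loss /= len(val_enc)
        val_f = micro_prf(preds, val_golds).f_measure
        log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "val_f": val_f}
        )

        improved = val_f > best_f + 1e-12 or val_loss < best_loss - 1e-12
        # model selection: best validation F, ties broken by lower loss
        if val_f > best_f or (val_f == best_f and val_loss < best_state_loss):
            best_f = val_f
            best_state_loss = val_loss
            best_state = model.state_copy()
        best_loss = min(best_loss, val_loss)
        if improved:
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
        if val_loss <= 1e-9:  # "validation loss reaches 0"
            break

    model.load_state(best_state)
    return model, log
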