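"""Generative sequence coder: code assignment as conditional generation.

Each training instance is rendered as one token sequence

    [CLS] text tokens ... [SEP] MAINCODE [#@#] OTHERCODE ... [SEP]

where CLS opens the input, SEP closes the text and the code tail, and the
``#@#`` separator splits the main (principal-diagnosis) code from the other
codes.  Every ICD code is a single vocabulary token.  A small causal
transformer language model is trained from scratch to maximize the
conditional likelihood of the code tail given the text (the text region is
masked out of the loss), and decodes greedily at inference time.  The
confidence of a generated code is the geometric mean of its token
probabilities (an arithmetic-mean variant is available via configuration).

A ``model_scale`` pointing at a checkpoint path replaces the from-scratch
initialization with pretrained weights, mirroring a fine-tuning regime.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .han import CodeProbabilities, EmptyDocumentError
from .icd import CodeSet, parse_code
from .preprocess import CorpusRecord, Document, truncate_tokens

__all__ = [
    "GenConfig",
    "CodedSequence",
    "GenModel",
    "build_training_sequence",
    "parse_decoded",
    "train_gen",
]

logger = logging.getLogger(__name__)

DTYPE = np.float32  # model arithmetic; reported confidences are float64

PAD, CLS, SEP, OSEP = "<pad>", "CLS", "SEP", "#@#"
_SPECIALS = (PAD, CLS, SEP, OSEP)


@dataclass(frozen=True)
class GenConfig:
    """Hyper-parameters; optimizer settings follow the study configuration."""

    max_seq_len: int = 1024
    lr: float = 1.5e-4
    epochs: int = 10
    batch_size: int = 4
    adam_eps: float = 1.0e-9
    model_scale: str = "tiny"  # or a path to pretrained checkpoint weights
    seed: int = 0
    max_new_tokens: int = 16
    embed_dim: int = 128
    n_layers: int = 2
    n_heads: int = 4
    prob_average: str = "geometric"  # or "arithmetic"

    def __post_init__(self):
        if self.max_seq_len < 8:
            raise ValueError(f"max_seq_len must be >= 8, got {self.max_seq_len}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.prob_average not in ("geometric", "arithmetic"):
            raise ValueError(f"unknown prob_average {self.prob_average!r}")


@dataclass(frozen=True)
class CodedSequence:
    """One training sequence: text prompt plus code-tail target."""

    prompt_tokens: tuple[str, ...]
    target_tokens: tuple[str, ...]

    @property
    def full_tokens(self) -> tuple[str, ...]:
        return self.prompt_tokens + self.target_tokens


def build_training_sequence(
    doc: Document,
    gold: CodeSet,
    config: GenConfig,
    code_freq: Optional[Mapping[str, int]] = None,
) -> CodedSequence:
    """Render one document + gold codes as a CLS/SEP/#@# token sequence.

    The text portion is truncated so the whole sequence fits
    ``max_seq_len``; the code portion is always kept intact.  Other codes
    are ordered by descending ``code_freq`` (ties lexicographic) when a
    frequency table is supplied, else in gold order.
    """
    others = [c.code for c in gold.other_codes]
    if code_freq is not None:
        others.sort(key=lambda c: (-code_freq.get(c, 0), c))
    target = (gold.main_code.code, OSEP, *others, SEP)
    budget = config.max_seq_len - len(target) - 2  # CLS + trailing text SEP
    if budget < 1:
        raise ValueError(
            f"no room for text: {len(target)} target tokens in "
            f"max_seq_len={config.max_seq_len}"
        )
    text = truncate_tokens(doc.tokens(), budget)
    if not text:
        raise EmptyDocumentError(f"document {doc.doc_id!r} has no tokens")
    return CodedSequence(
        prompt_tokens=(CLS, *text, SEP), target_tokens=target
    )


def parse_decoded(
    decoded: Sequence[tuple[str, float]], prob_average: str = "geometric"
) -> tuple[Optional[CodeSet], CodeProbabilities]:
    """Interpret a greedy-decoded token/probability stream as a code set.

    The first parsable code token before ``#@#`` is the main code; parsable
    tokens after it become other codes.  Duplicates are dropped (first
    occurrence kept); unparsable tokens are dropped with a warning.  If no
    main code can be identified the flagged no-principal-diagnosis result
    (``None``) is returned.  Each code's confidence is the geometric (or
    arithmetic) mean of its token probabilities.
    """
    main: Optional[str] = None
    others: list[str] = []
    confidences: dict[str, list[float]] = {}
    in_tail = False
    for token, prob in decoded:
        if token == SEP:
            break
        if token == OSEP:
            in_tail = True
            continue
        try:
            parsed = parse_code(token)
        except ValueError:
            logger.warning("dropping unparsable generated token %r", token)
            continue
        code = parsed.code
        if code in confidences:
            continue  # duplicate: first occurrence kept
        confidences[code] = [prob]
        if main is None and not in_tail:
            main = code
        else:
            others.append(code)
    if main is None:
        return None, CodeProbabilities({})
    agg = {
        c: (
            float(np.exp(np.mean(np.log(np.clip(ps, 1e-12, 1.0)))))
            if prob_average == "geometric"
            else float(np.mean(ps))
        )
        for c, ps in confidences.items()
    }
    return CodeSet.from_strings(main, others), CodeProbabilities(agg)


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    m = ag.mean(x, axis=-1, keepdims=True)
    centered = x - m
    var = ag.mean(centered * centered, axis=-1, keepdims=True)
    return centered * ag.pow_const(var + eps, -0.5) * g + b


class GenModel:
    """A tiny causal transformer LM over text tokens plus code tokens."""

    def __init__(self, config: GenConfig, vocab: Mapping[str, int], codes: Sequence[str]):
        self.config = config
        self.vocab = dict(vocab)
        self.inv_vocab = {i: t for t, i in self.vocab.items()}
        self.codes = tuple(sorted(codes))
        rng = np.random.default_rng(config.seed)
        d, v = config.embed_dim, len(self.vocab)
        scale = 0.02

        def norm(*shape):
            return rng.normal(0, scale, shape).astype(DTYPE)
        p: dict[str, Tensor] = {
            "tok_emb": ag.parameter(norm(v, d)),
            "pos_emb": ag.parameter(norm(config.max_seq_len, d)),
            "lnf.g": ag.parameter(np.ones(d, dtype=DTYPE)),
            "lnf.b": ag.parameter(np.zeros(d, dtype=DTYPE)),
            "head.W": ag.parameter(norm(d, v)),
            "head.b": ag.parameter(np.zeros(v, dtype=DTYPE)),
        }
        for i in range(config.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"l{i}.{name}"] = ag.parameter(norm(d, d))
            p[f"l{i}.ln1.g"] = ag.parameter(np.ones(d, dtype=DTYPE))
            p[f"l{i}.ln1.b"] = ag.parameter(np.zeros(d, dtype=DTYPE))
            p[f"l{i}.ln2.g"] = ag.parameter(np.ones(d, dtype=DTYPE))
            p[f"l{i}.ln2.b"] = ag.parameter(np.zeros(d, dtype=DTYPE))
            p[f"l{i}.W1"] = ag.parameter(norm(d, 4 * d))
            p[f"l{i}.b1"] = ag.parameter(np.zeros(4 * d, dtype=DTYPE))
            p[f"l{i}.W2"] = ag.parameter(norm(4 * d, d))
            p[f"l{i}.b2"] = ag.parameter(np.zeros(d, dtype=DTYPE))
        self.params = p

    # -- encoding ------------------------------------------------------
    def encode_tokens(self, tokens: Sequence[str]) -> list[int]:
        unk = self.vocab.get("<unk>", 0)
        return [self.vocab.get(t, unk) for t in tokens]

    # -- forward -------------------------------------------------------
    def forward(self, ids: np.ndarray) -> Tensor:
        """Logits (B, T, V) for a batch of id sequences."""
        cfg = self.config
        b, t = ids.shape
        p = self.params
        x = ag.embedding(p["tok_emb"], ids) + p["pos_emb"][:t, :]
        h = cfg.embed_dim // cfg.n_heads
        causal = np.triu(np.full((t, t), -1e9, dtype=DTYPE), k=1)[None, None, :, :]
        for i in range(cfg.n_layers):
            xn = _layer_norm(x, p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"])

            def heads(w):
                y = xn @ w  # (B, T, D)
                y = ag.reshape(y, (b, t, cfg.n_heads, h))
                return ag.swapaxes(y, 1, 2)  # (B, H, T, h)

            q, k, v = heads(p[f"l{i}.Wq"]), heads(p[f"l{i}.Wk"]), heads(p[f"l{i}.Wv"])
            scores = (q @ ag.swapaxes(k, -1, -2)) * (1.0 / np.sqrt(h))
            attn = ag.softmax(scores + Tensor(causal), axis=-1)
            ctx = ag.swapaxes(attn @ v, 1, 2)  # (B, T, H, h)
            ctx = ag.reshape(ctx, (b, t, cfg.embed_dim))
            x = x + ctx @ p[f"l{i}.Wo"]
            xn2 = _layer_norm(x, p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"])
            ff = ag.relu(xn2 @ p[f"l{i}.W1"] + p[f"l{i}.b1"]) @ p[f"l{i}.W2"] + p[f"l{i}.b2"]
            x = x + ff
        x = _layer_norm(x, p["lnf.g"], p["lnf.b"])
        return x @ p["head.W"] + p["head.b"]

    def sequence_loss(self, sequences: Sequence[CodedSequence]) -> Tensor:
        """Mean negative log-likelihood per target token (text masked out)."""
        ids, mask = self._batch(sequences)
        logits = self.forward(ids[:, :-1])
        logp = ag.log_softmax(logits, axis=-1)
        picked = ag.take_along(logp, ids[:, 1:, None], axis=-1)  # (B, T-1, 1)
        picked = ag.reshape(picked, ids[:, 1:].shape)
        m = mask[:, 1:]
        total = ag.sum_(picked * Tensor(m))
        return total * (-1.0 / m.sum())

    def _batch(self, sequences: Sequence[CodedSequence]):
        t_max = max(len(s.full_tokens) for s in sequences)
        ids = np.zeros((len(sequences), t_max), dtype=np.int64)
        mask = np.zeros((len(sequences), t_max), dtype=DTYPE)
        for i, s in enumerate(sequences):
            full = self.encode_tokens(s.full_tokens)
            ids[i, : len(full)] = full
            mask[i, len(s.prompt_tokens) : len(full)] = 1.0
        return ids, mask

    # -- inference -----------------------------------------------------
    def generate(
        self, doc: Document
    ) -> tuple[Optional[CodeSet], CodeProbabilities]:
        """Greedy decode; returns (CodeSet or flagged None, confidences).

        Decoding runs from [CLS] text [SEP] until a SEP token or the
        ``max_new_tokens`` budget.  The first decoded code token is the
        main code; tokens after ``#@#`` are other codes.  Duplicates are
        dropped (first kept) and unparsable tokens are dropped with a
        warning.  If no parsable main code is decoded the result is the
        flagged no-principal-diagnosis outcome (None).
        """
        cfg = self.config
        text = truncate_tokens(
            doc.tokens(), cfg.max_seq_len - cfg.max_new_tokens - 2
        )
        if not text:
            raise EmptyDocumentError(f"document {doc.doc_id!r} has no tokens")
        ids = self.encode_tokens((CLS, *text, SEP))
        decoded: list[tuple[str, float]] = []
        for _ in range(cfg.max_new_tokens):
            logits = self.forward(np.array([ids])).data[0, -1].astype(np.float64)
            shifted = logits - logits.max()
            probs = np.exp(shifted) / np.exp(shifted).sum()
            nxt = int(probs.argmax())
            token = self.inv_vocab[nxt]
            decoded.append((token, float(probs[nxt])))
            if token == SEP:
                break
            ids.append(nxt)
            if len(ids) >= cfg.max_seq_len:
                break

        return parse_decoded(decoded, cfg.prob_average)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "format": "autoicd-gen-v1",
            "config": asdict(self.config),
            "vocab": self.vocab,
            "codes": list(self.codes),
        }
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path) -> "GenModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
            if meta.get("format") != "autoicd-gen-v1":
                raise ValueError(f"not a generative-coder checkpoint: {path}")
            model = cls(GenConfig(**meta["config"]), meta["vocab"], meta["codes"])
            for k in model.params:
                model.params[k].data = archive[f"param:{k}"].copy()
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}


def build_gen_vocab(
    records: Sequence[CorpusRecord], codes: Sequence[str]
) -> dict[str, int]:
    """Specials, then text tokens in first-seen order, then code tokens."""
    vocab = {t: i for i, t in enumerate(_SPECIALS)}
    vocab["<unk>"] = len(vocab)
    for rec in records:
        for tok in rec.document.tokens():
            if tok not in vocab:
                vocab[tok] = len(vocab)
    for code in sorted(codes):
        if code not in vocab:
            vocab[code] = len(vocab)
    return vocab


def train_gen(
    records: Sequence[CorpusRecord], config: GenConfig
) -> tuple[GenModel, list[dict]]:
    """Train the causal LM with AdamW for ``epochs`` epochs (seeded).

    Returns the trained model and a per-epoch log of mean training loss.
    """
    if not records:
        raise ValueError("empty corpus")
    codes = sorted({c for rec in records for c in rec.gold.all_codes()})
    vocab = build_gen_vocab(records, codes)
    if config.model_scale != "tiny":
        model = GenModel.load(config.model_scale)
    else:
        model = GenModel(config, vocab, codes)
    code_freq: dict[str, int] = {}
    for rec in records:
        for c in rec.gold.all_codes():
            code_freq[c] = code_freq.get(c, 0) + 1
    sequences = [
        build_training_sequence(rec.document, rec.gold, config, code_freq)
        for rec in records
    ]
    rng = np.random.default_rng(config.seed + 1)
    opt = ag.Adam(
        model.params.values(),
        lr=config.lr,
        eps=config.adam_eps,
        weight_decay=0.01,
        decoupled=True,
    )
    log: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(sequences))
        total = 0.0
        for i in range(0, len(order), config.batch_size):
            batch = [sequences[j] for j in order[i : i + config.batch_size]]
            loss = model.sequence_loss(batch)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(batch)
        log.append({"epoch": epoch, "train_loss": total / len(sequences)})
    return model, log
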