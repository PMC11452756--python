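# autoicd

Automatic ICD-10-CM coding of free-text discharge summaries, with the
evaluation apparatus used to judge coding systems in a DRG payment
context.

Hospitals label every discharge with one **principal diagnosis** plus
**secondary diagnoses** in ICD-10-CM (3–7 character codes, 21 chapters).
The principal diagnosis determines the major diagnostic category (MDC) and
hence the diagnosis-related group (DRG) used for reimbursement, so an
autocoder must be evaluated both as a multi-label retriever and on
principal-diagnosis / MDC agreement with a certified coding specialist
(CCS). `autoicd` provides:

* **Two coders.**
  * A **hierarchical attention network (HAN)**: word- and sentence-level
    bidirectional GRU encoders with additive attention, a sigmoid output
    over the code inventory trained with summed binary cross-entropy; the
    argmax code is the main code and codes with probability ≥ t (default
    0.5) are secondary. Attention weights are exported for
    interpretability.
  * A **generative sequence coder**: a causal transformer LM over
    `[CLS] text [SEP] MAINCODE [#@#] OTHERCODE … [SEP]` sequences, trained
    to maximize Π p(yᵢ | x, y<ᵢ) over the code tail and decoded greedily;
    each generated code carries a confidence (geometric mean of its token
    probabilities).
* **Evaluation**: micro precision/recall/F (P = TP/(TP+FP),
  R = TP/(TP+FN), F = 2PR/(P+R)) with top-K, per-block-letter and
  main-code breakdowns; the four-way principal-diagnosis outcome taxonomy
  and its overall correct rate; MDC grouping with per-category one-vs-rest
  Cohen κ = (p_o − p_e)/(1 − p_e), Landis–Koch bands and the
  blank-excluding average.
* **A seeded synthetic-corpus generator** reproducing the structure of
  sectioned discharge summaries (delimiters, `#`-prefixed diagnosis
  lines), a long-tailed code inventory (~4.4 codes/summary) and exact
  keyword–code correlations, so the whole pipeline is testable without
  any real patient data.

Everything runs on a small self-contained numpy autodiff engine: one CPU,
no GPU, fully deterministic per seed.

## Worked example

```bash
# 1. generate a seeded synthetic corpus (train/val/test + codebook)
autoicd synth --out-dir corpus --n-docs 2000 --num-codes 50 --seed 11 \
    --config examples/synth.yaml   # optional YAML with e.g. split_fracs

# 2. train the HAN coder
autoicd train han --train corpus/train.jsonl --val corpus/val.jsonl \
    --out han.npz --config examples/han.yaml

# 3. predict and evaluate on the held-out split
autoicd predict --model han.npz --input corpus/test.jsonl --out preds.jsonl
autoicd evaluate --pred preds.jsonl --gold corpus/test.jsonl \
    --freq-from corpus/train.jsonl --out-dir report --mdc-map default
```

The same flow in Python:

```python
from autoicd import (SynthConfig, generate_records, HanConfig, train_han,
                     micro_prf, make_document, CodeSet)
from autoicd.preprocess import CorpusRecord

splits, codebook = generate_records(
    SynthConfig(n_docs=2000, num_codes=50, seed=11,
                split_fracs=(0.8, 0.1, 0.1)))
to_rec = lambda r: CorpusRecord(make_document(r["id"], r["text"]),
                                CodeSet.from_strings(r["main_code"],
                                                     r["other_codes"]))
train = [to_rec(r) for r in splits["train"]]
val = [to_rec(r) for r in splits["val"]]
test = [to_rec(r) for r in splits["test"]]

model, log = train_han(train, val, HanConfig(
    embed_dim=96, word_hidden=48, sent_hidden=48, batch_size=32,
    lr=1.2e-2, lr_decay=0.97, max_epochs=45, patience=12, seed=1))
report = micro_prf([model.predict(r.document) for r in test],
                   [r.gold for r in test])
print(f"held-out micro P={report.precision:.3f} R={report.recall:.3f} "
      f"F={report.f_measure:.3f}")
```

which prints

```
held-out micro P=0.990 R=0.919 F=0.953
```

Precision is near-perfect because every synthetic trigger phrase is
unambiguous; recall is bounded by the generator's 5% keyword-dropout (a
code whose phrase was never emitted is unrecoverable), so ≈0.92 recall
means the network has learned essentially all of the recoverable
keyword–code associations. The generative coder on the same corpus
reaches main-code F ≈ 0.98: the position signal (the main code's phrase
opens the chief complaint) makes principal-diagnosis selection learnable.

## Layout

```
src/autoicd/
  icd.py          code validation, chapters, code sets
  preprocess.py   cleaning, sentence split, tokenization, corpus JSONL
  han.py          hierarchical attention network coder
  generative.py   causal-LM sequence coder
  metrics.py      micro P/R/F, top-K, per-block, PD outcomes
  mdc.py          MDC grouping, Cohen kappa, Landis-Koch bands
  synth.py        synthetic corpus generator
  cli.py          synth / train / predict / evaluate commands
  _autograd.py    reverse-mode autodiff core
docs/methods.md   model and evaluation details, design choices
```

See `docs/methods.md` for the full methods note, including what the
synthetic corpus does and does not demonstrate about real clinical text.
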