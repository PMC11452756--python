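# Methods

## The problem

Hospitals encode every discharge in ICD-10-CM: one *principal diagnosis*
(the main cause of hospitalization) plus *secondary diagnoses*. The
principal diagnosis drives the major diagnostic category (MDC) and hence
the DRG used for prospective payment, so automatic coding must be judged
not only by multi-label retrieval scores but also by whether the principal
diagnosis — and its MDC — agrees with a certified coding specialist (CCS).

`autoicd` implements this pipeline end to end: text preprocessing, two
coders, and the full evaluation apparatus (micro P/R/F with top-K,
per-block-letter and main-code breakdowns; the four-way principal-diagnosis
outcome taxonomy; MDC grouping with per-category Cohen κ).

## Models

### Hierarchical attention network (HAN)

Words are embedded (`embed_dim`, default 300) and encoded with a
bidirectional GRU (`word_hidden` per direction, default 50); additive
attention pools each sentence into a vector; a second bidirectional GRU
(`sent_hidden`) plus sentence-level attention pools the document; a fully
connected layer and an elementwise sigmoid give one independent probability
per code. Training minimizes the binary cross-entropy summed over labels
and averaged over the batch (Adam, lr 1e-3, batch 32, up to 500 epochs,
early-stopping patience 50 — patience resets whenever the validation
micro-F *or* loss improves, and training stops if the validation loss
reaches zero). The best-validation-F parameters are returned, ties broken
by lower validation loss.

Inference: the argmax code is always the main code (no threshold); every
other code with probability ≥ t (default 0.5) becomes a secondary code in
descending-probability order, ties to the lexicographically smaller code.
Documents are capped at 64 sentences × 64 words by default.

Two training choices are this package's own. The output-layer bias is
initialized at the label-prior logits, so early epochs separate codes
instead of learning base rates — without it the first several epochs
plateau at head-code predictions. `lr_decay` (default 1.0, i.e. off)
multiplies the learning rate each epoch for late-training stability at
large desk-scale learning rates. Embeddings are randomly initialized and
trained; `HanModel.load_pretrained_embeddings` can overwrite rows from a
text file of word-vector rows (e.g. 300-d GloVe) to recover the pretrained
regime.

### Generative sequence coder

Coding is cast as conditional generation over

    [CLS] text … [SEP] MAINCODE [#@#] OTHERCODE … [SEP]

with each code a single vocabulary token. A small causal transformer
(default 128-d, 2 layers, 4 heads, learned positions, pre-norm residual
blocks) is trained from scratch with AdamW (lr 1.5e-4, eps 1e-9, batch 4,
10 epochs) to maximize the likelihood of the code tail; the text region is
masked out of the loss. Text is truncated so the whole sequence fits the
1024-token context window; the code tail is never truncated. Training
targets order the other codes by descending training-set frequency (the
ordering is otherwise unconstrained, and a canonical order makes the
sequence distribution learnable). A `model_scale` pointing at a checkpoint
replaces the random initialization, mirroring fine-tuning from pretrained
weights.

Decoding is greedy (the decoding strategy is otherwise unspecified and
temperature-0 is deterministic). The first parsable code token is the main
code; tokens after `#@#` are secondary; duplicates keep their first
occurrence; unparsable tokens are dropped with a warning; a decode with no
parsable main code yields the flagged *no principal diagnosis* result
rather than an exception. A generated code's confidence is the geometric
mean of its token probabilities — "averaged accumulated conditional
probabilities" read as a length-invariant mean of log-probabilities; an
arithmetic-mean variant sits behind `prob_average="arithmetic"`.

Both engines run on a small in-repo reverse-mode autodiff core
(`autoicd._autograd`) over numpy arrays: model arithmetic is float32 (the
reported probabilities are float64), gradients follow the tape in reverse
topological order, and all randomness flows from explicit integer seeds,
so training logs are bit-reproducible run to run.

## Evaluation

Micro P/R/F pools true positives, false positives and false negatives over
all code instances (predicted set = {main} ∪ others vs the gold set), with
the conservative 0/0 → 0 convention; the F-measure is the harmonic mean.
Top-K scoring intersects both sides with the K training-most-frequent codes
(ties lexicographic); per-block scoring partitions counts by the code's
leading letter; main-code scoring restricts to the singleton main sets,
a flagged empty prediction counting as a false negative only.

The principal-diagnosis outcome of a case is, in order: **all correct**
(identical sets and mains), **principal diagnosis with incorrect secondary
diagnoses** (mains equal, sets differ), **no principal diagnosis** (mains
differ or absent but the sets overlap), **all incorrect** (disjoint sets).
The set-intersection boundary between the last two is the only reading
under which the four categories partition all cases. The *overall correct
rate* counts the first two outcomes.

MDC agreement: each rater's principal diagnosis is grouped into pre-MDC /
MDC 1–25 / NONE, and every category is scored one-vs-rest with Cohen
κ = (p_o − p_e)/(1 − p_e); categories unused by both raters, or with
degenerate marginals (p_e = 1), are undefined and excluded from the
arithmetic average. One-vs-rest is the only construction that yields a
per-category κ from single-label assignments. Bands follow Landis–Koch,
applied to the value rounded to two decimals because the band table is
stated at two decimals (so a κ of 0.803, falling in the 0.80–0.81 gap,
bands as substantial — matching how published agreement tables report it).

The packaged code→MDC map is a transparent chapter-range approximation of
the proprietary national grouper: ICD-10-CM chapter ranges map to the
nearest MDC, with first-match-wins sub-ranges for HIV (B20–B24 → 25),
substance use (F10–F19 → 20), hepatobiliary (K70–K87 → 7), burns
(T20–T32 → 22) and male/female genitourinary splits; congenital (Q) and
external-cause (V–Y) codes, which have no single natural MDC, map to NONE.
Any analysis needing grouper fidelity should supply its own TSV
(`prefix_start  prefix_end  mdc`).

## ICD-10-CM domain model

Codes are 3–7 characters, alphabetic first character, alphanumeric rest; a
dot after the third character is stripped on input. The leading
3-character category resolves the chapter through a packaged 21-row block
table (A00–B99 → I … Z00–Z99 → XXI). Validation is structural plus
range-based; U-category codes are rejected under the default table, and
gaps (e.g. D49, H96–H99) are rejected as unmapped. Seventh-character
extensions (including placeholder X) pass structural validation. An
optional user-supplied code dictionary tightens validation to an explicit
inventory; the full official dictionary is deliberately not shipped.

## Synthetic corpus generator

Real discharge summaries cannot be redistributed, so `autoicd.synth`
generates corpora with the structural and statistical properties the
coders rely on:

* **Sections and markup.** Chief complaint / Impression on Admission /
  Discharge Diagnosis (a `--underlying--` delimiter line and `#`-prefixed
  diagnosis lines) / History on Admission — exercising exactly what the
  cleaning stage removes.
* **Label shape.** Codes per summary follow a truncated Poisson (≥ 1) with
  mean 4.4, matching the study-scale ratio of ~568k codes over 129k
  training summaries; codes are drawn without replacement with Zipf
  weights (rank^−1.2 over 50 codes by default), giving a long-tailed
  inventory. Because head codes can appear at most once per document,
  their aggregate share saturates near 46% — skewed, but a genuinely
  extreme tail needs the study's thousands-of-codes inventory.
* **Keyword–code correlation.** Every code owns 1–3 unique trigger phrases
  built from a deterministic pseudo-English word pool disjoint from the
  500-word filler vocabulary. A code's phrase appears in its diagnosis
  line with probability 0.95 (`keyword_emit_prob`); the main code's phrase
  additionally appears in the chief-complaint and impression sections,
  giving a learnable position signal for principal-diagnosis selection.
  The 5% non-emissions bound attainable recall, so perfect scores are
  impossible by construction.
* **Splits.** Defaults follow the study's 94.27/5/0.73 scheme
  (largest-remainder rounding); held-out codes are guaranteed to occur in
  training unless `tail_leak` is set, which withholds the rarest code from
  train/val and forces it into a test summary to reproduce the
  unseen-code failure mode.

What passing on this corpus does *not* show: robustness to misspellings,
abbreviations, synonymy, negation, multi-source evidence, or a
71,900-code inventory — the generator's correlations are exact where real
clinical text is noisy, so synthetic scores are an upper bound on realism.

## Problem sizes and the recovery protocol

The synthetic-recovery evaluation (in `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses n = 2000 summaries over 50 codes with an
0.8/0.1/0.1 split — the default 0.73% test fraction would leave only 15
test documents, too few for a stable micro-F, and split fractions are
evaluation protocol rather than corpus conditions. Desk-scale model
configurations, chosen for single-CPU training: HAN with 96-d embeddings,
48/direction hidden units, batch 32, lr 1.2e-2 with 0.97/epoch decay, at
most 45 epochs, patience 12; generative coder with 64-d, 2 layers, 4
heads, 128-token window, batch 16, lr 1e-3, 10 epochs. Under this
protocol the HAN reaches held-out micro-F ≈ 0.94 and the generative coder
main-code F ≈ 0.98 (exact values depend on the seed; the acceptance script
recomputes them).

## Numerical conventions and degenerate inputs

* BCE probabilities are clamped to [1e-12, 1−1e-12]; training uses the
  logit-space formulation, which is exact and overflow-free.
* Argmax ties in inference break to the lexicographically smaller code.
* Empty documents (no tokens after cleaning) raise a dedicated error at
  the library level; the CLI logs and emits a flagged empty prediction so
  a batch run continues.
* κ with p_e = 1 is undefined (signalled as None/blank), never 0.
* P, R, F are 0 when their denominators vanish; empty evaluation inputs
  raise.
* Checkpoints are single-file npz archives stamped with a format version,
  containing config, vocabulary, code inventory and weights.

## Known limitations

* The autodiff core implements only the operations these models need; it
  is not a general-purpose framework (no GPU, no higher-order gradients).
* The default MDC map is an approximation; per-MDC κ against a real
  grouper requires a user-supplied table.
* The synthetic generator does not emulate clinical language; see above.
* Block-letter evaluation scores code instances, not whole documents —
  document-level letter scoring would need an explicit aggregation choice.
* The coders treat the summary as one text stream; multi-section EMR
  selection is out of scope.
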