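# emoattn

Depression detection from social-media posts with an **emotion-based
attention network**: a two-branch neural text classifier for researchers in
clinical NLP and computational mental health who want an inspectable,
dependency-light reference implementation.

Posts written by depressed users carry distinctive emotional vocabulary —
more negative words, fewer positive words — and that signal is easy for a
generic sequence encoder to dilute.  The model therefore reads each post
twice:

* a **semantic branch**: Bi-LSTM over the full post with additive attention
  pooling, producing `h_att`;
* an **emotion branch**: a word-polarity lexicon routes each word occurrence
  into an ordered positive and an ordered negative sub-sequence, each
  encoded by its own Bi-LSTM + attention (`h_pos`, `h_neg`) and fused by a
  learnable convex gate

  `h_emo = θ·h_pos + (1−θ)·h_neg`, `θ = σ(v·[h_pos; h_neg] + b₀) ∈ [0, 1]`.

The classifier is `y = softmax(W·[h_att; h_emo] + b)` trained with
cross-entropy (Adam, batch 128, Bi-LSTM unit size 64), evaluated with
stratified 10-fold cross-validation on accuracy / precision / recall / F1
(depression-indicative = positive class).  Ablations are built in:
semantic-only (SUN), emotion-only (EUN), single emotion unit, fixed θ=0.5,
concatenate fusion, and plain LSTM / Bi-LSTM (+attention) baselines.

The network — LSTM cells, attention, fusion gate, backprop and Adam — is
implemented in NumPy with hand-written gradients that the test-suite checks
against finite differences, so every quantity (attention weights α, gate
value θ) is directly inspectable.

A synthetic-corpus generator reproduces the lexical statistics this
architecture exploits (class imbalance ≈ 1293:549; emotion-word rates
8.62%/6.70% for depression posts vs 9.41%/4.85% for standard posts), so the
whole pipeline runs with no external data.

## Worked example

```python
import emoattn as ea

lexicon = ea.bundled_lexicon()
post = ea.make_example_posts()[0]          # a depression-indicative post
split = ea.split_by_polarity(ea.tokenize(post.text), lexicon)
print(split.neg_tokens)
```

prints

```
['horrible', 'die', 'stupid', 'sick']
```

— the negative emotional part the emotion branch will encode, in original
word order.  Training end to end (`examples/03_train_and_inspect.py`, ~1
minute on one CPU) prints

```
epoch losses: [0.684, 0.626, 0.517, 0.3, 0.126, 0.037]
held-out accuracy 1.000, F1 1.000
label=1 pred=1 p(depression)=1.000 theta=0.129
```

the falling training loss, the held-out metrics on a strongly separable
synthetic corpus, and per-post diagnostics: `p(depression)` is `y[1]`, and
`theta = 0.129` means the fused emotion vector for this depression-indicative
post leans heavily on the negative branch.  The other scripts in `examples/` demonstrate corpus generation and
statistics, polarity splitting, and the ablation table.

A thin CLI wraps the same functions:

```bash
emoattn synth --n 1842 --seed 0 --out corpus.jsonl --lexicon-out lex.tsv
emoattn stats --corpus corpus.jsonl --lexicon lex.tsv --out stats/
emoattn cv --corpus corpus.jsonl --lexicon lex.tsv --folds 10 --out run/
emoattn ablate --corpus corpus.jsonl --lexicon lex.tsv \
    --variants EAN,SUN,EUN --seeds 0,1,2 --out ablation/
```

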