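"""Descriptive corpus statistics: emotion-word percentage tables,
per-class word-frequency lists, and the fusion-coefficient (theta) report.

The percentage of positive emotion words in a class is

    100 * (# tokens with positive lexicon score) / (# all tokens)

counted after tokenization and stop-word removal (and likewise for negative
words); the denominator choice — all non-stop-word tokens of the class — is
configurable but is the reading that yields small single-digit percentages
on forum text.  Stop-word removal applies only here, never to model inputs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import LabeledPost, tokenize
from .emotion_lexicon import PolarityLexicon, bundled_stopwords

CLASS_NAMES = {1: "depression", 0: "standard"}


@dataclass
class ClassEmotionRow:
    positive_pct: float
    negative_pct: float
    total_tokens: int


@dataclass
class EmotionPercentageTable:
    """Per-class percentages of positive and negative emotion tokens."""

    rows: dict[str, ClassEmotionRow]

    def as_dict(self) -> dict:
        return {
            cls: {
                "positive_pct": row.positive_pct,
                "negative_pct": row.negative_pct,
                "total_tokens": row.total_tokens,
            }
            for cls, row in self.rows.items()
        }


@dataclass
class WordFrequencyReport:
    """Ranked (word, count) lists per class: all / positive / negative words."""

    rows: dict[str, dict[str, list[tuple[str, int]]]]
    top_k: int

    def as_dict(self) -> dict:
        return {
            cls: {kind: [[w, c] for w, c in lst] for kind, lst in kinds.items()}
            for cls, kinds in self.rows.items()
        }


def _class_token_counts(
    corpus: Sequence[LabeledPost],
    stopwords: Iterable[str] | None,
) -> dict[int, Counter]:
    stop = frozenset(bundled_stopwords() if stopwords is None else stopwords)
    counts: dict[int, Counter] = {0: Counter(), 1: Counter()}
    for post in corpus:
        counts[post.label].update(
            t for t in tokenize(post.text) if t not in stop)
    return counts


def emotion_percentages(
    corpus: Sequence[LabeledPost],
    lexicon: PolarityLexicon,
    stopwords: Iterable[str] | None = None,
) -> EmotionPercentageTable:
    """Percentage of positive / negative emotion tokens per class.

    A token is positive (negative) iff its lexicon score is > 0 (< 0); the
    denominator is the class's total token count after stop-word removal.
    Pass ``stopwords=()`` to disable removal.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    counts = _class_token_counts(corpus, stopwords)
    rows: dict[str, ClassEmotionRow] = {}
    for label, counter in counts.items():
        total = sum(counter.values())
        pos = sum(c for w, c in counter.items() if lexicon.score(w) > 0)
        neg = sum(c for w, c in counter.items() if lexicon.score(w) < 0)
        rows[CLASS_NAMES[label]] = ClassEmotionRow(
            positive_pct=100.0 * pos / total if total else 0.0,
            negative_pct=100.0 * neg / total if total else 0.0,
            total_tokens=total,
        )
    return EmotionPercentageTable(rows)


def word_frequencies(
    corpus: Sequence[LabeledPost],
    lexicon: PolarityLexicon,
    stopwords: Iterable[str] | None = None,
    k: int = 50,
) -> WordFrequencyReport:
    """Top-k word lists per class: all words, positive words, negative words.

    Ranking is count-descending with lexicographic tie-breaks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = _class_token_counts(corpus, stopwords)

    def ranked(counter: Counter, pred) -> list[tuple[str, int]]:
        items = [(w, c) for w, c in counter.items() if pred(w)]
        items.sort(key=lambda wc: (-wc[1], wc[0]))
        return items[:k]

    rows = {}
    for label, counter in counts.items():
        rows[CLASS_NAMES[label]] = {
            "all": ranked(counter, lambda w: True),
            "positive": ranked(counter, lambda w: lexicon.score(w) > 0),
            "negative": ranked(counter, lambda w: lexicon.score(w) < 0),
        }
    return WordFrequencyReport(rows=rows, top_k=k)


def theta_report(diagnostics: Sequence[Mapping] | str | Path) -> dict:
    """Summarise the fusion coefficient theta over per-post diagnostics.

    Accepts the diagnostic records produced by ``EanModel.diagnostics`` (or
    a JSONL path of them).  Reports per-post (theta, 1-theta) shares and
    per-class mean theta, and flags whether the depression class on average
    weighs the negative branch more (mean(1-theta) > 0.5), the qualitative
    behaviour expected of the dynamic fusion gate on this task.
    """
    if isinstance(diagnostics, (str, Path)):
        with open(diagnostics, encoding="utf-8") as fh:
            diagnostics = [json.loads(line) for line in fh if line.strip()]
    records = list(diagnostics)
    if not records:
        raise ValueError("no diagnostic records supplied")
    for i, rec in enumerate(records):
        if "theta" not in rec:
            raise ValueError(
                f"record {i} has no theta (variant without a fusion gate, "
                "e.g. concatenate fusion, cannot produce a theta report)")

    per_post = [{
        "theta": float(r["theta"]),
        "one_minus_theta": 1.0 - float(r["theta"]),
        "label": r.get("label"),
    } for r in records]

    per_class: dict[str, dict] = {}
    for label in (0, 1):
        thetas = np.array([p["theta"] for p in per_post if p["label"] == label])
        if thetas.size:
            per_class[CLASS_NAMES[label]] = {
                "n": int(thetas.size),
                "mean_theta": float(thetas.mean()),
                "mean_one_minus_theta": float(1.0 - thetas.mean()),
            }
    dep = per_class.get("depression")
    flag = bool(dep and dep["mean_one_minus_theta"] > 0.5)
    return {
        "per_post": per_post,
        "per_class": per_class,
        "depression_prefers_negative": flag,
    }
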