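"""Corpus reading/writing, tokenization, vocabularies and word embeddings.

The classifier consumes social-media posts labelled as depression-indicative
(class 1) or standard (class 0).  This module owns everything between the
raw corpus file and the integer id sequences the network embeds: JSONL/CSV
parsing, a contraction-preserving tokenizer, frequency-ordered vocabularies
with reserved PAD/UNK slots, and GloVe-text embedding loading with seeded
random initialisation for out-of-vocabulary words.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

#: default label mapping: strings mapped case-insensitively to the binary class
DEFAULT_LABEL_MAP = {
    "depression": 1,
    "nondepression": 0,
    "standard": 0,
    "1": 1,
    "0": 0,
}


class CorpusFormatError(ValueError):
    """Raised when a corpus record violates the file contract."""


@dataclass(frozen=True)
class LabeledPost:
    """One social-media post with its binary depression label.

    ``label`` is 1 for depression-indicative posts and 0 for standard posts.
    """

    text: str
    label: int

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("post text must be non-empty after stripping")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class TokenSequence:
    """A tokenized post mapped to vocabulary ids, optionally padded.

    ``length`` counts real (pre-padding) tokens; after :func:`encode_and_pad`
    the id list has the configured fixed length with PAD only at the tail.
    """

    tokens: list[str]
    ids: list[int]
    length: int

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.ids):
            raise ValueError("tokens and ids must have equal length")


@dataclass
class Vocabulary:
    """Word-to-index map with reserved PAD=0 and UNK=1 entries."""

    word_to_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.word_to_index.setdefault(PAD_TOKEN, PAD_INDEX)
        self.word_to_index.setdefault(UNK_TOKEN, UNK_INDEX)

    def __len__(self) -> int:
        return len(self.word_to_index)

    def __contains__(self, word: str) -> bool:
        return word in self.word_to_index

    def index(self, word: str) -> int:
        return self.word_to_index.get(word, UNK_INDEX)

    @property
    def index_to_word(self) -> list[str]:
        out = [""] * len(self.word_to_index)
        for w, i in self.word_to_index.items():
            out[i] = w
        return out


@dataclass
class EmbeddingMatrix:
    """V x d word-embedding table; row 0 (PAD) is fixed at zero."""

    matrix: np.ndarray
    provenance: str  # "pretrained" | "random"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite values")
        if np.any(self.matrix[PAD_INDEX] != 0.0):
            raise ValueError("PAD row must be the zero vector")

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])


# --------------------------------------------------------------------------
# corpus files


def _map_label(raw, label_map: Mapping[str, int], where: str) -> int:
    if isinstance(raw, bool):
        raise CorpusFormatError(f"{where}: boolean label not allowed")
    if isinstance(raw, (int, np.integer)):
        if raw in (0, 1):
            return int(raw)
        raise CorpusFormatError(f"{where}: integer label must be 0 or 1, got {raw}")
    key = str(raw).strip().lower()
    if key not in label_map:
        allowed = ", ".join(sorted(label_map))
        raise CorpusFormatError(
            f"{where}: unknown label {raw!r}; allowed values: {allowed}"
        )
    return label_map[key]


def read_corpus(
    path: str | Path,
    format: str | None = None,
    label_map: Mapping[str, int] | None = None,
) -> list[LabeledPost]:
    """Read a labeled post corpus from JSONL or CSV.

    JSONL records look like ``{"text": "...", "label": "depression"}``; CSV
    files carry a ``text,label`` header.  Label strings are mapped
    case-insensitively through ``label_map`` (default maps "depression" to 1
    and "standard"/"nondepression" to 0).  ``format`` is inferred from the
    file suffix when omitted.
    """
    path = Path(path)
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    posts: list[LabeledPost] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                where = f"{path.name}:{lineno}"
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{where}: invalid JSON ({exc})") from exc
                if "text" not in rec or "label" not in rec:
                    raise CorpusFormatError(f"{where}: record needs 'text' and 'label'")
                if not str(rec["text"]).strip():
                    raise CorpusFormatError(f"{where}: empty text")
                posts.append(
                    LabeledPost(str(rec["text"]), _map_label(rec["label"], label_map, where))
                )
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"text", "label"} <= set(reader.fieldnames):
                raise CorpusFormatError(f"{path.name}: CSV header must contain text,label")
            for lineno, row in enumerate(reader, start=2):
                where = f"{path.name}:{lineno}"
                text = row.get("text") or ""
                if not text.strip():
                    raise CorpusFormatError(f"{where}: empty text")
                posts.append(LabeledPost(text, _map_label(row["label"], label_map, where)))
    return posts


def write_corpus(posts: Iterable[LabeledPost], path: str | Path) -> None:
    """Write posts as JSONL with string labels ("depression"/"standard")."""
    names = {1: "depression", 0: "standard"}
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps({"text": post.text, "label": names[post.label]},
                                ensure_ascii=False) + "\n")


# --------------------------------------------------------------------------
# tokenization

# word = alphanumeric runs, optionally glued by internal apostrophes so
# contractions ("i'm", "can't", "don't") survive as single tokens
_WORD_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)
_APOSTROPHES = {"’": "'", "‘": "'", "ʼ": "'"}


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumerics, preserving contractions.

    Curly apostrophes are normalised to ``'`` first.  An empty result is
    replaced by a single UNK token so every post has length >= 1.
    """
    for fancy, plain in _APOSTROPHES.items():
        text = text.replace(fancy, plain)
    text = unicodedata.normalize("NFKC", text).lower()
    tokens = _WORD_RE.findall(text)
    return tokens if tokens else [UNK_TOKEN]


# --------------------------------------------------------------------------
# vocabulary


def build_vocab(corpus: Sequence[LabeledPost], min_count: int = 1) -> Vocabulary:
    """Build a vocabulary of tokens occurring at least ``min_count`` times.

    Index order is deterministic: frequency descending, ties broken
    lexicographically, after the reserved PAD and UNK slots.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for post in corpus:
        counts.update(tokenize(post.text))
    ordered = sorted(
        (w for w, c in counts.items() if c >= min_count and w not in (PAD_TOKEN, UNK_TOKEN)),
        key=lambda w: (-counts[w], w),
    )
    vocab = Vocabulary()
    for w in ordered:
        vocab.word_to_index[w] = len(vocab.word_to_index)
    return vocab


# --------------------------------------------------------------------------
# embeddings


def load_embeddings(
    path: str | Path | None,
    vocab: Vocabulary,
    dim: int = 300,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Load GloVe-text embeddings for a vocabulary.

    In-vocabulary rows are copied from the file; missing words and UNK are
    initialised uniform(-0.05, 0.05) from ``seed`` so they stay trainable;
    the PAD row is zero.  With ``path=None`` the whole table (except PAD) is
    seeded-random and ``provenance`` is "random".
    """
    rng = np.random.default_rng(seed)
    mat = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
    mat[PAD_INDEX] = 0.0
    if path is None:
        return EmbeddingMatrix(mat, provenance="random")

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: expected {dim} values, got {len(values)}"
                )
            if word in vocab:
                idx = vocab.index(word)
                if idx not in (PAD_INDEX, UNK_INDEX):
                    mat[idx] = [float(v) for v in values]
    mat[PAD_INDEX] = 0.0
    return EmbeddingMatrix(mat, provenance="pretrained")


# --------------------------------------------------------------------------
# encoding


def encode_and_pad(
    post: LabeledPost | str,
    vocab: Vocabulary,
    max_len: int,
) -> TokenSequence:
    """Tokenize, map to ids (OOV -> UNK), truncate to the first ``max_len``
    tokens and pad the tail with PAD."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    text = post.text if isinstance(post, LabeledPost) else post
    tokens = tokenize(text)[:max_len]
    ids = [vocab.index(t) for t in tokens]
    n = len(tokens)
    tokens = tokens + [PAD_TOKEN] * (max_len - n)
    ids = ids + [PAD_INDEX] * (max_len - n)
    return TokenSequence(tokens=tokens, ids=ids, length=n)


def encode_tokens(tokens: Sequence[str], vocab: Vocabulary, max_len: int) -> TokenSequence:
    """Like :func:`encode_and_pad` but for an already-tokenized list.

    An empty token list yields the all-PAD sequence with ``length`` 0 (the
    degenerate case used for empty emotional sides)."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    toks = list(tokens)[:max_len]
    ids = [vocab.index(t) for t in toks]
    n = len(toks)
    return TokenSequence(
        tokens=toks + [PAD_TOKEN] * (max_len - n),
        ids=ids + [PAD_INDEX] * (max_len - n),
        length=n,
    )
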