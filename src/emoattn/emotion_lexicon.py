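"""Word-polarity lexicon and polarity splitting of posts.

The emotion branch of the network does not read the whole post: a polarity
lexicon (a word -> signed score map, standing in for a sentiment knowledge
base queried per word) routes each token occurrence into an ordered positive
sub-sequence (score > 0) or negative sub-sequence (score < 0).  Neutral and
unknown words are dropped from both sides — the semantic branch already sees
the full text.  The two sub-sequences are then embedded exactly like the
full post and feed the positive / negative emotion encoders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .corpus_io import TokenSequence, Vocabulary, encode_tokens

logger = logging.getLogger(__name__)


@dataclass
class PolarityLexicon:
    """Map from word to signed polarity score; absent words are neutral (0)."""

    scores: dict[str, float] = field(default_factory=dict)
    name: str = "lexicon"

    def __post_init__(self) -> None:
        for w, s in self.scores.items():
            if not (s == s and abs(s) != float("inf")):
                raise ValueError(f"non-finite score for word {w!r}")

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, word: str) -> bool:
        return word in self.scores

    def score(self, word: str) -> float:
        return self.scores.get(word, 0.0)


@dataclass
class PolaritySplit:
    """The ordered positive and negative word sub-sequences of one post."""

    pos_tokens: list[str]
    neg_tokens: list[str]
    source_length: int


def load_lexicon(path: str | Path, name: str | None = None) -> PolarityLexicon:
    """Read a TSV lexicon: ``word<TAB>score`` per line, ``#`` comments ignored.

    Duplicate words keep the last occurrence (a warning is logged).
    """
    path = Path(path)
    scores: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 'word<TAB>score'")
            word, raw = parts
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: unparseable score {raw!r}"
                ) from exc
            if word in scores:
                logger.warning("%s:%d: duplicate word %r, last occurrence wins",
                               path.name, lineno, word)
            scores[word] = score
    return PolarityLexicon(scores, name=name or path.stem)


def bundled_lexicon() -> PolarityLexicon:
    """The small lexicon bundled for tests and demos.

    It scores the high-frequency positive and negative words observed in
    depression-forum posts (plus a handful of intensity-graded negatives
    such as "horrible", "die", "stupid", "sick").
    """
    ref = resources.files("emoattn.data").joinpath("bundled_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_lexicon(path, name="bundled")


def bundled_stopwords() -> frozenset[str]:
    """The bundled English stop-word list (plain text, one word per line)."""
    ref = resources.files("emoattn.data").joinpath("stopwords_en.txt")
    words = ref.read_text(encoding="utf-8").split()
    return frozenset(words)


def split_by_polarity(tokens: Sequence[str], lexicon: PolarityLexicon) -> PolaritySplit:
    """Route each token occurrence by the sign of its lexicon score.

    score > 0 -> positive side, score < 0 -> negative side, score == 0 (or
    absent) -> dropped.  Original within-post order is preserved on both
    sides; either side may come out empty.
    """
    if not tokens:
        raise ValueError("token list must be non-empty")
    pos: list[str] = []
    neg: list[str] = []
    for tok in tokens:
        s = lexicon.score(tok)
        if s > 0:
            pos.append(tok)
        elif s < 0:
            neg.append(tok)
    return PolaritySplit(pos_tokens=pos, neg_tokens=neg, source_length=len(tokens))


def encode_split(
    split: PolaritySplit,
    vocab: Vocabulary,
    max_len_emo: int = 100,
) -> tuple[TokenSequence, TokenSequence]:
    """Encode both sides of a polarity split as padded id sequences.

    An empty side yields the all-PAD sequence with ``length`` 0; downstream
    the encoder emits a zero context vector for such sequences, so an absent
    emotional part contributes nothing to the fusion.
    """
    pos_seq = encode_tokens(split.pos_tokens, vocab, max_len_emo)
    neg_seq = encode_tokens(split.neg_tokens, vocab, max_len_emo)
    return pos_seq, neg_seq
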