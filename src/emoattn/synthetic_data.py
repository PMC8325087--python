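"""Synthetic labeled corpora with the lexical statistics the EAN exploits.

Real depression-forum corpora show two lexical regularities the emotion
branch is built around: depression-indicative posts carry a *higher* rate of
negative-emotion words and a *lower* rate of positive-emotion words than
standard posts (defaults 6.70% vs 4.85% negative and 8.62% vs 9.41%
positive), and the two classes are imbalanced roughly 1293:549.  The
generator emulates exactly these token-level statistics — bag-style word
emission, no syntax — plus one extra knob the real data does not expose:
``signal_strength`` makes emotion-word *identity* (not just rate)
class-specific, so corpora can be built where the emotion vocabulary is
provably the only label signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np

from .corpus_io import LabeledPost
from .emotion_lexicon import PolarityLexicon, bundled_lexicon

#: class prior of the reference corpus: 1293 depression / 1842 total posts
DEFAULT_CLASS_PRIOR = 1293 / 1842

#: per-class emotion-word token rates of the reference corpus
DEFAULT_RATES = {
    "pos_rate_dep": 0.0862,
    "neg_rate_dep": 0.0670,
    "pos_rate_std": 0.0941,
    "neg_rate_std": 0.0485,
}


@dataclass(frozen=True)
class WordPools:
    """Disjoint neutral / positive / negative vocabularies with sub-pools.

    Each emotion pool is partitioned into a shared half and two
    class-exclusive quarters; ``signal_strength`` decides how often a draw
    comes from the drawing class's exclusive quarter.
    """

    neutral: tuple[str, ...]
    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def subpools(self, kind: str) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
        """(shared, depression-exclusive, standard-exclusive) for a pool."""
        pool = getattr(self, kind)
        n = len(pool)
        half, q3 = n // 2, n // 2 + (n - n // 2) // 2
        return pool[:half], pool[half:q3], pool[q3:]

    def lexicon(self) -> PolarityLexicon:
        scores = {w: 0.5 for w in self.positive}
        scores.update({w: -0.5 for w in self.negative})
        return PolarityLexicon(scores, name="synthetic-pools")


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Generative knobs; generation is a pure function of this spec."""

    n_posts: int = 1842
    class_prior: float = DEFAULT_CLASS_PRIOR
    pos_rate_dep: float = DEFAULT_RATES["pos_rate_dep"]
    neg_rate_dep: float = DEFAULT_RATES["neg_rate_dep"]
    pos_rate_std: float = DEFAULT_RATES["pos_rate_std"]
    neg_rate_std: float = DEFAULT_RATES["neg_rate_std"]
    signal_strength: float = 0.8
    signal_pools: tuple[str, ...] = ("positive", "negative")
    length_mean: float = 60.0
    min_length: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.pos_rate_dep, self.neg_rate_dep,
                 self.pos_rate_std, self.neg_rate_std)
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise ValueError("emotion rates must lie in [0, 1]")
        if self.pos_rate_dep + self.neg_rate_dep > 1.0:
            raise ValueError("depression-class pos+neg rate exceeds 1")
        if self.pos_rate_std + self.neg_rate_std > 1.0:
            raise ValueError("standard-class pos+neg rate exceeds 1")
        if not 0.0 <= self.class_prior <= 1.0:
            raise ValueError("class_prior must lie in [0, 1]")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not set(self.signal_pools) <= {"positive", "negative"}:
            raise ValueError("signal_pools entries must be 'positive'/'negative'")


def build_word_pools(
    seed: int = 0,
    n_neutral: int = 500,
    n_positive: int = 100,
    n_negative: int = 100,
) -> tuple[WordPools, PolarityLexicon]:
    """Construct disjoint word pools and the matching flat-score lexicon.

    The positive and negative pools start from the bundled high-frequency
    emotion words observed in depression-forum posts and are padded with
    synthetic word strings up to the requested sizes; neutral words are all
    synthetic.  The order within each pool is a seeded shuffle, so pools are
    deterministic per seed.
    """
    lex = bundled_lexicon()
    base_pos = sorted(w for w, s in lex.scores.items() if s > 0)
    base_neg = sorted(w for w, s in lex.scores.items() if s < 0)
    pos = list(base_pos[:n_positive])
    neg = list(base_neg[:n_negative])
    pos += [f"glimmer{i:03d}" for i in range(n_positive - len(pos))]
    neg += [f"gloom{i:03d}" for i in range(n_negative - len(neg))]
    neutral = [f"topic{i:04d}" for i in range(n_neutral)]
    rng = np.random.default_rng(seed)
    for pool in (neutral, pos, neg):
        rng.shuffle(pool)
    pools = WordPools(neutral=tuple(neutral), positive=tuple(pos),
                      negative=tuple(neg))
    return pools, pools.lexicon()


def generate_corpus(
    spec: SyntheticCorpusSpec,
) -> tuple[list[LabeledPost], PolarityLexicon]:
    """Generate a labeled corpus (and its lexicon) from a spec.

    Per post: the label is Bernoulli(class_prior); length is
    Poisson(length_mean) resampled to be >= min_length; each token is
    positive-pool with the class's positive rate, negative-pool with its
    negative rate, else neutral.  Within a signal pool, a draw is taken from
    the class-exclusive sub-pool with probability ``signal_strength`` and
    from the shared sub-pool otherwise, so ``signal_strength = 0`` leaves
    emotion-word identities class-independent while rates still differ.
    """
    rng = np.random.default_rng(spec.seed)
    pools, lexicon = build_word_pools(spec.seed)
    sub = {k: pools.subpools(k) for k in ("positive", "negative")}
    neutral = pools.neutral

    posts: list[LabeledPost] = []
    for _ in range(spec.n_posts):
        label = int(rng.random() < spec.class_prior)
        length = int(rng.poisson(spec.length_mean))
        while length < spec.min_length:
            length = int(rng.poisson(spec.length_mean))
        if label == 1:
            p_pos, p_neg = spec.pos_rate_dep, spec.neg_rate_dep
        else:
            p_pos, p_neg = spec.pos_rate_std, spec.neg_rate_std
        u = rng.random(length)
        tokens: list[str] = []
        for ui in u:
            if ui < p_pos:
                kind = "positive"
            elif ui < p_pos + p_neg:
                kind = "negative"
            else:
                tokens.append(neutral[rng.integers(len(neutral))])
                continue
            shared, dep_only, std_only = sub[kind]
            use_exclusive = (kind in spec.signal_pools
                             and rng.random() < spec.signal_strength)
            if use_exclusive:
                pool = dep_only if label == 1 else std_only
            else:
                pool = shared
            tokens.append(pool[rng.integers(len(pool))])
        posts.append(LabeledPost(" ".join(tokens), label))
    return posts, lexicon


def make_example_posts() -> list[LabeledPost]:
    """Three short reference posts (two depression-indicative, one standard)
    used for smoke tests and documentation examples."""
    return [
        LabeledPost(
            "Today, I feel so horrible, it makes me want to die I made a fool "
            "of myself at work, felt so stupid after the meeting so I left "
            "work, told the boss I’m sick. Spent the remaining afternoon in bed.",
            1,
        ),
        LabeledPost(
            "That feeling when you hate who you are as a person but can’t get "
            "yourself to change because you are so used to being like this for "
            "the past several years. I’ve become a shitty person. The thought "
            "of change seems impossible to me at this point.",
            1,
        ),
        LabeledPost("Looking for cool ways to tell parents my wife is pregnant.", 0),
    ]


def write_spec_sidecar(spec: SyntheticCorpusSpec, path: str | Path) -> None:
    """Record the full generative spec next to an emitted corpus."""
    d = asdict(spec)
    d["signal_pools"] = list(d["signal_pools"])
    Path(path).write_text(json.dumps(d, indent=2), encoding="utf-8")
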