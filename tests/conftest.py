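import numpy as np
import pytest

import emoattn as ea
from emoattn.ean_model import ModelConfig, build_variant


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small synthetic corpus + lexicon shared by fast tests."""
    spec = ea.SyntheticCorpusSpec(n_posts=60, seed=5, length_mean=15, min_length=5)
    return ea.generate_corpus(spec)


@pytest.fixture(scope="session")
def tiny_vocab(tiny_corpus):
    posts, _ = tiny_corpus
    return ea.build_vocab(posts)


@pytest.fixture()
def tiny_model_factory(tiny_corpus, tiny_vocab):
    posts, lexicon = tiny_corpus

    def make(variant="EAN", **overrides):
        defaults = dict(embed_dim=8, hidden_size=4, max_len=24, max_len_emo=8,
                        seed=0)
        defaults.update(overrides)
        if variant == "LSTM":
            defaults.setdefault("hidden_size", 6)
        cfg = ModelConfig(variant=variant, **defaults)
        return build_variant(variant, cfg, vocab=tiny_vocab, lexicon=lexicon)

    return make


@pytest.fixture(scope="session")
def example_posts():
    return ea.make_example_posts()


def rel_err(num: float, ana: float, floor: float = 1e-7) -> float:
    return abs(num - ana) / max(floor, abs(num) + abs(ana))


@pytest.fixture(scope="session")
def gradcheck():
    """Central finite-difference gradient checker for a model on a batch."""

    def check(model, batch, n_per_param=4, eps=1e-6, tol=5e-5):
        _, grads = model.loss_and_grads(batch)
        rng = np.random.default_rng(123)
        for name, g in grads.items():
            flat = model.params[name].ravel()
            ga = np.asarray(g).ravel()
            idxs = rng.choice(flat.size, size=min(n_per_param, flat.size),
                              replace=False)
            for ix in idxs:
                old = flat[ix]
                flat[ix] = old + eps
                lp, _ = model.loss_and_grads(batch)
                flat[ix] = old - eps
                lm, _ = model.loss_and_grads(batch)
                flat[ix] = old
                num = (lp - lm) / (2 * eps)
                # absolute floor absorbs finite-difference noise on tiny entries
                assert abs(num - ga[ix]) <= tol * max(1.0, abs(num) + abs(ga[ix])), (
                    f"{name}[{ix}]: numeric {num:.3e} vs analytic {ga[ix]:.3e}")

    return check
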