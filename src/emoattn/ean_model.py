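"""The emotion-based attention network (EAN) and its ablation variants.

The full model classifies a post with two branches that share one word
embedding table:

* **semantic branch** (SUN): Bi-LSTM over the whole post followed by
  additive attention pooling, producing ``h_att`` (size 2u);
* **emotion branch** (EUN): the lexicon-routed positive and negative word
  sub-sequences are each encoded by their own Bi-LSTM + attention, producing
  ``h_pos`` and ``h_neg``, fused by a learnable convex gate::

      h_emo = theta * h_pos + (1 - theta) * h_neg,   theta in [0, 1]

The final representation ``f_final = [h_att ; h_emo]`` feeds a softmax
classifier trained with cross-entropy.  Ablations drop a branch, pin
``theta = 0.5``, replace the gate by concatenation, or reduce to plain
LSTM / Bi-LSTM (+ attention) baselines.

Everything is NumPy with hand-written backward passes (see ``_nn``); the
op-level functions (:func:`lstm_step`, :func:`bilstm_encode`,
:func:`attention_pool`, :func:`dynamic_fuse`) expose the same computations
on single examples for inspection and testing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _nn
from .corpus_io import (
    PAD_INDEX,
    EmbeddingMatrix,
    LabeledPost,
    TokenSequence,
    Vocabulary,
    encode_and_pad,
    tokenize,
)
from .emotion_lexicon import PolarityLexicon, encode_split, split_by_polarity

logger = logging.getLogger(__name__)

VALID_VARIANTS = (
    "EAN",
    "SUN",
    "EUN",
    "SUN+positive",
    "SUN+negative",
    "LSTM",
    "BiLSTM",
    "BiLSTM+Att",
    "EAN_fixed_fusion",
    "EAN_concat_fusion",
)

_EPS = 1e-12


@dataclass
class ModelConfig:
    """Architecture and encoding hyper-parameters.

    ``hidden_size`` is the per-direction LSTM unit size (64 for all
    bidirectional variants; the unidirectional LSTM baseline uses 128).
    ``fusion_mode`` selects how theta is realised: ``per_example`` derives it
    from a sigmoid over [h_pos; h_neg]; ``global`` trains one scalar shared
    by all posts (also squashed by a sigmoid so theta stays in [0, 1]).
    """

    variant: str = "EAN"
    hidden_size: int = 64
    embed_dim: int = 300
    max_len: int = 400
    max_len_emo: int = 100
    fusion_mode: str = "per_example"  # per_example | global
    init_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VALID_VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid: {', '.join(VALID_VARIANTS)}"
            )
        if self.fusion_mode not in ("per_example", "global"):
            raise ValueError("fusion_mode must be 'per_example' or 'global'")


# ---------------------------------------------------------------------------
# op-level dataclasses (single-example API)


@dataclass
class LstmCellParams:
    """Gate weights acting on the concatenated [h_{t-1}; x_t] vector."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def units(self) -> int:
        return self.W_i.shape[0]

    @classmethod
    def random(cls, rng: np.random.Generator, d_in: int, units: int,
               scale: float = 0.05) -> "LstmCellParams":
        def w():
            return rng.uniform(-scale, scale, size=(units, units + d_in))
        return cls(W_i=w(), W_f=w(), W_c=w(), W_o=w(),
                   b_i=np.zeros(units), b_f=np.zeros(units),
                   b_c=np.zeros(units), b_o=np.zeros(units))

    def to_fused(self) -> dict[str, np.ndarray]:
        """Convert to the fused (Wx, Wh, b) layout of the batched layer."""
        u = self.units
        Wcat = np.concatenate([self.W_i, self.W_f, self.W_c, self.W_o], axis=0)
        Wh = Wcat[:, :u].T            # (u, 4u)
        Wx = Wcat[:, u:].T            # (d_in, 4u)
        b = np.concatenate([self.b_i, self.b_f, self.b_c, self.b_o])
        return {"Wx": Wx, "Wh": Wh, "b": b}


@dataclass
class LstmState:
    """Hidden state, memory cell and gate activations after one step."""

    h: np.ndarray
    c: np.ndarray
    i: np.ndarray | None = None
    f: np.ndarray | None = None
    o: np.ndarray | None = None

    @classmethod
    def zeros(cls, units: int) -> "LstmState":
        return cls(h=np.zeros(units), c=np.zeros(units))


@dataclass
class EncodedSequence:
    """Per-position Bi-LSTM outputs H (n x 2u) with a validity mask."""

    H: np.ndarray
    mask: np.ndarray

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class AttentionParams:
    Wa: np.ndarray
    ba: np.ndarray
    q: np.ndarray

    @classmethod
    def random(cls, rng: np.random.Generator, d_in: int, d_att: int,
               scale: float = 0.05) -> "AttentionParams":
        return cls(Wa=rng.uniform(-scale, scale, size=(d_in, d_att)),
                   ba=np.zeros(d_att),
                   q=rng.uniform(-scale, scale, size=d_att))


@dataclass
class AttentionOutput:
    weights: np.ndarray
    context: np.ndarray


@dataclass
class FusionGate:
    """Realisation of the convex fusion coefficient theta.

    ``per_example``: theta = sigmoid(v . [h_pos; h_neg] + b0), one value per
    post.  ``global``: theta = sigmoid(s) with a single trainable scalar.
    ``fixed``: theta pinned (0.5 in the fixed-fusion ablation).
    """

    mode: str = "per_example"
    v: np.ndarray | None = None
    b0: float = 0.0
    s: float = 0.0
    theta_fixed: float = 0.5


# ---------------------------------------------------------------------------
# op-level functions


def lstm_step(x_t: np.ndarray, prev: LstmState, params: LstmCellParams) -> LstmState:
    """One LSTM recurrence step on a single input vector.

    Gates: f_t, i_t, o_t are sigmoid of W.[h;x]+b; candidate tanh; then
    c_t = f_t*c_{t-1} + i_t*c~_t and h_t = o_t*tanh(c_t).
    """
    hx = np.concatenate([prev.h, x_t])
    if params.W_i.shape[1] != hx.shape[0]:
        raise ValueError(
            f"cell expects [h;x] of size {params.W_i.shape[1]}, got {hx.shape[0]}"
        )
    i = _nn.sigmoid(params.W_i @ hx + params.b_i)
    f = _nn.sigmoid(params.W_f @ hx + params.b_f)
    g = np.tanh(params.W_c @ hx + params.b_c)
    o = _nn.sigmoid(params.W_o @ hx + params.b_o)
    c = f * prev.c + i * g
    h = o * np.tanh(c)
    return LstmState(h=h, c=c, i=i, f=f, o=o)


def bilstm_encode(
    seq: TokenSequence,
    emb: EmbeddingMatrix,
    fwd: LstmCellParams,
    bwd: LstmCellParams,
) -> EncodedSequence:
    """Encode one padded id sequence with a bidirectional LSTM.

    Output row t is [h_fwd_t ; h_bwd_t]; PAD positions are masked and, with
    the zero initial state carried through padding, contribute nothing.
    """
    ids = np.asarray(seq.ids)[None, :]
    mask = np.zeros_like(ids, dtype=float)
    mask[0, :seq.length] = 1.0
    X = emb.matrix[ids]
    H, _ = _nn.bilstm_forward(X, mask, fwd.to_fused(), bwd.to_fused())
    return EncodedSequence(H=H[0], mask=mask[0])


def attention_pool(enc: EncodedSequence, params: AttentionParams) -> AttentionOutput:
    """Additive attention pooling over unmasked positions.

    Empty input (all positions masked) yields a zero context with empty
    weights, the contract used for absent emotional sides.
    """
    if enc.empty:
        return AttentionOutput(weights=np.zeros(enc.H.shape[0]),
                               context=np.zeros(enc.H.shape[1]))
    ctx, alpha, _ = _nn.attention_forward(
        enc.H[None], enc.mask[None],
        {"Wa": params.Wa, "ba": params.ba, "q": params.q},
    )
    return AttentionOutput(weights=alpha[0], context=ctx[0])


def dynamic_fuse(
    h_pos: np.ndarray, h_neg: np.ndarray, gate: FusionGate,
) -> tuple[np.ndarray, float]:
    """Convex fusion h_emo = theta*h_pos + (1-theta)*h_neg; returns theta too."""
    h_pos = np.asarray(h_pos, dtype=float)
    h_neg = np.asarray(h_neg, dtype=float)
    if h_pos.shape != h_neg.shape:
        raise ValueError(f"shape mismatch: {h_pos.shape} vs {h_neg.shape}")
    if gate.mode == "fixed":
        theta = float(gate.theta_fixed)
    elif gate.mode == "global":
        theta = float(_nn.sigmoid(np.array([gate.s]))[0])
    elif gate.mode == "per_example":
        z = float(np.concatenate([h_pos, h_neg]) @ gate.v + gate.b0)
        theta = float(_nn.sigmoid(np.array([z]))[0])
    else:
        raise ValueError(f"unknown fusion mode {gate.mode!r}")
    return theta * h_pos + (1.0 - theta) * h_neg, theta


def loss(y: np.ndarray, label: int) -> float:
    """Cross-entropy -log y[label], clamped at 1e-12 (a clamp is logged)."""
    y = np.asarray(y, dtype=float)
    p = y[label]
    if p < _EPS:
        logger.warning("probability %.3g clamped to %.0e in cross-entropy", p, _EPS)
        p = _EPS
    return float(-np.log(p))


# ---------------------------------------------------------------------------
# the trainable model


class EanModel:
    """A trainable EAN variant bundling vocabulary, lexicon and parameters.

    Parameters live in ``self.params`` (name -> float64 array); gradients
    are computed by :meth:`loss_and_grads` with hand-written backprop and
    consumed by the Adam loop in :mod:`emoattn.training_eval`.
    """

    def __init__(
        self,
        config: ModelConfig,
        vocab: Vocabulary,
        lexicon: PolarityLexicon | None = None,
        embeddings: EmbeddingMatrix | None = None,
    ):
        self.config = config
        self.vocab = vocab
        self.lexicon = lexicon
        if self._uses_emotion() and lexicon is None:
            raise ValueError(f"variant {config.variant} requires a polarity lexicon")
        rng = np.random.default_rng(config.seed)
        if embeddings is None:
            mat = rng.uniform(-config.init_scale, config.init_scale,
                              size=(len(vocab), config.embed_dim))
            mat[PAD_INDEX] = 0.0
            embeddings = EmbeddingMatrix(mat, provenance="random")
        if embeddings.dim != config.embed_dim:
            raise ValueError("embedding dim does not match config.embed_dim")
        self.params: dict[str, np.ndarray] = {"E": embeddings.matrix.astype(float).copy()}
        self._init_params(rng)

    # -- architecture helpers ------------------------------------------------

    def _uses_semantic(self) -> bool:
        return self.config.variant != "EUN"

    def _uses_emotion(self) -> bool:
        return self.config.variant in (
            "EAN", "EUN", "SUN+positive", "SUN+negative",
            "EAN_fixed_fusion", "EAN_concat_fusion",
        )

    def _emotion_units(self) -> tuple[bool, bool]:
        v = self.config.variant
        if v in ("EAN", "EUN", "EAN_fixed_fusion", "EAN_concat_fusion"):
            return True, True
        if v == "SUN+positive":
            return True, False
        if v == "SUN+negative":
            return False, True
        return False, False

    def _semantic_kind(self) -> str:
        # how the semantic branch pools: attention vs final state
        v = self.config.variant
        if v == "LSTM":
            return "last_uni"
        if v == "BiLSTM":
            return "last_bi"
        return "att"  # SUN, BiLSTM+Att and all EAN variants

    def _fusion_kind(self) -> str:
        v = self.config.variant
        if v in ("EAN", "EUN"):
            return self.config.fusion_mode
        if v == "EAN_fixed_fusion":
            return "fixed"
        if v == "EAN_concat_fusion":
            return "concat"
        return "none"

    @property
    def feature_size(self) -> int:
        u = self.config.hidden_size
        v = self.config.variant
        if v == "LSTM":
            return u
        if v in ("SUN", "BiLSTM", "BiLSTM+Att", "EUN"):
            return 2 * u
        if v in ("EAN", "EAN_fixed_fusion", "SUN+positive", "SUN+negative"):
            return 4 * u
        if v == "EAN_concat_fusion":
            return 6 * u
        raise AssertionError(v)

    # -- parameter initialisation -------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        u, d, sc = cfg.hidden_size, cfg.embed_dim, cfg.init_scale

        def add_lstm(prefix: str) -> None:
            for nm, shape in _nn.lstm_param_shapes(d, u).items():
                arr = (_nn.uniform_init(rng, shape, sc) if nm != "b"
                       else np.zeros(shape))
                self.params[f"{prefix}.{nm}"] = arr

        def add_att(prefix: str) -> None:
            for nm, shape in _nn.attention_param_shapes(2 * u, 2 * u).items():
                arr = (_nn.uniform_init(rng, shape, sc) if nm != "ba"
                       else np.zeros(shape))
                self.params[f"{prefix}.{nm}"] = arr

        if self._uses_semantic():
            add_lstm("sun_f")
            if self.config.variant != "LSTM":
                add_lstm("sun_b")
            if self._semantic_kind() == "att":
                add_att("sun_att")
        use_pos, use_neg = self._emotion_units()
        if use_pos:
            add_lstm("pos_f"); add_lstm("pos_b"); add_att("pos_att")
        if use_neg:
            add_lstm("neg_f"); add_lstm("neg_b"); add_att("neg_att")
        fk = self._fusion_kind()
        if fk == "per_example":
            self.params["fuse.v"] = _nn.uniform_init(rng, (4 * u,), sc)
            self.params["fuse.b0"] = np.zeros(1)
        elif fk == "global":
            self.params["fuse.s"] = np.zeros(1)
        self.params["W"] = _nn.uniform_init(rng, (self.feature_size, 2), sc)
        self.params["b"] = np.zeros(2)

    def _sub(self, prefix: str) -> dict[str, np.ndarray]:
        n = len(prefix) + 1
        return {k[n:]: v for k, v in self.params.items() if k.startswith(prefix + ".")}

    # -- encoding ------------------------------------------------------------

    def encode_posts(self, posts: Sequence[LabeledPost | str]) -> dict:
        """Encode a batch of posts into padded id/mask arrays.

        Sequences are trimmed to the longest real length in the batch (never
        past ``max_len``), which cannot change predictions because trailing
        padding is inert by construction.
        """
        cfg = self.config
        seqs = [encode_and_pad(p, self.vocab, cfg.max_len) for p in posts]
        T = max(1, max(s.length for s in seqs))
        ids = np.array([s.ids[:T] for s in seqs])
        mask = np.zeros(ids.shape)
        for b, s in enumerate(seqs):
            mask[b, :min(s.length, T)] = 1.0
        batch = {"ids": ids, "mask": mask}
        if self._uses_emotion():
            pos_seqs, neg_seqs = [], []
            for p in posts:
                text = p.text if isinstance(p, LabeledPost) else p
                split = split_by_polarity(tokenize(text), self.lexicon)
                ps, ns = encode_split(split, self.vocab, cfg.max_len_emo)
                pos_seqs.append(ps)
                neg_seqs.append(ns)
            for nm, ss in (("pos", pos_seqs), ("neg", neg_seqs)):
                Te = max(1, max(s.length for s in ss))
                eids = np.array([s.ids[:Te] for s in ss])
                emask = np.zeros(eids.shape)
                for b, s in enumerate(ss):
                    emask[b, :min(s.length, Te)] = 1.0
                batch[f"{nm}_ids"] = eids
                batch[f"{nm}_mask"] = emask
        labels = [p.label for p in posts if isinstance(p, LabeledPost)]
        if len(labels) == len(posts):
            batch["labels"] = np.array(labels)
        return batch

    # -- forward -------------------------------------------------------------

    def _branch_forward(self, prefix: str, ids, mask, pooled: str):
        E = self.params["E"]
        X = E[ids]
        if pooled == "last_uni":
            H, ch = _nn.lstm_forward(X, mask, self._sub(f"{prefix}_f"))
            ctx = H[:, -1]
            return ctx, None, {"kind": pooled, "lstm": ch, "ids": ids, "T": ids.shape[1]}
        H, ch = _nn.bilstm_forward(X, mask, self._sub(f"{prefix}_f"),
                                   self._sub(f"{prefix}_b"))
        if pooled == "last_bi":
            u = self.config.hidden_size
            # forward state at the last position; backward state at position 0
            ctx = np.concatenate([H[:, -1, :u], H[:, 0, u:]], axis=1)
            return ctx, None, {"kind": pooled, "bilstm": ch, "ids": ids}
        ctx, alpha, ca = _nn.attention_forward(H, mask, self._sub(f"{prefix}_att"))
        return ctx, alpha, {"kind": "att", "bilstm": ch, "att": ca, "ids": ids}

    def forward(self, batch: Mapping, want_cache: bool = False):
        """Forward pass; returns (probs, diagnostics[, cache]).

        ``probs`` is (B, 2); diagnostics carry attention weights and the
        realised theta per example where the variant defines them.
        """
        caches: dict = {}
        feats: list[np.ndarray] = []
        diag: dict = {}
        B = batch["ids"].shape[0] if "ids" in batch else batch["pos_ids"].shape[0]

        if self._uses_semantic():
            ctx, alpha, c = self._branch_forward(
                "sun", batch["ids"], batch["mask"], self._semantic_kind())
            caches["sun"] = c
            feats.append(ctx)
            if alpha is not None:
                diag["alpha_sun"] = alpha

        use_pos, use_neg = self._emotion_units()
        h_pos = h_neg = None
        if use_pos:
            h_pos, a, c = self._branch_forward("pos", batch["pos_ids"],
                                               batch["pos_mask"], "att")
            caches["pos"] = c
            diag["alpha_pos"] = a
        if use_neg:
            h_neg, a, c = self._branch_forward("neg", batch["neg_ids"],
                                               batch["neg_mask"], "att")
            caches["neg"] = c
            diag["alpha_neg"] = a

        fk = self._fusion_kind()
        if fk in ("per_example", "global", "fixed"):
            if fk == "per_example":
                hcat = np.concatenate([h_pos, h_neg], axis=1)
                z = hcat @ self.params["fuse.v"] + self.params["fuse.b0"][0]
                theta = _nn.sigmoid(z)
                caches["fuse"] = {"hcat": hcat, "theta": theta}
            elif fk == "global":
                theta = np.full(B, _nn.sigmoid(self.params["fuse.s"])[0])
                caches["fuse"] = {"theta": theta}
            else:
                theta = np.full(B, 0.5)
                caches["fuse"] = {"theta": theta}
            h_emo = theta[:, None] * h_pos + (1.0 - theta[:, None]) * h_neg
            caches["fuse"].update({"h_pos": h_pos, "h_neg": h_neg})
            feats.append(h_emo)
            diag["theta"] = theta
        elif fk == "concat":
            feats.append(h_pos)
            feats.append(h_neg)
        elif use_pos:
            feats.append(h_pos)
        elif use_neg:
            feats.append(h_neg)

        F = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        logits = F @ self.params["W"] + self.params["b"]
        probs = _nn.softmax_rows(logits)
        caches["F"] = F
        caches["feat_slices"] = self._feat_slices()
        if want_cache:
            return probs, diag, caches
        return probs, diag

    def _feat_slices(self) -> dict[str, slice]:
        u2 = 2 * self.config.hidden_size
        slices: dict[str, slice] = {}
        off = 0
        if self._uses_semantic():
            w = self.config.hidden_size if self._semantic_kind() == "last_uni" else u2
            slices["sun"] = slice(off, off + w)
            off += w
        fk = self._fusion_kind()
        use_pos, use_neg = self._emotion_units()
        if fk in ("per_example", "global", "fixed"):
            slices["emo"] = slice(off, off + u2); off += u2
        elif fk == "concat":
            slices["pos"] = slice(off, off + u2); off += u2
            slices["neg"] = slice(off, off + u2); off += u2
        elif use_pos:
            slices["pos"] = slice(off, off + u2); off += u2
        elif use_neg:
            slices["neg"] = slice(off, off + u2); off += u2
        return slices

    # -- backward ------------------------------------------------------------

    def loss_and_grads(self, batch: Mapping) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy over the batch and gradients for all params."""
        labels = batch["labels"]
        probs, _, caches = self.forward(batch, want_cache=True)
        B = probs.shape[0]
        p_true = np.clip(probs[np.arange(B), labels], _EPS, None)
        loss_val = float(-np.log(p_true).mean())

        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        F = caches["F"]
        grads["W"] = F.T @ dlogits
        grads["b"] = dlogits.sum(axis=0)
        dF = dlogits @ self.params["W"].T

        sl = caches["feat_slices"]
        dE = np.zeros_like(self.params["E"])

        def back_branch(prefix: str, dctx: np.ndarray) -> None:
            c = caches[prefix]
            if c["kind"] == "att":
                dH, g_att = _nn.attention_backward(dctx, c["att"])
                for nm, g in g_att.items():
                    grads[f"{prefix}_att.{nm}"] = grads.get(f"{prefix}_att.{nm}", 0) + g
                dX, gf, gb = _nn.bilstm_backward(dH, c["bilstm"])
                for tag, gd in (("f", gf), ("b", gb)):
                    for nm, g in gd.items():
                        key = f"{prefix}_{tag}.{nm}"
                        grads[key] = grads.get(key, 0) + g
            elif c["kind"] == "last_bi":
                u = self.config.hidden_size
                dH = np.zeros(c["bilstm"]["cf"]["X"].shape[:2] + (2 * u,))
                dH[:, -1, :u] = dctx[:, :u]
                dH[:, 0, u:] = dctx[:, u:]
                dX, gf, gb = _nn.bilstm_backward(dH, c["bilstm"])
                for tag, gd in (("f", gf), ("b", gb)):
                    for nm, g in gd.items():
                        grads[f"{prefix}_{tag}.{nm}"] = g
            else:  # last_uni
                shape = c["lstm"]["X"].shape
                dH = np.zeros((shape[0], shape[1], self.config.hidden_size))
                dH[:, -1] = dctx
                dX, gf = _nn.lstm_backward(dH, c["lstm"])
                for nm, g in gf.items():
                    grads[f"{prefix}_f.{nm}"] = g
            ids = c["ids"]
            np.add.at(dE, ids.ravel(), dX.reshape(-1, dX.shape[-1]))

        if self._uses_semantic():
            back_branch("sun", np.ascontiguousarray(dF[:, sl["sun"]]))

        fk = self._fusion_kind()
        use_pos, use_neg = self._emotion_units()
        if fk in ("per_example", "global", "fixed"):
            fz = caches["fuse"]
            theta, h_pos, h_neg = fz["theta"], fz["h_pos"], fz["h_neg"]
            dh_emo = np.ascontiguousarray(dF[:, sl["emo"]])
            dh_pos = theta[:, None] * dh_emo
            dh_neg = (1.0 - theta[:, None]) * dh_emo
            dtheta = (dh_emo * (h_pos - h_neg)).sum(axis=1)
            if fk == "per_example":
                dz = dtheta * theta * (1.0 - theta)
                grads["fuse.v"] = fz["hcat"].T @ dz
                grads["fuse.b0"] = np.array([dz.sum()])
                dhcat = dz[:, None] * self.params["fuse.v"][None, :]
                u2 = 2 * self.config.hidden_size
                dh_pos = dh_pos + dhcat[:, :u2]
                dh_neg = dh_neg + dhcat[:, u2:]
            elif fk == "global":
                s = _nn.sigmoid(self.params["fuse.s"])[0]
                grads["fuse.s"] = np.array([dtheta.sum() * s * (1.0 - s)])
            back_branch("pos", dh_pos)
            back_branch("neg", dh_neg)
        elif fk == "concat":
            back_branch("pos", np.ascontiguousarray(dF[:, sl["pos"]]))
            back_branch("neg", np.ascontiguousarray(dF[:, sl["neg"]]))
        elif use_pos:
            back_branch("pos", np.ascontiguousarray(dF[:, sl["pos"]]))
        elif use_neg:
            back_branch("neg", np.ascontiguousarray(dF[:, sl["neg"]]))

        dE[PAD_INDEX] = 0.0  # PAD embedding stays fixed at zero
        grads["E"] = dE
        return loss_val, grads

    # -- prediction & diagnostics -------------------------------------------

    def predict_proba(self, posts: Sequence[LabeledPost | str],
                      batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(posts), batch_size):
            probs, _ = self.forward(self.encode_posts(posts[i:i + batch_size]))
            out.append(probs)
        return np.vstack(out)

    def predict(self, posts: Sequence[LabeledPost | str]) -> np.ndarray:
        return self.predict_proba(posts).argmax(axis=1)

    def diagnostics(self, posts: Sequence[LabeledPost | str],
                    top_k: int = 5) -> list[dict]:
        """Per-post prediction record with theta and top-k attention words."""
        records = []
        for i in range(0, len(posts), 256):
            chunk = posts[i:i + 256]
            batch = self.encode_posts(chunk)
            probs, diag = self.forward(batch)
            for j, post in enumerate(chunk):
                text = post.text if isinstance(post, LabeledPost) else post
                rec: dict = {
                    "text": text,
                    "pred": int(probs[j].argmax()),
                    "y": [float(v) for v in probs[j]],
                }
                if isinstance(post, LabeledPost):
                    rec["label"] = post.label
                if "theta" in diag:
                    rec["theta"] = float(diag["theta"][j])
                if "alpha_sun" in diag:
                    toks = tokenize(text)[:batch["ids"].shape[1]]
                    alpha = diag["alpha_sun"][j][:len(toks)]
                    order = np.argsort(alpha)[::-1][:top_k]
                    rec["top_words"] = [
                        {"word": toks[k], "weight": float(alpha[k])}
                        for k in order if alpha[k] > 0
                    ]
                records.append(rec)
        return records

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write parameters (npz archive) plus a JSON config sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params)
        sidecar = {
            "config": asdict(self.config),
            "vocab": self.vocab.word_to_index,
            "lexicon": self.lexicon.scores if self.lexicon else None,
        }
        (directory / "model.json").write_text(json.dumps(sidecar), encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "EanModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text(encoding="utf-8"))
        vocab = Vocabulary(dict(sidecar["vocab"]))
        lex = (PolarityLexicon(dict(sidecar["lexicon"]))
               if sidecar["lexicon"] is not None else None)
        model = cls(ModelConfig(**sidecar["config"]), vocab, lex)
        with np.load(directory / "params.npz") as npz:
            for k in model.params:
                model.params[k] = npz[k]
        return model


def forward_ean(
    post_seq: TokenSequence,
    split_seqs: tuple[TokenSequence, TokenSequence],
    model: EanModel,
) -> tuple[np.ndarray, dict]:
    """Single-example forward pass from pre-encoded sequences.

    Returns the length-2 probability vector and a diagnostics dict with the
    attention weights and realised theta the variant defines.
    """
    batch: dict = {
        "ids": np.asarray(post_seq.ids)[None, :],
        "mask": np.concatenate([np.ones(post_seq.length),
                                np.zeros(len(post_seq.ids) - post_seq.length)])[None, :],
    }
    if model._uses_emotion():
        ps, ns = split_seqs
        batch["pos_ids"] = np.asarray(ps.ids)[None, :]
        batch["neg_ids"] = np.asarray(ns.ids)[None, :]
        pm = np.zeros(len(ps.ids)); pm[:ps.length] = 1.0
        nm = np.zeros(len(ns.ids)); nm[:ns.length] = 1.0
        batch["pos_mask"] = pm[None, :]
        batch["neg_mask"] = nm[None, :]
    probs, diag = model.forward(batch)
    out = {k: (v[0] if isinstance(v, np.ndarray) else v) for k, v in diag.items()}
    return probs[0], out


def build_variant(
    name: str,
    config: ModelConfig | None = None,
    *,
    vocab: Vocabulary,
    lexicon: PolarityLexicon | None = None,
    embeddings: EmbeddingMatrix | None = None,
    **overrides,
) -> EanModel:
    """Construct a model variant by name (EAN, SUN, EUN, baselines, ...).

    The unidirectional LSTM baseline defaults to unit size 128; all
    bidirectional variants to 64 per direction.
    """
    if name not in VALID_VARIANTS:
        raise ValueError(
            f"unknown variant {name!r}; valid names: {', '.join(VALID_VARIANTS)}"
        )
    if config is None:
        base: dict = {"hidden_size": 128 if name == "LSTM" else 64}
        base.update(overrides)
        config = ModelConfig(variant=name, **base)
    else:
        cfg_dict = asdict(config)
        cfg_dict["variant"] = name
        cfg_dict.update(overrides)
        config = ModelConfig(**cfg_dict)
    return EanModel(config, vocab, lexicon, embeddings)


def write_diagnostics(records: Sequence[Mapping], path: str | Path) -> None:
    """Export per-post diagnostics as JSONL (consumed by the theta report)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(dict(rec), ensure_ascii=False) + "\n")
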