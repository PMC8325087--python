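"""Training, cross-validation and evaluation for EAN model variants.

Training minimises mean cross-entropy with Adam (batch size 128 by default)
under a fixed seed that drives initialisation, shuffling and batching, so a
run is exactly reproducible.  Evaluation follows the standard protocol for
this task: stratified 10-fold cross-validation (90% train / 10% test per
fold) with accuracy, precision, recall and F1 computed on the
depression-indicative class as the positive class, reported as fold means.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._nn import Adam
from .corpus_io import LabeledPost, build_vocab
from .ean_model import EanModel, ModelConfig, build_variant
from .emotion_lexicon import PolarityLexicon

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters (Adam, batch 128 by default)."""

    batch_size: int = 128
    learning_rate: float = 1e-3
    max_epochs: int = 20
    patience: int = 3           # early stop on held-out loss; <=0 disables
    val_fraction: float = 0.1   # carved from the training set when patience>0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    stopped_early: bool = False


@dataclass
class ConfusionCounts:
    """Binary confusion counts; positive class = depression-indicative."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        return cls(
            TP=int(((yt == 1) & (yp == 1)).sum()),
            FP=int(((yt == 0) & (yp == 1)).sum()),
            FN=int(((yt == 1) & (yp == 0)).sum()),
            TN=int(((yt == 0) & (yp == 0)).sum()),
        )


@dataclass
class MetricsResult:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class FoldMetrics:
    """Per-fold metrics plus their mean and standard deviation."""

    folds: list[MetricsResult]

    def _col(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds])

    def mean(self) -> MetricsResult:
        return MetricsResult(*(float(self._col(n).mean())
                               for n in ("accuracy", "precision", "recall", "f1")))

    def std(self) -> MetricsResult:
        return MetricsResult(*(float(self._col(n).std())
                               for n in ("accuracy", "precision", "recall", "f1")))

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean().as_dict(),
            "std": self.std().as_dict(),
        }


def compute_metrics(counts: ConfusionCounts) -> MetricsResult:
    """Accuracy, precision, recall and F1 from confusion counts.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R).  Undefined ratios (zero denominator) are reported as 0
    with a warning.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero examples")

    def guarded(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (0/0); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    acc = (counts.TP + counts.TN) / counts.total
    prec = guarded(counts.TP, counts.TP + counts.FP, "precision")
    rec = guarded(counts.TP, counts.TP + counts.FN, "recall")
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    return MetricsResult(accuracy=acc, precision=prec, recall=rec, f1=f1)


def evaluate(model: EanModel, posts: Sequence[LabeledPost]) -> MetricsResult:
    preds = model.predict(posts)
    counts = ConfusionCounts.from_predictions([p.label for p in posts], preds)
    return compute_metrics(counts)


# ---------------------------------------------------------------------------
# training


def _mean_loss(model: EanModel, posts: Sequence[LabeledPost], batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(posts), batch_size):
        chunk = posts[i:i + batch_size]
        batch = model.encode_posts(chunk)
        probs, _ = model.forward(batch)
        p = np.clip(probs[np.arange(len(chunk)), batch["labels"]], 1e-12, None)
        total += float(-np.log(p).sum())
        n += len(chunk)
    return total / n


def train(model: EanModel, posts: Sequence[LabeledPost],
          config: TrainConfig | None = None) -> TrainLog:
    """Train a model in place; returns the per-epoch loss log.

    Shuffling and batching are driven by ``config.seed``.  With
    ``patience > 0`` a validation split is carved from ``posts`` and
    training stops once validation loss fails to improve for that many
    epochs (the best-so-far parameters are restored).
    """
    config = config or TrainConfig()
    labels = {p.label for p in posts}
    if len(posts) < 2 or labels != {0, 1}:
        raise ValueError("training needs >= 2 posts covering both classes")

    rng = np.random.default_rng(config.seed)
    train_posts = list(posts)
    val_posts: list[LabeledPost] = []
    if config.patience > 0 and config.val_fraction > 0:
        y = [p.label for p in posts]
        n_val = max(2, int(round(config.val_fraction * len(posts))))
        if len(posts) - n_val >= 2 and n_val < len(posts):
            tr_idx, va_idx = train_test_split(
                np.arange(len(posts)), test_size=n_val, stratify=y,
                random_state=config.seed % (2 ** 32))
            train_posts = [posts[i] for i in tr_idx]
            val_posts = [posts[i] for i in va_idx]

    opt = Adam(model.params.keys(), lr=config.learning_rate)
    log = TrainLog()
    best_val = np.inf
    best_params: dict | None = None
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_posts))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [train_posts[j] for j in order[i:i + config.batch_size]]
            batch = model.encode_posts(chunk)
            loss_val, grads = model.loss_and_grads(batch)
            if config.learning_rate > 0:
                opt.step(model.params, grads)
            epoch_loss += loss_val * len(chunk)
            seen += len(chunk)
        log.epoch_losses.append(epoch_loss / max(seen, 1))

        if val_posts:
            vl = _mean_loss(model, val_posts, config.batch_size)
            log.val_losses.append(vl)
            if vl < best_val - 1e-6:
                best_val = vl
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    log.stopped_early = True
                    break
        logger.debug("epoch %d: train loss %.4f", epoch, log.epoch_losses[-1])

    if best_params is not None and log.stopped_early:
        model.params.update(best_params)
    return log


# ---------------------------------------------------------------------------
# cross-validation


def stratified_fold_indices(labels: Sequence[int], n_folds: int, seed: int,
                            ) -> list[np.ndarray]:
    """Test-index sets of a stratified k-fold partition (disjoint, exhaustive)."""
    y = np.asarray(labels)
    for cls in (0, 1):
        if (y == cls).sum() < n_folds:
            raise ValueError(
                f"class {cls} has only {(y == cls).sum()} members; "
                f"use fewer than {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=seed % (2 ** 32))
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def cross_validate(
    variant: str,
    corpus: Sequence[LabeledPost],
    lexicon: PolarityLexicon | None = None,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    n_folds: int = 10,
    min_count: int = 1,
    collect_diagnostics: bool = False,
) -> FoldMetrics | tuple[FoldMetrics, list[dict]]:
    """Stratified k-fold cross-validation of a model variant.

    Each post is tested exactly once.  The vocabulary is built once from the
    whole corpus (token identities only; labels never cross fold
    boundaries).  With ``collect_diagnostics`` the per-post test-time
    diagnostic records (prediction, theta, attention words) are returned too.
    """
    train_config = train_config or TrainConfig()
    vocab = build_vocab(corpus, min_count=min_count)
    labels = [p.label for p in corpus]
    folds = stratified_fold_indices(labels, n_folds, train_config.seed)

    results: list[MetricsResult] = []
    diagnostics: list[dict] = []
    for k, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_posts = [p for i, p in enumerate(corpus) if i not in test_set]
        test_posts = [corpus[i] for i in test_idx]
        model = build_variant(variant, model_config, vocab=vocab, lexicon=lexicon)
        train(model, train_posts, train_config)
        results.append(evaluate(model, test_posts))
        if collect_diagnostics:
            for rec in model.diagnostics(test_posts):
                rec["fold"] = k
                diagnostics.append(rec)
        logger.info("fold %d/%d %s: acc %.3f", k + 1, n_folds, variant,
                    results[-1].accuracy)
    fm = FoldMetrics(results)
    if collect_diagnostics:
        return fm, diagnostics
    return fm


def run_ablation_suite(
    corpus: Sequence[LabeledPost],
    lexicon: PolarityLexicon,
    variants: Sequence[str],
    seeds: Sequence[int],
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    n_folds: int = 10,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Cross-validate each variant under each seed; tabulate mean +/- sd.

    Returns a DataFrame with one row per variant (columns: mean and sd of
    accuracy/precision/recall/F1 pooled over seeds x folds) and, when
    ``out_dir`` is given, writes ``ablation.csv`` and ``ablation.json``.
    """
    base_tc = train_config or TrainConfig()
    rows = []
    per_variant: dict[str, dict] = {}
    for variant in variants:
        fold_results: list[MetricsResult] = []
        for seed in seeds:
            tc = TrainConfig(**{**asdict(base_tc), "seed": int(seed)})
            mc = model_config
            if mc is not None:
                mc = ModelConfig(**{**asdict(mc), "variant": variant, "seed": int(seed)})
            fm = cross_validate(variant, corpus, lexicon, tc, mc, n_folds=n_folds)
            fold_results.extend(fm.folds)
        pooled = FoldMetrics(fold_results)
        mean, std = pooled.mean(), pooled.std()
        per_variant[variant] = pooled.as_dict()
        rows.append({
            "variant": variant,
            **{f"{n}_mean": getattr(mean, n) for n in ("accuracy", "precision", "recall", "f1")},
            **{f"{n}_std": getattr(std, n) for n in ("accuracy", "precision", "recall", "f1")},
        })
    table = pd.DataFrame(rows).set_index("variant")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "ablation.csv")
        (out_dir / "ablation.json").write_text(
            json.dumps(per_variant, indent=2), encoding="utf-8")
    return table


def write_metrics(fm: FoldMetrics, path: str | Path) -> None:
    """Write per-fold and mean metrics as JSON (the `metrics.json` artifact)."""
    Path(path).write_text(json.dumps(fm.as_dict(), indent=2, sort_keys=True),
                          encoding="utf-8")
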