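"""Bootstrapped training of the 3D CNN and prediction helpers.

Training follows the bootstrap protocol: ``n_runs`` independent runs, each
with a freshly re-randomized train/validation/test partition of the working
cells, fresh weight initialization and a fresh batch order every epoch;
within a run the checkpoint at the epoch of minimum validation loss is
retained, and across runs the model with the lowest best validation loss is
selected.  The strict test set (whole held-out images) is never seen by any
run and is evaluated once per run for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dataset import CellSample, split_train_val_test, stack_tensors
from .layers import softmax_cross_entropy
from .model import CNN3D, ModelConfig, build_model


@dataclass
class TrainingRunResult:
    run_id: int
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    test_accuracy: float = float("nan")
    strict_accuracy: float | None = None


def categorical_cross_entropy(y_true, y_pred, eps: float = 1e-7) -> float:
    """Cross-entropy -sum(y * log(p)) for one-hot targets.

    Accepts a single (pair, pair) or batched arrays; batched input returns
    the mean per-sample loss.  Predicted probabilities are clipped at
    ``eps`` so a zero probability for the true class stays finite.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    p = np.clip(y_pred, eps, 1.0)
    per_sample = -(y_true * np.log(p)).sum(axis=-1)
    return float(per_sample.mean())


def _accuracy(model: CNN3D, x: np.ndarray, y: np.ndarray, normalized=True) -> float:
    probs = model.predict_proba(x, normalized=normalized)
    return float((probs.argmax(axis=1) == y).mean())


def _eval_loss_acc(model: CNN3D, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba(x, normalized=True)
    onehot = np.eye(probs.shape[1])[y]
    return categorical_cross_entropy(onehot, probs), float((probs.argmax(axis=1) == y).mean())


def train_run(
    splits: dict[str, tuple[np.ndarray, np.ndarray]],
    config: ModelConfig,
    seed: int,
    run_id: int = 0,
    epochs: int | None = None,
) -> tuple[CNN3D, TrainingRunResult]:
    """One training run; returns the best-epoch model and its history.

    ``splits`` maps 'train'/'val'/'test' (and optionally 'strict_test') to
    (x, y) arrays of raw-intensity tensors and label indices.
    """
    rng = np.random.default_rng(seed)
    model = build_model(config, rng)
    x_train, y_train = splits["train"]
    if len(x_train) == 0 or len(splits["val"][0]) == 0:
        raise ValueError("empty train or validation split")

    # per-channel standardization fitted on this run's training split
    mean = x_train.mean(axis=(0, 2, 3, 4), dtype=np.float64)
    std = x_train.std(axis=(0, 2, 3, 4), dtype=np.float64)
    std[std == 0] = 1.0
    model.norm_mean = mean.astype(np.float32)
    model.norm_std = std.astype(np.float32)

    norm = {k: (model.normalize(x), y) for k, (x, y) in splits.items() if len(x)}
    x_train, y_train = norm["train"]
    x_val, y_val = norm["val"]

    optimizer = model.make_optimizer()
    result = TrainingRunResult(run_id=run_id)
    best_state = None
    n_epochs = epochs if epochs is not None else config.max_epochs
    for epoch in range(n_epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss, grad, probs = softmax_cross_entropy(logits, y_train[idx])
            model.backward(grad)
            optimizer.step(lr)
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == y_train[idx]).sum())
        result.train_loss.append(float(np.mean(losses)))
        result.train_acc.append(correct / len(order))

        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val)
        result.val_loss.append(val_loss)
        result.val_acc.append(val_acc)
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            best_state = model.state()

    if best_state is not None:
        model.load_state(best_state)
    if "test" in norm and len(norm["test"][0]):
        result.test_accuracy = _accuracy(model, *norm["test"])
    if "strict_test" in norm and len(norm["strict_test"][0]):
        result.strict_accuracy = _accuracy(model, *norm["strict_test"])
    return model, result


def run_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-run seeds derived from one master seed (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def train_bootstrap(
    working: list[CellSample],
    config: ModelConfig,
    strict: list[CellSample] | None = None,
    proportions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    n_runs: int | None = None,
    epochs: int | None = None,
    group_rotations: bool = True,
) -> tuple[CNN3D, list[TrainingRunResult]]:
    """Bootstrapped training over re-randomized partitions of the working set.

    Returns the across-run best model (lowest best validation loss) and all
    run results.  ``n_runs``/``epochs`` default to the config values.
    """
    if not working:
        raise ValueError("empty working set")
    n_runs = n_runs if n_runs is not None else config.n_runs
    strict_xy = stack_tensors(strict) if strict else None
    results: list[TrainingRunResult] = []
    best_model: CNN3D | None = None
    for run_id, seed in enumerate(run_seeds(config.seed, n_runs)):
        assigned, _ = split_train_val_test(
            working, proportions, seed=seed, group_rotations=group_rotations
        )
        splits = {}
        for name in ("train", "val", "test"):
            subset = [s for s in assigned if s.split == name]
            if subset:
                splits[name] = stack_tensors(subset)
        if strict_xy is not None:
            splits["strict_test"] = strict_xy
        model, result = train_run(splits, config, seed=seed, run_id=run_id, epochs=epochs)
        results.append(result)
        if best_model is None or result.best_val_loss < min(
            r.best_val_loss for r in results[:-1]
        ):
            best_model = model
    return best_model, results


def predict(model: CNN3D, samples) -> list[dict]:
    """Per-sample predicted label and probability.

    ``samples`` may be CellSamples (with tensors) or a raw (n,3,20,50,50)
    array; output is deterministic (inference mode).
    """
    from ..dataset import LABELS

    if isinstance(samples, np.ndarray):
        x = samples
        ids = [str(i) for i in range(len(x))]
    else:
        x, _ = stack_tensors(samples)
        ids = [s.sample_id for s in samples]
    probs = model.predict_proba(x)
    out = []
    for sid, p in zip(ids, probs):
        k = int(p.argmax())
        out.append({"sample_id": sid, "label": LABELS[k], "probability": float(p[k])})
    return out
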