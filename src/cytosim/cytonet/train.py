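"""Training/evaluation harness and the transparent gating baseline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from cytosim.cytonet import _layers as L
from cytosim.cytonet.model import CLASS_NAMES, CytoNetModel


@dataclass
class TrainingConfig:
    split_fraction: float = 0.7  # train share of a stratified split
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    # Stop once held-out accuracy stays at/above this level for
    # ``patience`` consecutive epochs (None disables early stopping).
    early_stop_accuracy: float | None = None
    patience: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid batch size or learning rate")


@dataclass
class ConfusionMatrix:
    """2x2 counts (rows = true class, cols = predicted), plus rates."""

    counts: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 2x2 matrix")

    @property
    def tpr(self) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, np.diag(self.counts) / totals, np.nan)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "class_names": list(self.class_names),
            "tpr": {n: float(t) for n, t in zip(self.class_names, self.tpr)},
            "accuracy": self.accuracy,
        }


@dataclass
class TrainingResult:
    model: CytoNetModel
    train_loss: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)
    confusion: ConfusionMatrix | None = None
    split_seed: int = 0

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "test_accuracy": self.test_accuracy,
            }
        )


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) arrays or a collection of labelled FragmentTensors."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        x, y = dataset
        return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=int)
    x = np.stack([f.values for f in dataset]).astype(np.float32)
    labels = [f.label for f in dataset]
    name_to_idx = {n: i for i, n in enumerate(CLASS_NAMES)}
    y = np.array([name_to_idx[lab] for lab in labels], dtype=int)
    return x, y


def train(model: CytoNetModel, dataset, cfg: TrainingConfig) -> TrainingResult:
    """Stratified 7:3 split, minibatch Adam, per-epoch loss/accuracy log."""
    x, y = _as_arrays(dataset)
    if np.unique(y).size < 2:
        raise ValueError("dataset must contain both classes")
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, train_size=cfg.split_fraction, stratify=y, random_state=cfg.seed
    )
    if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
        raise ValueError("both classes must be present in both splits")

    rng = np.random.default_rng(cfg.seed)
    opt = L.Adam(model.params, lr=cfg.learning_rate)
    result = TrainingResult(model=model, split_seed=cfg.seed)
    n = x_tr.shape[0]
    streak = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            logits, cache = model.forward(x_tr[sel], return_cache=True)
            loss, dlogits = L.softmax_cross_entropy(logits, y_tr[sel])
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            losses.append(loss)
        acc = float((model.predict(x_te) == y_te).mean())
        result.train_loss.append(float(np.mean(losses)))
        result.test_accuracy.append(acc)
        if cfg.early_stop_accuracy is not None:
            streak = streak + 1 if acc >= cfg.early_stop_accuracy else 0
            if streak >= cfg.patience:
                break
    result.confusion = evaluate(model, x_te, y_te)
    return result


def evaluate(model: CytoNetModel, x: np.ndarray, y: np.ndarray) -> ConfusionMatrix:
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=int)
    if x.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(x)
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (y, pred), 1)
    return ConfusionMatrix(counts=counts)


def gating_baseline(
    features: pd.DataFrame,
    diameter_cut_um: float,
    opacity_cut: float,
) -> np.ndarray:
    """Rectangular gate on (diameter, Opacity_2/0.5).

    Predicts TUMOR iff diameter > diameter_cut and opacity_2_05 <
    opacity_cut; the manual-gating comparison arm for the CNN.  Returns
    integer class indices (see CLASS_NAMES).
    """
    d = features["estimated_diameter_um"].to_numpy(dtype=float)
    op = features["opacity_2_05"].to_numpy(dtype=float)
    return ((d > diameter_cut_um) & (op < opacity_cut)).astype(int)
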