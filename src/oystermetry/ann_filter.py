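"""MLP filter that removes non-oyster pixel groups.

A small multilayer perceptron (3 inputs → 100 ReLU units → 3 classes),
trained with full-batch Adam and categorical cross-entropy for 200 epochs,
classifies each segmented group from its size-share features.  Class-0
groups (shadows, debris, the reference cap) are removed; class-1 (oyster)
and class-2 (fused) groups survive to the measurement stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .features import GroupRecordANN
from .segmentation import PixelGroup

__all__ = ["AnnModel", "train_ann", "filter_groups"]

logger = logging.getLogger(__name__)

HIDDEN_UNITS = 100
TRAIN_EPOCHS = 200


@dataclass
class AnnModel:
    """Fitted scaler + MLP with training metadata."""

    scaler: StandardScaler
    mlp: MLPClassifier
    seed: int
    train_accuracy: float
    loss_curve: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        coefs = self.mlp.coefs_
        if len(coefs) != 2 or coefs[0].shape != (3, HIDDEN_UNITS):
            raise ValueError(
                f"model must be 3 → {HIDDEN_UNITS} → k; got layer shapes "
                f"{[c.shape for c in coefs]}"
            )

    def predict(self, records: list[GroupRecordANN]) -> np.ndarray:
        X = np.array([r.as_vector() for r in records])
        return self.mlp.predict(self.scaler.transform(X))

    def predict_proba(self, records: list[GroupRecordANN]) -> np.ndarray:
        X = np.array([r.as_vector() for r in records])
        return self.mlp.predict_proba(self.scaler.transform(X))

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "kind": "oystermetry-ann",
                "version": 1,
                "scaler": self.scaler,
                "mlp": self.mlp,
                "seed": self.seed,
                "train_accuracy": self.train_accuracy,
                "loss_curve": self.loss_curve,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AnnModel":
        blob = joblib.load(path)
        if blob.get("kind") != "oystermetry-ann":
            raise ValueError(f"{path} is not a saved group-filter model")
        return cls(
            scaler=blob["scaler"],
            mlp=blob["mlp"],
            seed=blob["seed"],
            train_accuracy=blob["train_accuracy"],
            loss_curve=blob["loss_curve"],
        )


def train_ann(records: list[GroupRecordANN], seed: int) -> AnnModel:
    """Train the group filter on labelled feature records.

    Features are standardised (zero mean, unit variance) before the MLP; the
    scaler is stored with the model.  Training is deterministic for a fixed
    seed.  Raises on single-class data.
    """
    labelled = [r for r in records if r.label is not None]
    X = np.array([r.as_vector() for r in labelled])
    y = np.array([r.label for r in labelled])
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train the group filter")

    scaler = StandardScaler().fit(X)
    mlp = MLPClassifier(
        hidden_layer_sizes=(HIDDEN_UNITS,),
        activation="relu",
        solver="adam",
        max_iter=TRAIN_EPOCHS,
        batch_size=len(X),  # full-batch updates: one step per epoch
        tol=0.0,
        n_iter_no_change=TRAIN_EPOCHS,  # never stop early
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        # reaching max_iter is intentional, not a convergence failure
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        mlp.fit(scaler.transform(X), y)
    acc = float(mlp.score(scaler.transform(X), y))
    logger.info("group-filter MLP trained on %d groups, accuracy %.4f", len(X), acc)
    return AnnModel(
        scaler=scaler,
        mlp=mlp,
        seed=seed,
        train_accuracy=acc,
        loss_curve=list(mlp.loss_curve_),
    )


def filter_groups(
    model: AnnModel,
    groups: list[PixelGroup],
    records: list[GroupRecordANN],
) -> tuple[list[tuple[PixelGroup, int]], list[PixelGroup]]:
    """Partition groups into survivors and removals by predicted class.

    Returns ``(kept, removed)`` where ``kept`` pairs each surviving group
    with its predicted class (1 or 2, retained for the refinement stage) and
    ``removed`` holds the class-0 groups.
    """
    if len(groups) != len(records):
        raise ValueError("groups and records must align one-to-one")
    if not groups:
        return [], []
    pred = model.predict(records)
    kept = [(g, int(c)) for g, c in zip(groups, pred) if c != 0]
    removed = [g for g, c in zip(groups, pred) if c == 0]
    return kept, removed
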