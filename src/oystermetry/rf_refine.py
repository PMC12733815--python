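"""Random Forest refinement: residual-noise removal and fused-oyster splitting.

A 100-tree forest classifies each measured group from its geometry features.
Class 0 (noise) is dropped, class 1 (single oyster) passes through, and
class 2 (two fused oysters) is replaced by two measurement records whose
lengths are each half of the fused length — the fused blob is not
re-segmented; halving exists to keep one fused pair from dragging the
per-image averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .features import GroupRecordRF
from .segmentation import PixelGroup

__all__ = ["RfModel", "OysterMeasurement", "train_rf", "refine", "DEFAULT_RF_SEED"]

logger = logging.getLogger(__name__)

N_TREES = 100
DEFAULT_RF_SEED = 42


@dataclass
class RfModel:
    forest: RandomForestClassifier
    seed: int
    train_accuracy: float
    confusion: np.ndarray

    def __post_init__(self) -> None:
        if self.forest.n_estimators != N_TREES:
            raise ValueError(f"forest must have {N_TREES} trees")

    def predict(self, records: list[GroupRecordRF]) -> np.ndarray:
        X = np.array([r.as_vector() for r in records])
        return self.forest.predict(X)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "kind": "oystermetry-rf",
                "version": 1,
                "forest": self.forest,
                "seed": self.seed,
                "train_accuracy": self.train_accuracy,
                "confusion": self.confusion,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RfModel":
        blob = joblib.load(path)
        if blob.get("kind") != "oystermetry-rf":
            raise ValueError(f"{path} is not a saved refinement model")
        return cls(
            forest=blob["forest"],
            seed=blob["seed"],
            train_accuracy=blob["train_accuracy"],
            confusion=blob["confusion"],
        )


@dataclass
class OysterMeasurement:
    group_id: int
    length_mm: float
    width_mm: float
    final_class: str  # "1" or "2-split"
    source_group_id: int | None = None  # fused group of origin, if split


def train_rf(records: list[GroupRecordRF], seed: int = DEFAULT_RF_SEED) -> RfModel:
    """Fit the 100-tree forest on labelled geometry records.

    Standard forest defaults (Gini impurity, unlimited depth, bootstrap);
    the fixed seed makes predictions bit-identical across runs.  Training
    accuracy and the 3×3 confusion matrix are retained as metadata.
    """
    labelled = [r for r in records if r.label is not None]
    X = np.array([r.as_vector() for r in labelled])
    y = np.array([r.label for r in labelled])
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train the refinement forest")
    forest = RandomForestClassifier(n_estimators=N_TREES, random_state=seed)
    forest.fit(X, y)
    pred = forest.predict(X)
    acc = float((pred == y).mean())
    cm = confusion_matrix(y, pred, labels=[0, 1, 2])
    logger.info("refinement forest trained on %d groups, accuracy %.4f", len(X), acc)
    return RfModel(forest=forest, seed=seed, train_accuracy=acc, confusion=cm)


def refine(
    model: RfModel,
    measurements: list[tuple[PixelGroup, float, float, GroupRecordRF]],
) -> list[OysterMeasurement]:
    """Apply the forest's verdict to measured groups.

    Output order follows input order; a fused group contributes two adjacent
    records whose lengths sum exactly to the fused length.
    """
    if not measurements:
        return []
    records = [m[3] for m in measurements]
    pred = model.predict(records)
    out: list[OysterMeasurement] = []
    for (group, length_mm, width_mm, _), cls in zip(measurements, pred):
        if cls == 0:
            continue
        if cls == 1:
            out.append(
                OysterMeasurement(
                    group_id=group.id,
                    length_mm=length_mm,
                    width_mm=width_mm,
                    final_class="1",
                )
            )
        else:  # fused pair: two halves along the longest dimension
            half = length_mm / 2.0
            for _ in range(2):
                out.append(
                    OysterMeasurement(
                        group_id=group.id,
                        length_mm=half,
                        width_mm=width_mm,
                        final_class="2-split",
                        source_group_id=group.id,
                    )
                )
    return out
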