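"""Shared fixtures: synthetic scenes and trained models, built once per session."""

from __future__ import annotations

import pytest

from oystermetry.ann_filter import train_ann
from oystermetry.pipeline import PipelineConfig
from oystermetry.rf_refine import train_rf
from oystermetry.synthetic import SceneSpec, generate_training_sets

#: Hough radius search band bracketing the default 30 px cap.
CAP_RADIUS_RANGE = (21, 39)


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(reference_diameter_mm=30.0, hough_radius_range=CAP_RADIUS_RANGE)


@pytest.fixture(scope="session")
def unit_models():
    """Filter + refiner trained on a small batch of scenes (unit-test grade)."""
    specs = [SceneSpec(seed=100 + i) for i in range(10)]
    ann_records, rf_records = generate_training_sets(specs)
    return train_ann(ann_records, seed=1), train_rf(rf_records)


@pytest.fixture(scope="session")
def study_models():
    """Models trained on the full 30-scene study batch (acceptance grade)."""
    specs = [SceneSpec(seed=1000 + i) for i in range(30)]
    ann_records, rf_records = generate_training_sets(specs)
    return train_ann(ann_records, seed=7), train_rf(rf_records)
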