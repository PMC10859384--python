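"""End-to-end model development: split, train full model, rank wavenumbers,
train the reduced model, and score both on the held-out set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PreprocessSpec, snv_spec
from .spectra import SpectraMatrix
from .svm import (ClassMetrics, ConfusionCounts, DiscriminantModel,
                  confusion_from_labels, feature_importance,
                  metrics_from_counts, predict, select_wavenumbers,
                  split_train_test, train_model)


@dataclass
class TrainSelectReport:
    full_model: DiscriminantModel
    reduced_model: DiscriminantModel
    selected_wavenumbers: list[float]
    full_confusion: ConfusionCounts
    reduced_confusion: ConfusionCounts
    full_metrics: ClassMetrics
    reduced_metrics: ClassMetrics
    train_sizes: dict
    test_sizes: dict

    def to_dict(self) -> dict:
        return {
            "selected_wavenumbers": self.selected_wavenumbers,
            "full": {
                "confusion": vars(self.full_confusion),
                "metrics": self.full_metrics.rounded(),
            },
            "reduced": {
                "confusion": vars(self.reduced_confusion),
                "metrics": self.reduced_metrics.rounded(),
            },
            "train_sizes": self.train_sizes,
            "test_sizes": self.test_sizes,
        }


def train_and_select(data: SpectraMatrix, seed: int = 0,
                     train_fraction: float = 2 / 3,
                     prep: PreprocessSpec | None = None,
                     C: float = 1.0, k: int = 4,
                     min_separation: float = 20.0) -> TrainSelectReport:
    """Run the full development path on a labeled spectra matrix."""
    prep = prep if prep is not None else snv_spec()
    train, test = split_train_test(data, train_fraction, seed)
    full = train_model(train, prep=prep, C=C, seed=seed)
    profile = feature_importance(full)
    selected = select_wavenumbers(profile, k=k, min_separation=min_separation)
    reduced = train_model(train, wavenumbers=selected, prep=prep, C=C, seed=seed)
    full.train_meta["split"] = {"fraction": train_fraction, "seed": seed}
    reduced.train_meta["split"] = {"fraction": train_fraction, "seed": seed}

    def _counts(labels):
        u, c = np.unique(labels, return_counts=True)
        return dict(zip(u.tolist(), c.astype(int).tolist()))

    full_conf = confusion_from_labels(test.labels, predict(full, test))
    red_conf = confusion_from_labels(test.labels, predict(reduced, test))
    return TrainSelectReport(
        full_model=full, reduced_model=reduced,
        selected_wavenumbers=selected,
        full_confusion=full_conf, reduced_confusion=red_conf,
        full_metrics=metrics_from_counts(full_conf),
        reduced_metrics=metrics_from_counts(red_conf),
        train_sizes=_counts(train.labels), test_sizes=_counts(test.labels),
    )
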