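"""Bridge from raw Utstein-style records to ensemble probability predictions.

Counterfactual sweeps operate on raw records (minutes in natural units) while
the networks consume the encoded design matrix, so every prediction re-runs
the *stored* training-time transform — never a re-fit — before the forward
pass.  This guarantees adjusted records are encoded exactly as training data
was.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import FeatureSchema, transform
from .prognet import ModelEnsemble, TrainedModel

__all__ = ["RecordPredictor"]


@dataclass
class RecordPredictor:
    """Callable: raw record frame -> stacked member probabilities."""

    model: TrainedModel | ModelEnsemble
    schema: FeatureSchema
    standardization: dict[str, tuple[float, float]]

    def encode(self, records: pd.DataFrame) -> np.ndarray:
        return transform(records, self.schema, self.standardization).values

    def __call__(self, records: pd.DataFrame) -> np.ndarray:
        X = self.encode(records)
        if isinstance(self.model, ModelEnsemble):
            return self.model.member_predictions(X)
        return self.model.predict(X)

    def mean_probability(self, records: pd.DataFrame) -> np.ndarray:
        """Per-record ensemble-mean probability (model-averaged)."""
        return np.atleast_2d(self(records)).mean(axis=0)
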