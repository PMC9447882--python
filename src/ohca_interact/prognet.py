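"""Training, class-weight calibration and cross-validated ensembling of the
prognostic network.

The outcome (favorable neurological status, CPC 1/2 at one month) occurs in
~4% of cases, so an unweighted network learns to predict "unfavorable"
everywhere.  The loss therefore carries a positive-class weight w_pos that is
*calibrated*: the smallest w_pos whose validation minority-class sensitivity
reaches the target (default 80%) is selected, which simultaneously keeps the
majority-class sensitivity as high as possible among qualifying weights.

``run_cv`` trains one calibrated model per cross-validation fold (four folds
over the non-test groups) and bundles them into a :class:`ModelEnsemble`
whose prediction is the arithmetic mean of the member probabilities — the
predictor contract consumed by the counterfactual sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .metrics import MetricsReport, metrics_report
from .mlp import MLP, ClassWeights, NetConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainedModel",
    "ModelEnsemble",
    "CalibrationResult",
    "train_model",
    "predict",
    "evaluate",
    "calibrate_class_weights",
    "run_cv",
]


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reuse it consistently."""

    net: MLP
    class_weights: ClassWeights
    threshold: float = 0.5
    training_log: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(X)

    def state_dict(self) -> dict:
        return {
            "net": self.net.state_dict(),
            "class_weights": [self.class_weights.w_pos, self.class_weights.w_neg],
            "threshold": self.threshold,
            "training_log": list(self.training_log),
        }

    @staticmethod
    def from_state_dict(state: dict) -> "TrainedModel":
        return TrainedModel(
            net=MLP.from_state_dict(state["net"]),
            class_weights=ClassWeights(*state["class_weights"]),
            threshold=float(state["threshold"]),
            training_log=list(state["training_log"]),
        )


@dataclass
class ModelEnsemble:
    """The four cross-validation models used jointly in counterfactual sweeps."""

    models: list[TrainedModel]
    threshold: float = 0.5

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean of the member predicted probabilities, row order preserved."""
        return np.mean([m.predict(X) for m in self.models], axis=0)

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict(X) for m in self.models])


def train_model(X: np.ndarray, y: np.ndarray, config: NetConfig,
                weights: ClassWeights | None = None) -> TrainedModel:
    """Fit one network; deterministic given ``config.seed``."""
    net = MLP(config)
    weights = weights or ClassWeights()
    log = net.fit(X, y, weights)
    return TrainedModel(net=net, class_weights=weights, training_log=log)


def predict(model: TrainedModel | ModelEnsemble, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def evaluate(model: TrainedModel | ModelEnsemble, X: np.ndarray, y: np.ndarray,
             threshold: float = 0.5) -> MetricsReport:
    """Per-class sensitivities and DeLong-interval AUROC of a predictor."""
    return metrics_report(model.predict(X), np.asarray(y).astype(bool), threshold)


@dataclass
class CalibrationResult:
    weights: ClassWeights
    trace: list[tuple[float, float, float]]  # (w_pos, sens_pos, sens_neg)
    converged: bool


def calibrate_class_weights(
    train_X: np.ndarray, train_y: np.ndarray,
    val_X: np.ndarray, val_y: np.ndarray,
    config: NetConfig | None = None,
    target_sensitivity: float = 0.80,
    tolerance: float = 0.02,
    grid: Sequence[float] = (1, 2, 4, 8, 16, 32, 64),
    weight_rtol: float = 0.05,
    threshold: float = 0.5,
    trainer: Callable[[float], np.ndarray] | None = None,
) -> CalibrationResult:
    """Search for the smallest positive-class weight hitting the target.

    A model is trained per candidate w_pos (ascending geometric grid); once a
    qualifying weight is found the bracket [last failing, first qualifying]
    is refined by geometric bisection until its ratio falls below
    ``1 + weight_rtol``.  Qualification means validation minority-class
    sensitivity >= target - tolerance.  The smallest weight qualifies first,
    so among qualifying weights the majority-class sensitivity is maximal.

    ``trainer(w_pos) -> validation scores`` can replace the default
    train-a-network step (used for oracle stubs in tests).  If nothing in
    range qualifies, the best-achieving weight is returned with
    ``converged=False``.
    """
    val_y = np.asarray(val_y).astype(bool)
    if not val_y.any() or val_y.all():
        raise ValueError("validation set must contain both classes")

    if trainer is None:
        if config is None:
            raise ValueError("either a NetConfig or a trainer stub is required")

        def trainer(w_pos: float) -> np.ndarray:
            model = train_model(train_X, train_y, config, ClassWeights(w_pos=w_pos))
            return model.predict(val_X)

    trace: list[tuple[float, float, float]] = []

    def sensitivities(w_pos: float) -> tuple[float, float]:
        scores = trainer(w_pos)
        pred = scores >= threshold
        s_pos = float((pred & val_y).sum() / val_y.sum())
        s_neg = float((~pred & ~val_y).sum() / (~val_y).sum())
        trace.append((float(w_pos), s_pos, s_neg))
        logger.info("calibration: w_pos=%.4g sens_pos=%.3f sens_neg=%.3f", w_pos, s_pos, s_neg)
        return s_pos, s_neg

    floor = target_sensitivity - tolerance
    lo = None  # largest failing weight seen
    hi = None  # smallest qualifying weight seen
    for w in grid:
        s_pos, _ = sensitivities(w)
        if s_pos >= floor:
            hi = float(w)
            break
        lo = float(w)
    if hi is None:
        best = max(trace, key=lambda t: t[1])
        logger.warning("calibration failed: best sens_pos=%.3f at w_pos=%.4g", best[1], best[0])
        return CalibrationResult(ClassWeights(w_pos=best[0]), trace, converged=False)
    if lo is not None:
        while hi / lo > 1.0 + weight_rtol:
            mid = float(np.sqrt(lo * hi))
            s_pos, _ = sensitivities(mid)
            if s_pos >= floor:
                hi = mid
            else:
                lo = mid
    return CalibrationResult(ClassWeights(w_pos=hi), trace, converged=True)


def run_cv(
    X: np.ndarray, y: np.ndarray, folds: Sequence[tuple[np.ndarray, np.ndarray]],
    config: NetConfig,
    target_sensitivity: float = 0.80,
    calibrate: bool = True,
    class_weights: ClassWeights | None = None,
) -> tuple[ModelEnsemble, list[MetricsReport], list[CalibrationResult | None]]:
    """Train one (optionally weight-calibrated) model per CV fold.

    Each fold gets its own derived seed; calibration is independent per fold.
    Returns the four-model ensemble, the per-fold validation metric reports,
    and the per-fold calibration traces (None when ``calibrate`` is off).
    """
    y = np.asarray(y).astype(float)
    models: list[TrainedModel] = []
    reports: list[MetricsReport] = []
    calibrations: list[CalibrationResult | None] = []
    for f, (train_idx, val_idx) in enumerate(folds):
        fold_cfg = replace(config, seed=int(
            np.random.SeedSequence([config.seed, 100 + f]).generate_state(1)[0] % (2**31)
        ))
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[val_idx], y[val_idx]
        if calibrate:
            cal = calibrate_class_weights(
                Xt, yt, Xv, yv, fold_cfg, target_sensitivity=target_sensitivity
            )
            weights = cal.weights
        else:
            cal = None
            weights = class_weights or ClassWeights()
        model = train_model(Xt, yt, fold_cfg, weights)
        models.append(model)
        reports.append(evaluate(model, Xv, yv))
        calibrations.append(cal)
        logger.info(
            "fold %d: w_pos=%.3g sens_pos=%.3f sens_neg=%.3f auroc=%.3f",
            f, weights.w_pos, reports[-1].sensitivity_pos,
            reports[-1].sensitivity_neg, reports[-1].auroc,
        )
    return ModelEnsemble(models), reports, calibrations
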