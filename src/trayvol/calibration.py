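"""Volume-to-weight density calibration per food class.

Integrated volumes are in arbitrary units (relative depth x pixel area), so
turning them into grams needs per-food calibration pairs of (measured volume,
weighed mass).  The physical premise is a constant density per food class,
giving a proportional model ``weight = k * volume`` fitted through the
origin; an affine variant ``weight = k * volume + intercept`` is available
for foods whose served portions carry a fixed offset (sauce, container bias).

:class:`DensityRegressor` is a scikit-learn estimator (fit/predict,
get_params/set_params) so it composes with sklearn model selection;
:func:`calibrate` / :func:`estimate_weight` are thin functional wrappers
producing the serializable :class:`DensityModel` "conversion table" entries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CalibrationPair",
    "DensityModel",
    "DensityRegressor",
    "calibrate",
    "estimate_weight",
    "percent_error",
    "save_models",
    "load_models",
]


@dataclass(frozen=True)
class CalibrationPair:
    """One calibration observation: integrated volume (a.u.) vs weighed grams."""

    volume: float
    weight: float
    food_class: str

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.weight <= 0:
            raise ValueError("calibration volume and weight must be positive")


@dataclass(frozen=True)
class DensityModel:
    """Fitted per-class conversion: ``weight = k * volume + intercept``."""

    food_class: str
    k: float  # grams per arbitrary volume unit
    intercept: float = 0.0
    n_pairs: int = 0
    rms_residual: float = 0.0  # grams

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("density factor k must be positive")


class DensityRegressor(RegressorMixin, BaseEstimator):
    """Least-squares density fit mapping food volume to weight.

    Parameters
    ----------
    mode : {"proportional", "affine"}
        ``"proportional"`` fits ``w = k v`` through the origin, the closed
        form ``k = sum(w v) / sum(v^2)`` (>= 1 pair).  ``"affine"`` fits
        ``w = k v + b`` by ordinary least squares (>= 2 pairs).

    Attributes
    ----------
    k_ : float
        Fitted density factor, grams per arbitrary volume unit.
    intercept_ : float
        Fitted offset in grams (0 in proportional mode).
    rms_residual_ : float
        Root-mean-square residual of the fit, grams.
    n_pairs_ : int
        Number of calibration pairs used.
    """

    def __init__(self, mode: str = "proportional"):
        self.mode = mode

    def fit(self, X, y):
        if self.mode not in ("proportional", "affine"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of volumes")
        v = X[:, 0]
        w = np.asarray(y, dtype=np.float64)
        if v.shape != w.shape:
            raise ValueError("X and y lengths differ")
        min_pairs = 1 if self.mode == "proportional" else 2
        if len(v) < min_pairs:
            raise ValueError(
                f"{self.mode} calibration needs at least {min_pairs} pair(s), got {len(v)}"
            )
        if np.any(v <= 0) or np.any(w <= 0):
            raise ValueError("calibration volumes and weights must be positive")

        if self.mode == "proportional":
            self.k_ = float(np.dot(w, v) / np.dot(v, v))
            self.intercept_ = 0.0
        else:
            design = np.column_stack([v, np.ones_like(v)])
            coeffs, _, _, _ = np.linalg.lstsq(design, w, rcond=None)
            self.k_, self.intercept_ = float(coeffs[0]), float(coeffs[1])
        if self.k_ <= 0:
            raise ValueError("fitted density factor is non-positive")
        residuals = w - (self.k_ * v + self.intercept_)
        self.rms_residual_ = float(np.sqrt(np.mean(residuals**2)))
        self.n_pairs_ = len(v)
        return self

    def predict(self, X):
        """Predicted weights in grams, floored at 0."""
        check_is_fitted(self, "k_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return np.maximum(self.k_ * X[:, 0] + self.intercept_, 0.0)


def calibrate(pairs: list[CalibrationPair], mode: str = "proportional") -> DensityModel:
    """Fit one food class's density model from its calibration pairs."""
    if not pairs:
        raise ValueError("no calibration pairs given")
    classes = {p.food_class for p in pairs}
    if len(classes) != 1:
        raise ValueError(f"calibration pairs mix food classes: {sorted(classes)}")
    reg = DensityRegressor(mode=mode).fit(
        [[p.volume] for p in pairs], [p.weight for p in pairs]
    )
    return DensityModel(
        food_class=pairs[0].food_class,
        k=reg.k_,
        intercept=reg.intercept_,
        n_pairs=reg.n_pairs_,
        rms_residual=reg.rms_residual_,
    )


def estimate_weight(volume: float, model: DensityModel) -> float:
    """``weight = k * volume + intercept``, floored at 0 grams."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return max(model.k * volume + model.intercept, 0.0)


def percent_error(estimated: float, reference: float) -> float:
    """Absolute percent error ``100 * |estimated - reference| / reference``."""
    if reference <= 0:
        raise ValueError("reference weight must be positive")
    return 100.0 * abs(estimated - reference) / reference


def save_models(models: dict[str, DensityModel], path: str | Path) -> None:
    """Persist fitted models as a JSON conversion table keyed by food class."""
    table = {cls: asdict(m) for cls, m in sorted(models.items())}
    Path(path).write_text(json.dumps(table, indent=2, sort_keys=True) + "\n")


def load_models(path: str | Path) -> dict[str, DensityModel]:
    table = json.loads(Path(path).read_text())
    return {cls: DensityModel(**entry) for cls, entry in table.items()}
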