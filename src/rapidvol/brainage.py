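"""Brain-age evaluation: error metrics, null benchmark, leave-one-out
offset correction, and a small Gaussian-process age model.

The error metric is the *median* absolute error (MAE) between predicted and
chronological age, benchmarked against the "worst possible" model that
predicts one constant — the mean age of the external brain-age model's
training sample (40.6 years by default) — for everyone. A systematically
offset prediction (e.g. from a reduced-coverage acquisition) can be
corrected by regressing the reference sequence's predictions on the offset
sequence's predictions with leave-one-out cross-validation, adjusting each
held-out participant with coefficients fitted on the remaining n-1.

``GprAgeModel`` is a deliberately small Gaussian-process regressor (squared
exponential kernel, fixed hyperparameters, prior mean = mean training age)
predicting age from global and octant tissue volumes. It exists to
demonstrate the offset mechanism: predicting from features computed on
truncated-field-of-view maps shifts the inputs away from the (full-coverage)
training distribution and produces systematically offset predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .config import STANDARD, TISSUES, GeneratorConfig
from .errors import DataError, DegenerateDataError, ParameterError
from .stats import association
from .volumetrics import TissueMapSet, global_volumes, reduce_fov

#: Mean age (years) of the external brain-age model's training sample,
#: used as the constant prediction of the null benchmark.
DEFAULT_REFERENCE_AGE = 40.6


# ---------------------------------------------------------------------------
# Error metrics


def mae(predicted, chronological, kind: str = "median") -> float:
    """Median (default) or mean absolute error between predictions and
    chronological age, in years."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    chronological = np.asarray(chronological, dtype=float).ravel()
    if predicted.size == 0:
        raise DataError("empty input")
    if predicted.size != chronological.size:
        raise DataError(
            f"length mismatch: {predicted.size} vs {chronological.size}"
        )
    err = np.abs(predicted - chronological)
    if kind == "median":
        return float(np.median(err))
    if kind == "mean":
        return float(err.mean())
    raise ParameterError(f"unknown MAE kind {kind!r}")


def null_mae(
    chronological, reference_age: float = DEFAULT_REFERENCE_AGE,
    kind: str = "median",
) -> float:
    """MAE of the degenerate model predicting ``reference_age`` for everyone."""
    chronological = np.asarray(chronological, dtype=float).ravel()
    if chronological.size == 0:
        raise DataError("empty input")
    return mae(np.full_like(chronological, reference_age), chronological, kind=kind)


def null_mae_ratio(null: float, model_mae: float) -> float:
    """Fold improvement of a model over the null benchmark: null / model."""
    if model_mae == 0:
        raise ParameterError(
            "null-MAE ratio undefined: model MAE is exactly 0 (division by zero)"
        )
    return float(null) / float(model_mae)


# ---------------------------------------------------------------------------
# Leave-one-out offset correction


@dataclass
class LooAdjustment:
    """Per-fold OLS coefficients and adjusted predictions."""

    slopes: np.ndarray
    intercepts: np.ndarray
    adjusted: np.ndarray
    adjusted_mae: float
    mae_kind: str = "median"

    @property
    def n(self) -> int:
        return self.adjusted.size


def loo_adjust(
    pred_offset, pred_reference, chronological, mae_kind: str = "median"
) -> LooAdjustment:
    """Leave-one-out regression correction of systematically offset
    predictions.

    For each participant ``i``, the reference predictions are regressed on
    the offset predictions over the other ``n - 1`` participants (ordinary
    least squares) and the held-out participant's adjusted prediction is
    ``intercept + slope * pred_offset[i]``. The overall adjusted MAE is
    computed against chronological age.
    """
    x = np.asarray(pred_offset, dtype=float).ravel()
    y = np.asarray(pred_reference, dtype=float).ravel()
    age = np.asarray(chronological, dtype=float).ravel()
    n = x.size
    if y.size != n or age.size != n:
        raise DataError("pred_offset, pred_reference and chronological must "
                        "have equal lengths")
    if n < 3:
        raise DataError(f"need at least 3 participants, got {n}")
    # Leave-one-out OLS via downdated sums (exact, no per-fold refit).
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    m = n - 1
    sx_i = sx - x
    sy_i = sy - y
    sxx_i = sxx - x * x
    sxy_i = sxy - x * y
    denom = m * sxx_i - sx_i**2
    if np.any(np.isclose(denom, 0.0)):
        raise DegenerateDataError(
            "offset predictions have zero variance in a leave-one-out fold"
        )
    slopes = (m * sxy_i - sx_i * sy_i) / denom
    intercepts = (sy_i - slopes * sx_i) / m
    adjusted = intercepts + slopes * x
    return LooAdjustment(
        slopes=slopes,
        intercepts=intercepts,
        adjusted=adjusted,
        adjusted_mae=mae(adjusted, age, kind=mae_kind),
        mae_kind=mae_kind,
    )


# ---------------------------------------------------------------------------
# Per-sequence evaluation (Table-style record)


@dataclass
class BrainAgeMetrics:
    """Evaluation record of one sequence's brain-age predictions."""

    sequence: str
    rs: float
    p: float
    r2: float
    mae: float
    null_mae: float
    null_mae_ratio: Optional[float]
    n: int

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "rs": self.rs,
            "p": self.p,
            "r2": self.r2,
            "mae": self.mae,
            "null_mae": self.null_mae,
            "null_mae_ratio": self.null_mae_ratio,
            "n": self.n,
        }


def _prediction_column(table: pd.DataFrame, sequence_label: str) -> str:
    for candidate in (sequence_label, f"pred_{sequence_label}"):
        if candidate in table.columns:
            return candidate
    raise KeyError(
        f"no prediction column for sequence {sequence_label!r} "
        f"(columns: {list(table.columns)})"
    )


def evaluate_sequence(
    table: pd.DataFrame,
    sequence_label: str,
    reference_age: float = DEFAULT_REFERENCE_AGE,
    mae_kind: str = "median",
) -> BrainAgeMetrics:
    """Assemble rs, p, r^2, MAE and the null-MAE ratio for one sequence.

    ``table`` must hold an ``age`` column and a prediction column named
    either ``<sequence_label>`` or ``pred_<sequence_label>``. A perfect
    prediction (MAE 0) reports the ratio as missing rather than infinite.
    """
    column = _prediction_column(table, sequence_label)
    age = table["age"].to_numpy(dtype=float)
    pred = table[column].to_numpy(dtype=float)
    assoc = association(age, pred)
    model_mae = mae(pred, age, kind=mae_kind)
    null = null_mae(age, reference_age, kind=mae_kind)
    ratio = None if model_mae == 0 else null_mae_ratio(null, model_mae)
    return BrainAgeMetrics(
        sequence=sequence_label,
        rs=assoc.rs,
        p=assoc.p,
        r2=assoc.r2,
        mae=model_mae,
        null_mae=null,
        null_mae_ratio=ratio,
        n=age.size,
    )


# ---------------------------------------------------------------------------
# Toy Gaussian-process age model


class GprAgeModel(BaseEstimator, RegressorMixin):
    """Gaussian-process age regressor with fixed hyperparameters.

    Posterior mean about a constant prior::

        m(x) = prior_mean + k(x, X) (K + sigma^2 I)^{-1} (y - prior_mean)

    with a squared-exponential kernel
    ``k(x, x') = signal_variance * exp(-||x - x'||^2 / (2 length_scale^2))``.

    Parameters
    ----------
    length_scale : float or "median"
        Kernel length scale in (standardized) feature units; ``"median"``
        sets it to ``length_scale_factor`` times the median pairwise
        distance between training points — generous by default, so the
        regressor behaves near-linearly within the training range.
    signal_variance : float or "var"
        Kernel amplitude; ``"var"`` uses the training-target variance.
    noise_variance : float
        Observation noise variance (years^2); 0 interpolates the training
        data (a tiny jitter keeps the solve positive definite).
    prior_mean : float or None
        Constant prior mean; None uses the mean training age.
    standardize : bool
        Whether to z-score features with training statistics.
    """

    def __init__(
        self,
        length_scale="median",
        length_scale_factor: float = 3.0,
        signal_variance="var",
        noise_variance: float = 25.0,
        prior_mean: Optional[float] = None,
        standardize: bool = True,
    ):
        self.length_scale = length_scale
        self.length_scale_factor = length_scale_factor
        self.signal_variance = signal_variance
        self.noise_variance = noise_variance
        self.prior_mean = prior_mean
        self.standardize = standardize

    def fit(self, X, y) -> "GprAgeModel":
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < 2:
            raise DataError("need at least 2 training rows")
        if self.noise_variance < 0:
            raise ParameterError("noise_variance must be non-negative")
        if self.standardize:
            self.feature_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.feature_scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.feature_mean_ = np.zeros(X.shape[1])
            self.feature_scale_ = np.ones(X.shape[1])
        Xs = (X - self.feature_mean_) / self.feature_scale_

        if self.length_scale == "median":
            d = pdist(Xs)
            d = d[d > 0]
            base = np.median(d) if d.size else 1.0
            self.length_scale_ = float(self.length_scale_factor * base)
        else:
            self.length_scale_ = float(self.length_scale)
        if self.length_scale_ <= 0:
            raise ParameterError("length_scale must be positive")
        if self.signal_variance == "var":
            self.signal_variance_ = float(max(np.var(y), 1e-12))
        else:
            self.signal_variance_ = float(self.signal_variance)
        self.prior_mean_ = (
            float(np.mean(y)) if self.prior_mean is None else float(self.prior_mean)
        )

        kernel = ConstantKernel(
            self.signal_variance_, constant_value_bounds="fixed"
        ) * RBF(self.length_scale_, length_scale_bounds="fixed")
        self.gpr_ = GaussianProcessRegressor(
            kernel=kernel,
            alpha=max(self.noise_variance, 1e-10),
            optimizer=None,
            normalize_y=False,
        )
        self.gpr_.fit(Xs, np.asarray(y, dtype=float) - self.prior_mean_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "gpr_")
        X = check_array(X)
        Xs = (X - self.feature_mean_) / self.feature_scale_
        return self.gpr_.predict(Xs) + self.prior_mean_


def gpr_fit(features, ages, **hyperparams) -> GprAgeModel:
    """Fit a :class:`GprAgeModel`; thin functional wrapper."""
    return GprAgeModel(**hyperparams).fit(features, ages)


def gpr_predict(model: GprAgeModel, features) -> np.ndarray:
    """Predict ages with a fitted :class:`GprAgeModel`."""
    return model.predict(features)


# ---------------------------------------------------------------------------
# Volumetric features and the field-of-view offset experiment


def extract_features(
    maps_by_tissue: dict[str, TissueMapSet]
) -> tuple[np.ndarray, list[str]]:
    """Per-participant volumetric feature matrix.

    Three global tissue volumes plus the eight octant GM volumes (grid split
    at the midpoint of each axis) — small, and sensitive to a truncated
    field of view.
    """
    missing = [t for t in TISSUES if t not in maps_by_tissue]
    if missing:
        raise DataError(f"missing tissue map sets: {missing}")
    columns = []
    names = []
    for tissue in TISSUES:
        columns.append(global_volumes(maps_by_tissue[tissue])["volume_mm3"].to_numpy())
        names.append(f"total_{tissue}")
    gm = maps_by_tissue["GM"].values
    _, nx, ny, nz = gm.shape
    hx, hy, hz = nx // 2, ny // 2, nz // 2
    for ix, xs in enumerate((slice(0, hx), slice(hx, nx))):
        for iy, ys in enumerate((slice(0, hy), slice(hy, ny))):
            for iz, zs in enumerate((slice(0, hz), slice(hz, nz))):
                columns.append(gm[:, xs, ys, zs].sum(axis=(1, 2, 3)))
                names.append(f"gm_octant_{ix}{iy}{iz}")
    return np.column_stack(columns), names


@dataclass
class FovExperimentReport:
    """Outcome of the truncated-feature prediction experiment."""

    mae_full: float
    mae_truncated: float
    mae_adjusted: float
    rs_full: float
    rs_truncated: float
    n_train: int
    n_test: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mae_full": self.mae_full,
            "mae_truncated": self.mae_truncated,
            "mae_adjusted": self.mae_adjusted,
            "rs_full": self.rs_full,
            "rs_truncated": self.rs_truncated,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
        }


def fov_offset_experiment(
    config: GeneratorConfig,
    n_train: int = 200,
    mae_kind: str = "median",
    **gpr_params,
) -> FovExperimentReport:
    """Demonstrate the offset mechanism of a truncated field of view.

    A GP age model is trained on full-coverage volumetric features of a
    training cohort. A separate test cohort is then predicted twice: from
    full-coverage features, and from features recomputed after reducing the
    field of view (the model never sees truncated data during training,
    mirroring an age model pre-trained on full-coverage scans). Truncation
    shifts every volumetric feature downward, which systematically offsets
    the predictions and inflates the MAE; the leave-one-out regression of
    full-coverage predictions on truncated predictions removes the offset.
    """
    from .synthetic import generate_cohort, generate_tissue_maps, make_fov_mask

    config.validate()
    train_config = config.replace(
        n_participants=n_train,
        n_retest=0,
        seed=(config.seed + 1_000_003) % (2**31),
    )
    train_cohort = generate_cohort(train_config)
    train_maps = generate_tissue_maps(train_cohort, train_config)[STANDARD]
    X_train, _ = extract_features(train_maps)
    model = GprAgeModel(**gpr_params).fit(
        X_train, train_cohort["age"].to_numpy()
    )

    test_cohort = generate_cohort(config)
    test_maps = generate_tissue_maps(test_cohort, config)[STANDARD]
    age = test_cohort["age"].to_numpy()
    X_full, _ = extract_features(test_maps)
    fov_mask = make_fov_mask(config)
    truncated_maps = {
        tissue: reduce_fov(test_maps[tissue], fov_mask) for tissue in TISSUES
    }
    X_trunc, _ = extract_features(truncated_maps)

    pred_full = model.predict(X_full)
    pred_trunc = model.predict(X_trunc)
    adjustment = loo_adjust(pred_trunc, pred_full, age, mae_kind=mae_kind)
    return FovExperimentReport(
        mae_full=mae(pred_full, age, kind=mae_kind),
        mae_truncated=mae(pred_trunc, age, kind=mae_kind),
        mae_adjusted=adjustment.adjusted_mae,
        rs_full=association(age, pred_full).rs,
        rs_truncated=association(age, pred_trunc).rs,
        n_train=n_train,
        n_test=len(test_cohort),
        seed=config.seed,
    )
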