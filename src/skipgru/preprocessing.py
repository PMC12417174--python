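"""Min-max normalization and polynomial-regression imputation.

Pipeline order is fixed: imputation runs first, on raw feature units, so
imputed values participate in the min/max fit; normalization then maps each
feature to [0, 1].

The imputation rule for a zero-coded feature is threshold-driven: if the
missing fraction is *strictly above* the decision threshold (default 5%)
the feature is imputed by a polynomial regression on the other features;
if it is positive but at or below the threshold the affected rows are
dropped instead; untouched if no value is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures

from .config import ImputationConfig
from .dataset import DatasetError, TabularDataset
from .reports import register_report

__all__ = [
    "NormalizationParams",
    "ImputationReport",
    "FeatureImputation",
    "Imputer",
    "fit_minmax",
    "apply_minmax",
    "invert_minmax",
    "missing_fraction",
    "impute",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------
@register_report
@dataclass
class NormalizationParams:
    """Per-feature minimum and maximum, in original feature units."""

    feature_names: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape or self.x_min.ndim != 1:
            raise ValueError("x_min/x_max must be 1-D arrays of equal length")
        if len(self.feature_names) != self.x_min.size:
            raise ValueError("feature_names length mismatch")
        if np.any(self.x_min > self.x_max):
            raise ValueError("x_min must be <= x_max per feature")


def fit_minmax(dataset: TabularDataset) -> NormalizationParams:
    """Per-feature min/max over all rows, ignoring zero-coded missing values."""
    miss = dataset.missing_mask()
    masked = np.ma.masked_array(dataset.features, mask=miss)
    x_min = np.asarray(masked.min(axis=0).filled(0.0), dtype=float)
    x_max = np.asarray(masked.max(axis=0).filled(0.0), dtype=float)
    return NormalizationParams(dataset.feature_names, x_min, x_max)


def apply_minmax(dataset: TabularDataset, params: NormalizationParams) -> TabularDataset:
    """Map each non-missing value to (x - x_min)/(x_max - x_min), clipped to [0, 1].

    A constant feature (x_min == x_max) maps to 0 with a logged warning.
    Zero-coded missing entries keep their 0 code.
    """
    if params.feature_names != dataset.feature_names:
        raise DatasetError("normalization params fitted on different feature names")
    span = params.x_max - params.x_min
    constant = span == 0.0
    if constant.any():
        names = [n for n, c in zip(dataset.feature_names, constant) if c]
        log.warning("constant features map to 0 under min-max scaling: %s", names)
    safe_span = np.where(constant, 1.0, span)
    scaled = (dataset.features - params.x_min) / safe_span
    scaled = np.where(constant, 0.0, scaled)
    scaled = np.clip(scaled, 0.0, 1.0)
    miss = dataset.missing_mask()
    scaled[miss] = 0.0
    return dataset.with_features(scaled)


def invert_minmax(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Undo the scaling: x = x_scaled * (x_max - x_min) + x_min."""
    return np.asarray(values) * (params.x_max - params.x_min) + params.x_min


# --------------------------------------------------------------------------
# imputation
# --------------------------------------------------------------------------
def missing_fraction(dataset: TabularDataset, feature: str) -> float:
    """Fraction of rows where the zero-coded feature holds the 0 code."""
    if feature not in dataset.missing_columns:
        raise DatasetError(f"feature {feature!r} is not declared zero-coded")
    col = dataset.column(feature)
    return float(np.count_nonzero(col == 0.0)) / dataset.n_samples


@register_report
@dataclass
class FeatureImputation:
    feature: str
    missing_fraction: float
    action: str  # none | impute | drop_rows
    degree: int | None = None
    predictor_features: tuple[str, ...] = ()
    n_values_imputed: int = 0


@register_report
@dataclass
class ImputationReport:
    threshold: float
    entries: list = field(default_factory=list)
    n_rows_dropped: int = 0

    def entry(self, feature: str) -> FeatureImputation:
        for e in self.entries:
            if e.feature == feature:
                return e
        raise KeyError(feature)


class Imputer:
    """Fit the per-feature action and regression models on one dataset,
    then apply to the same or held-out data (leakage-safe for CV).

    On training data (``transform``) the drop_rows action removes affected
    rows. On held-out data (``apply_holdout``) rows are never dropped:
    impute-action features are filled by the fitted polynomial model and
    drop-action features by the training-fold mean (a held-out patient
    cannot be discarded).
    """

    def __init__(self, config: ImputationConfig | None = None) -> None:
        self.config = config or ImputationConfig()
        self.config.validate()
        self.report_: ImputationReport | None = None
        self._models: dict[str, tuple[PolynomialFeatures, LinearRegression]] = {}
        self._means: dict[str, float] = {}
        self._obs_range: dict[str, tuple[float, float]] = {}
        self._feature_names: tuple[str, ...] | None = None

    def fit(self, dataset: TabularDataset) -> "Imputer":
        deg = self.config.degree
        thr = self.config.missing_threshold
        self._feature_names = dataset.feature_names
        report = ImputationReport(threshold=thr)
        for name in sorted(dataset.missing_columns, key=dataset.column_index):
            frac = missing_fraction(dataset, name)
            j = dataset.column_index(name)
            observed = dataset.features[:, j] != 0.0
            self._means[name] = (
                float(dataset.features[observed, j].mean()) if observed.any() else 0.0
            )
            if observed.any():
                self._obs_range[name] = (
                    float(dataset.features[observed, j].min()),
                    float(dataset.features[observed, j].max()),
                )
            if frac == 0.0:
                report.entries.append(FeatureImputation(name, frac, "none"))
                continue
            if frac <= thr:
                report.entries.append(FeatureImputation(name, frac, "drop_rows"))
                continue
            predictors = [k for k in range(dataset.n_features) if k != j]
            pred_names = tuple(dataset.feature_names[k] for k in predictors)
            poly = PolynomialFeatures(degree=deg, include_bias=False)
            X_obs = poly.fit_transform(dataset.features[observed][:, predictors])
            n_coef = X_obs.shape[1] + 1
            if X_obs.shape[0] < n_coef:
                raise DatasetError(
                    f"feature {name!r}: {X_obs.shape[0]} complete rows cannot fit "
                    f"a degree-{deg} polynomial with {n_coef} coefficients"
                )
            model = LinearRegression()
            model.fit(X_obs, dataset.features[observed, j])
            self._models[name] = (poly, model)
            report.entries.append(
                FeatureImputation(
                    name, frac, "impute", degree=deg,
                    predictor_features=pred_names,
                    n_values_imputed=int(np.count_nonzero(~observed)),
                )
            )
        self.report_ = report
        return self

    def _check_fitted(self, dataset: TabularDataset) -> None:
        if self.report_ is None:
            raise RuntimeError("Imputer not fitted")
        if dataset.feature_names != self._feature_names:
            raise DatasetError("imputer fitted on different feature names")

    def _fill(self, dataset: TabularDataset, fill_drop_with_mean: bool) -> TabularDataset:
        feats = dataset.features.copy()
        for entry in self.report_.entries:
            j = dataset.column_index(entry.feature)
            missing = feats[:, j] == 0.0
            if not missing.any():
                continue
            if entry.action == "impute":
                poly, model = self._models[entry.feature]
                predictors = [k for k in range(dataset.n_features) if k != j]
                pred = model.predict(poly.transform(feats[missing][:, predictors]))
                # keep imputed values inside the observed range: clinical
                # features are positive and 0 must stay reserved as the code
                lo, hi = self._obs_range[entry.feature]
                feats[missing, j] = np.clip(pred, lo, hi)
            elif entry.action == "drop_rows" and fill_drop_with_mean:
                feats[missing, j] = self._means[entry.feature]
        return dataset.with_features(feats)

    def transform(self, dataset: TabularDataset) -> tuple[TabularDataset, ImputationReport]:
        """Impute/drop on (typically) the data the imputer was fitted on."""
        self._check_fitted(dataset)
        filled = self._fill(dataset, fill_drop_with_mean=False)
        keep = np.ones(dataset.n_samples, dtype=bool)
        for entry in self.report_.entries:
            if entry.action == "drop_rows":
                j = dataset.column_index(entry.feature)
                keep &= filled.features[:, j] != 0.0
        self.report_.n_rows_dropped = int(np.count_nonzero(~keep))
        return filled.take_rows(np.flatnonzero(keep)), self.report_

    def apply_holdout(self, dataset: TabularDataset) -> TabularDataset:
        """Fill a held-out fold without dropping any row."""
        self._check_fitted(dataset)
        return self._fill(dataset, fill_drop_with_mean=True)


def impute(
    dataset: TabularDataset, config: ImputationConfig | None = None
) -> tuple[TabularDataset, ImputationReport]:
    """One-shot fit+transform; output has no missing codes in treated columns."""
    imp = Imputer(config)
    imp.fit(dataset)
    return imp.transform(dataset)
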