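"""Synthetic clinical-tabular data with known ground truth.

Generates datasets with the statistical structure the pipeline assumes:

* a subset of *informative* features whose class-conditional means are
  separated by a configurable effect size (in noise-SD units), so a Bayes
  error is computable and feature-selection recovery is scoreable;
* *zero-coded missingness* in designated columns, imposed after an affine
  rescaling into strictly positive clinical-looking ranges so the 0 code
  never collides with a legitimate value;
* configurable class imbalance (e.g. the 103/53/844 three-class layout);
* an optional polynomial link between two features for exercising
  regression-based imputation.

Presets emulate the two public clinical layouts the pipeline targets: an
8-feature/2-class cohort of 768 patients ("pima-like") and a
~12-feature/3-class cohort of 1000 patients ("lmch-like").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import TabularDataset
from .reports import register_report

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "presets"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``effect_size`` is the separation between adjacent class means of an
    informative feature, in units of the within-class SD (1.0).
    ``missing_spec`` maps feature index -> fraction of rows zeroed out.
    ``polynomial_link`` is ``(target_idx, source_idx, coeffs, noise_sd)``:
    the target feature is overwritten with
    ``polyval(coeffs, source) + noise`` before rescaling.
    """

    n_samples: int
    n_features: int
    informative: tuple[int, ...]
    effect_size: float = 1.0
    n_classes: int = 2
    class_priors: tuple[float, ...] | None = None
    missing_spec: Mapping[int, float] = field(default_factory=dict)
    feature_ranges: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    default_range: tuple[float, float] = (10.0, 100.0)
    polynomial_link: tuple[int, int, tuple[float, ...], float] | None = None
    feature_names: tuple[str, ...] | None = None
    class_names: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be >= 1")
        if not set(self.informative) <= set(range(self.n_features)):
            raise ValueError("informative indices out of range")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.class_priors is not None:
            if len(self.class_priors) != self.n_classes:
                raise ValueError("class_priors must have one entry per class")
            if min(self.class_priors) <= 0.0:
                raise ValueError("class_priors must be strictly positive")
        for j, frac in self.missing_spec.items():
            if not 0 <= j < self.n_features or not 0.0 <= frac < 1.0:
                raise ValueError("missing_spec entries must be valid (index, fraction<1)")
        for lo, hi in {**dict(self.feature_ranges), -1: self.default_range}.values():
            if not 0.0 < lo < hi:
                raise ValueError("feature ranges must be strictly positive with lo < hi")
        if self.polynomial_link is not None:
            tgt, src, coeffs, noise_sd = self.polynomial_link
            if tgt == src or not (0 <= tgt < self.n_features and 0 <= src < self.n_features):
                raise ValueError("polynomial_link indices invalid")
            if noise_sd < 0:
                raise ValueError("polynomial_link noise_sd must be >= 0")

    def priors(self) -> tuple[float, ...]:
        if self.class_priors is None:
            return tuple([1.0 / self.n_classes] * self.n_classes)
        total = float(sum(self.class_priors))
        return tuple(p / total for p in self.class_priors)

    def names(self) -> tuple[str, ...]:
        if self.feature_names is not None:
            if len(self.feature_names) != self.n_features:
                raise ValueError("feature_names length mismatch")
            return self.feature_names
        return tuple(f"f{j}" for j in range(self.n_features))


@register_report
@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-deriving anything."""

    informative: tuple[int, ...]
    pre_missing_features: np.ndarray  # values before zeroing, after rescaling
    missing_mask: np.ndarray          # True where a value was zeroed out
    link: tuple | None
    seed: int


def generate(spec: SyntheticSpec, seed: int = 0) -> tuple[TabularDataset, GroundTruth]:
    """Draw one dataset from the spec; fully determined by (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n, d = spec.n_samples, spec.n_features
    priors = np.asarray(spec.priors())
    labels = rng.choice(spec.n_classes, size=n, p=priors)

    # class-conditional Gaussians for informative features, pure noise else
    raw = rng.standard_normal((n, d))
    for j in spec.informative:
        raw[:, j] += spec.effect_size * labels

    if spec.polynomial_link is not None:
        tgt, src, coeffs, noise_sd = spec.polynomial_link
        raw[:, tgt] = np.polyval(list(coeffs), raw[:, src])
        if noise_sd > 0:
            raw[:, tgt] += noise_sd * rng.standard_normal(n)

    # affine map each column into its (strictly positive) clinical range
    features = np.empty_like(raw)
    for j in range(d):
        lo, hi = dict(spec.feature_ranges).get(j, spec.default_range)
        cmin, cmax = raw[:, j].min(), raw[:, j].max()
        span = cmax - cmin
        if span == 0.0:
            features[:, j] = (lo + hi) / 2.0
        else:
            features[:, j] = lo + (raw[:, j] - cmin) / span * (hi - lo)

    pre_missing = features.copy()
    missing_mask = np.zeros((n, d), dtype=bool)
    names = spec.names()
    missing_cols = []
    for j, frac in sorted(spec.missing_spec.items()):
        n_miss = int(round(frac * n))
        idx = rng.choice(n, size=n_miss, replace=False)
        features[idx, j] = 0.0
        missing_mask[idx, j] = True
        missing_cols.append(names[j])

    class_names = spec.class_names or tuple(f"c{c}" for c in range(spec.n_classes))
    dataset = TabularDataset(
        features=features,
        labels=labels,
        feature_names=names,
        class_names=class_names,
        missing_columns=frozenset(missing_cols),
    )
    truth = GroundTruth(
        informative=tuple(spec.informative),
        pre_missing_features=pre_missing,
        missing_mask=missing_mask,
        link=spec.polynomial_link,
        seed=seed,
    )
    return dataset, truth


_PIMA_NAMES = (
    "pregnancies", "glucose", "blood_pressure", "skin_thickness",
    "insulin", "bmi", "pedigree", "age",
)
_LMCH_NAMES = (
    "age", "gender", "urea", "creatinine", "hba1c", "cholesterol",
    "triglycerides", "hdl", "ldl", "vldl", "bmi", "blood_sugar",
)


def presets() -> dict[str, SyntheticSpec]:
    """Named recipes emulating the clinical layouts the pipeline targets.

    ``pima-like``: 768 patients, 8 features, 2 classes with 500/268 split,
    zero-coded missingness in the five columns where 0 is physiologically
    impossible, informative set matching the clinically relevant features
    (glucose, insulin, BMI, pedigree, age).

    ``lmch-like``: 1000 patients, 12 features, 3 classes with the heavily
    imbalanced 103/53/844 split, informative set = HbA1c, blood sugar,
    BMI, age, LDL.
    """
    pima = SyntheticSpec(
        n_samples=768,
        n_features=8,
        informative=(1, 4, 5, 6, 7),
        effect_size=1.0,
        n_classes=2,
        class_priors=(500 / 768, 268 / 768),
        missing_spec={1: 0.007, 2: 0.046, 3: 0.30, 4: 0.49, 5: 0.014},
        feature_ranges={
            0: (1.0, 17.0), 1: (44.0, 199.0), 2: (24.0, 122.0),
            3: (7.0, 99.0), 4: (14.0, 846.0), 5: (18.0, 67.0),
            6: (0.08, 2.42), 7: (21.0, 81.0),
        },
        feature_names=_PIMA_NAMES,
        class_names=("non_diabetic", "diabetic"),
    )
    lmch = SyntheticSpec(
        n_samples=1000,
        n_features=12,
        informative=(0, 4, 8, 10, 11),
        effect_size=1.0,
        n_classes=3,
        class_priors=(103 / 1000, 53 / 1000, 844 / 1000),
        missing_spec={4: 0.02, 11: 0.02},
        feature_ranges={
            0: (20.0, 79.0), 1: (1.0, 2.0), 2: (0.5, 38.9), 3: (6.0, 800.0),
            4: (0.9, 16.0), 5: (0.1, 10.3), 6: (0.3, 13.8), 7: (0.2, 9.9),
            8: (0.3, 9.9), 9: (0.1, 35.0), 10: (19.0, 47.8), 11: (0.5, 25.0),
        },
        feature_names=_LMCH_NAMES,
        class_names=("normal", "prediabetes", "diabetes"),
    )
    return {"pima-like": pima, "lmch-like": lmch}
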