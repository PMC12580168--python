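"""Trainable plasma-volume estimator from CBC + anthropometrics.

The estimator maps one complete blood count (plus sex, age, height and
optionally weight) to absolute plasma volume in mL.  Three regressor
families are offered — ordinary least squares, gradient-boosted trees and
RBF kernel ridge — behind a single artifact type.  A weight-free variant
supports the anti-doping setting where body weight is unreliable; since
passport interpretation rests on PV *changes* between visits rather than
absolute levels, dropping weight mostly costs absolute accuracy.

The module also provides the supporting statistics the estimator is used
with: per-marker perturbation sensitivity grids, estimated-vs-measured
validation (Spearman rank correlation + Bland–Altman agreement) and the
per-sex weighting index — the R² of the simple linear regression between
estimated PV and hemoglobin concentration, which quantifies how much of
the [Hb] variation is attributable to PV shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .domain import ANTHROPOMETRICS, CBC_MARKERS, CBCSample, PVEstimate, Sex

ARTIFACT_VERSION = 1

#: Default feature set: full CBC panel plus demographics.
DEFAULT_FEATURES = (*CBC_MARKERS, *ANTHROPOMETRICS)

#: Perturbation levels (percent) applied in the sensitivity analysis.
SENSITIVITY_LEVELS = (-0.2, -0.1, -0.05, 0.05, 0.1, 0.2)

#: Per-sex weighting index defaults: R² of the estimated-PV ↔ [Hb]
#: regression (fraction of [Hb] variation attributable to PV shifts).
DEFAULT_WEIGHTS = {Sex.MALE: 0.28, Sex.FEMALE: 0.42}

#: Estimates below this floor (mL) are clamped with a warning.
PV_FLOOR_ML = 100.0

MIN_TRAINING_SAMPLES = 30

REGRESSOR_KINDS = ("linear", "tree_ensemble", "kernel")


def _make_regressor(kind: str, seed: int):
    if kind == "linear":
        core = LinearRegression()
    elif kind == "tree_ensemble":
        # boosted trees on top of an OLS baseline: the linear part carries
        # the smooth concentration/anthropometric signal, the trees learn
        # interaction corrections (e.g. discounting hematocrit shifts that
        # co-occur with suppressed reticulocytes)
        core = GradientBoostingRegressor(
            init=LinearRegression(),
            n_estimators=600,
            max_depth=3,
            learning_rate=0.05,
            min_samples_leaf=10,
            subsample=0.9,
            random_state=seed,
        )
    elif kind == "kernel":
        core = KernelRidge(alpha=0.01, kernel="rbf", gamma=0.05)
    else:
        raise ValueError(
            f"regressor_kind must be one of {REGRESSOR_KINDS}, got {kind!r}"
        )
    pipe = Pipeline([("scale", StandardScaler()), ("regress", core)])
    if kind == "kernel":
        # kernel ridge needs the target on unit scale as well
        return TransformedTargetRegressor(
            regressor=pipe, transformer=StandardScaler()
        )
    return pipe


def _design_matrix(frame: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Numeric design matrix; sex is encoded male=1 / female=0."""
    missing = [f for f in features if f not in frame.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {', '.join(missing)}")
    cols = []
    for f in features:
        if f == "sex":
            col = frame["sex"].map(
                lambda s: 1.0 if Sex.coerce(s) is Sex.MALE else 0.0
            )
        else:
            col = pd.to_numeric(frame[f], errors="coerce")
        if col.isna().any():
            raise ValueError(f"feature {f!r} contains missing values")
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclass
class PVModel:
    """Fitted plasma-volume regression artifact."""

    pipeline: object  # fitted sklearn estimator
    feature_list: tuple[str, ...]
    regressor_kind: str
    weight_free: bool
    training_meta: dict = field(default_factory=dict)

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Estimated PV (mL) for every row; deterministic given the fit."""
        X = _design_matrix(frame, self.feature_list)
        pv = np.asarray(self.pipeline.predict(X), dtype=float)
        if np.any(pv < PV_FLOOR_ML):
            warnings.warn(
                f"{int(np.sum(pv < PV_FLOOR_ML))} PV estimate(s) below "
                f"{PV_FLOOR_ML} mL clamped to the floor",
                stacklevel=2,
            )
            pv = np.maximum(pv, PV_FLOOR_ML)
        return pv

    def save(self, path) -> None:
        joblib.dump(
            {
                "version": ARTIFACT_VERSION,
                "feature_list": self.feature_list,
                "regressor_kind": self.regressor_kind,
                "weight_free": self.weight_free,
                "training_meta": self.training_meta,
                "pipeline": self.pipeline,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PVModel":
        blob = joblib.load(path)
        if blob.get("version") != ARTIFACT_VERSION:
            raise ValueError(
                f"unsupported model artifact version {blob.get('version')!r}"
            )
        return cls(
            pipeline=blob["pipeline"],
            feature_list=tuple(blob["feature_list"]),
            regressor_kind=blob["regressor_kind"],
            weight_free=blob["weight_free"],
            training_meta=blob["training_meta"],
        )


def train_pv_model(
    samples: pd.DataFrame,
    regressor_kind: str = "tree_ensemble",
    weight_free: bool = False,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
) -> PVModel:
    """Fit a PV estimator on samples carrying measured plasma volume.

    Parameters
    ----------
    samples
        Sample table with the feature columns and ``pv_measured`` (mL).
    regressor_kind
        ``linear`` | ``tree_ensemble`` | ``kernel``.
    weight_free
        Exclude body weight from the feature list (retraining option for
        settings where weight cannot be obtained reliably).
    seed
        Makes stochastic regressors reproducible.
    """
    if features is None:
        features = DEFAULT_FEATURES
    features = tuple(features)
    if weight_free:
        features = tuple(f for f in features if f != "weight")
    if "pv_measured" not in samples.columns:
        raise KeyError("missing feature column(s): pv_measured")
    fit_frame = samples.dropna(subset=["pv_measured"])
    n = len(fit_frame)
    if n < MIN_TRAINING_SAMPLES:
        raise ValueError(
            f"need at least {MIN_TRAINING_SAMPLES} samples with measured PV "
            f"to train, got {n}"
        )
    X = _design_matrix(fit_frame, features)
    y = fit_frame["pv_measured"].to_numpy(dtype=float)
    pipeline = _make_regressor(regressor_kind, seed)
    pipeline.fit(X, y)
    return PVModel(
        pipeline=pipeline,
        feature_list=features,
        regressor_kind=regressor_kind,
        weight_free=weight_free,
        training_meta={"n": n, "seed": seed},
    )


def train_default_model(seed: int = 0, n_subjects: int = 120) -> PVModel:
    """The package's default PV estimator, retrained deterministically.

    Boosted-tree regressor fitted on a heterogeneous synthetic reference
    cohort (controls plus fluid-shift and erythropoietic scenarios).  The
    artifact is regenerated from the seed rather than shipped, so runs
    are reproducible from source alone.
    """
    from .simulate import generate_cohort, training_cohort_config

    samples, _ = generate_cohort(
        training_cohort_config(seed=seed, n_subjects=n_subjects)
    )
    return train_pv_model(
        samples, regressor_kind="tree_ensemble", seed=seed
    )


def estimate_pv(model: PVModel, sample: "CBCSample | dict | pd.Series") -> PVEstimate:
    """Estimate plasma volume (mL) for a single visit."""
    if isinstance(sample, CBCSample):
        row = sample.as_row()
    elif isinstance(sample, pd.Series):
        row = sample.to_dict()
    else:
        row = dict(sample)
    frame = pd.DataFrame([row])
    pv = float(model.predict_frame(frame)[0])
    return PVEstimate(pv=pv)


def perturb_marker(frame: pd.DataFrame, marker: str, level_pct: float) -> pd.DataFrame:
    """Copy of ``frame`` with one CBC marker scaled by ``1 + level/100``."""
    if marker not in CBC_MARKERS:
        raise ValueError(
            f"unknown CBC marker {marker!r}; expected one of {CBC_MARKERS}"
        )
    out = frame.copy()
    out[marker] = out[marker] * (1.0 + level_pct / 100.0)
    return out


def sensitivity_analysis(
    model: PVModel,
    samples: pd.DataFrame,
    levels: Sequence[float] = SENSITIVITY_LEVELS,
    markers: Sequence[str] = CBC_MARKERS,
) -> pd.DataFrame:
    """Per-marker leverage on the PV estimate under small perturbations.

    Each marker is individually scaled by every percent level before
    re-estimating; the grid cell is the mean difference (mL) relative to
    the unperturbed estimates.  Rows: levels (%); columns: markers.
    """
    for m in markers:
        if m not in CBC_MARKERS:
            raise ValueError(
                f"unknown CBC marker {m!r}; expected one of {CBC_MARKERS}"
            )
    base = model.predict_frame(samples)
    grid = pd.DataFrame(
        index=pd.Index(list(levels), name="level_pct"),
        columns=list(markers),
        dtype=float,
    )
    for marker in markers:
        for level in levels:
            if level == 0:
                grid.loc[level, marker] = 0.0
                continue
            perturbed = perturb_marker(samples, marker, level)
            grid.loc[level, marker] = float(
                np.mean(model.predict_frame(perturbed) - base)
            )
    return grid


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float


@dataclass
class ValidationReport:
    """Agreement between estimated and measured PV."""

    spearman_r: float
    p_value: float
    bland_altman: BlandAltman
    n: int
    per_sex: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "spearman_r": self.spearman_r,
            "p_value": self.p_value,
            "bland_altman_bias_ml": self.bland_altman.bias,
            "limits_of_agreement_ml": [
                self.bland_altman.loa_lower,
                self.bland_altman.loa_upper,
            ],
            "n": self.n,
            "per_sex": {
                k: {
                    "spearman_r": v.spearman_r,
                    "p_value": v.p_value,
                    "bland_altman_bias_ml": v.bland_altman.bias,
                    "limits_of_agreement_ml": [
                        v.bland_altman.loa_lower,
                        v.bland_altman.loa_upper,
                    ],
                    "n": v.n,
                }
                for k, v in self.per_sex.items()
            },
        }


def _validate_pair(estimated: np.ndarray, measured: np.ndarray) -> ValidationReport:
    diff = estimated - measured
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    ba = BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd)
    if np.ptp(estimated) == 0 or np.ptp(measured) == 0:
        r, p = float("nan"), float("nan")  # rank correlation undefined
    else:
        r, p = stats.spearmanr(estimated, measured)
        r, p = float(r), float(p)
    return ValidationReport(r, p, ba, n=len(diff))


def validate_pv_model(
    estimated: Sequence[float],
    measured: Sequence[float],
    sex_labels: Optional[Sequence] = None,
) -> ValidationReport:
    """Spearman correlation and Bland–Altman agreement, optionally per sex.

    Bias is ``mean(estimated − measured)`` in mL; limits of agreement are
    ``bias ± 1.96·SD`` of the differences.
    """
    estimated = np.asarray(estimated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if estimated.shape != measured.shape:
        raise ValueError("estimated and measured must have equal length")
    if estimated.size < 3:
        raise ValueError("need at least 3 pairs")
    report = _validate_pair(estimated, measured)
    if sex_labels is not None:
        sex_arr = np.array([Sex.coerce(s).value for s in sex_labels])
        for sex in np.unique(sex_arr):
            mask = sex_arr == sex
            if mask.sum() >= 3:
                report.per_sex[sex] = _validate_pair(
                    estimated[mask], measured[mask]
                )
    return report


def pv_hb_regression(pv: Sequence[float], hb: Sequence[float]):
    """OLS of [Hb] on estimated PV: returns (slope, intercept, r_squared).

    R² is orientation-free for a simple linear regression (it equals the
    squared Pearson correlation), so only the slope depends on which
    variable is treated as the response.
    """
    pv = np.asarray(pv, dtype=float)
    hb = np.asarray(hb, dtype=float)
    if pv.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pv) == 0 or np.ptp(hb) == 0:
        raise ValueError("degenerate (constant) series: R² undefined")
    res = stats.linregress(pv, hb)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def weighting_index(pv: Sequence[float], hb: Sequence[float]) -> float:
    """R² of the estimated-PV ↔ [Hb] linear regression (one sex's data)."""
    _, _, r2 = pv_hb_regression(pv, hb)
    return r2


def fit_weighting_indices(
    frame: pd.DataFrame,
    pv_col: str = "pv_estimated",
    hb_col: str = "hb",
) -> dict[Sex, float]:
    """Per-sex weighting indices fitted from a cohort table."""
    out: dict[Sex, float] = {}
    for sex_val, grp in frame.groupby("sex"):
        sex = Sex.coerce(sex_val)
        out[sex] = weighting_index(grp[pv_col], grp[hb_col])
    return out
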