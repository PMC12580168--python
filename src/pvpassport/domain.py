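"""Core data types, unit conventions and closed-form marker computations.

Unit conventions used throughout the package:

* hemoglobin concentration ``hb`` — g·dL⁻¹ (the ×10 conversion to g·L⁻¹
  happens only inside :func:`compute_off_score`)
* hematocrit ``hct`` — %
* red-cell count ``rbc`` — 10⁶·µL⁻¹
* reticulocyte percentage ``ret_pct`` — %
* mean corpuscular volume ``mcv`` — fL
* mean corpuscular hemoglobin concentration ``mchc`` — g·dL⁻¹
* plasma volume — mL
* height — cm, weight — kg, age — years
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def coerce(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError as exc:
            raise ValueError(
                f"sex must be 'male' or 'female', got {value!r}"
            ) from exc


class Flag(str, enum.Enum):
    """Per-visit atypical-passport-finding status for one marker."""

    NONE = "none"
    ATPF = "atpf"
    ATPF_EXPLAINED_BY_PV = "atpf_explained_by_pv"


#: CBC markers carried by every sample, in canonical column order.
CBC_MARKERS = ("hb", "hct", "rbc", "ret_pct", "mcv", "mchc")

#: Anthropometric / demographic covariates.
ANTHROPOMETRICS = ("sex", "age", "height", "weight")

#: Canonical CSV column order for longitudinal sample tables.
SAMPLE_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "height",
    "weight",
    "visit_index",
    *CBC_MARKERS,
    "pv_measured",
)


@dataclass
class CBCSample:
    """One visit's complete-blood-count panel plus anthropometrics."""

    subject_id: str
    sex: Sex
    age: float
    height: float
    visit_index: int
    hb: float
    hct: float
    rbc: float
    ret_pct: float
    mcv: float
    mchc: float
    weight: Optional[float] = None
    pv_measured: Optional[float] = None

    def __post_init__(self) -> None:
        self.sex = Sex.coerce(self.sex)
        self.validate()

    def validate(self) -> None:
        if not self.hb > 0:
            raise ValueError(f"hb must be > 0, got {self.hb}")
        if not 0 < self.hct < 100:
            raise ValueError(f"hct must be in (0, 100), got {self.hct}")
        if not 0 <= self.ret_pct < 100:
            raise ValueError(f"ret_pct must be in [0, 100), got {self.ret_pct}")
        if self.visit_index < 1:
            raise ValueError(
                f"visit_index must be >= 1, got {self.visit_index}"
            )

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "sex": self.sex.value,
            "age": self.age,
            "height": self.height,
            "weight": self.weight,
            "visit_index": self.visit_index,
            "hb": self.hb,
            "hct": self.hct,
            "rbc": self.rbc,
            "ret_pct": self.ret_pct,
            "mcv": self.mcv,
            "mchc": self.mchc,
            "pv_measured": self.pv_measured,
        }


@dataclass(frozen=True)
class OffScore:
    value: float


@dataclass(frozen=True)
class PVEstimate:
    """Estimated plasma volume (mL) with its per-sex standardized z-score."""

    pv: float
    z_score: float = math.nan


@dataclass(frozen=True)
class LimitPair:
    """Lower/upper individual reference limits for one marker at one visit."""

    lower: float
    upper: float
    specificity: float = 0.99

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"lower must be < upper, got ({self.lower}, {self.upper})"
            )
        if not 0 < self.specificity < 1:
            raise ValueError(
                f"specificity must be in (0, 1), got {self.specificity}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0


def compute_off_score(hb, ret_pct):
    """OFF-score: ``hb[g·dL⁻¹]·10 − 60·√ret_pct``.

    The ×10 converts hemoglobin from g·dL⁻¹ to g·L⁻¹; the reticulocyte
    term penalises active erythropoiesis, making the score sensitive to
    withdrawal of erythropoietic stimulation.  Accepts scalars or arrays.
    """
    hb = np.asarray(hb, dtype=float)
    ret_pct = np.asarray(ret_pct, dtype=float)
    if np.any(hb <= 0):
        raise ValueError("hb must be > 0")
    if np.any(ret_pct < 0):
        raise ValueError("ret_pct must be >= 0 (square root undefined)")
    value = hb * 10.0 - 60.0 * np.sqrt(ret_pct)
    if value.ndim == 0:
        return float(value)
    return value


def pv_z_scores(pv_series, group_mean: float, group_sd: float):
    """Standardize plasma volumes against a (per-sex) group mean and SD."""
    if not group_sd > 0:
        raise ValueError(f"group SD must be > 0, got {group_sd}")
    pv = np.asarray(pv_series, dtype=float)
    z = (pv - group_mean) / group_sd
    if z.ndim == 0:
        return float(z)
    return z


def cohort_pv_z(frame: pd.DataFrame, pv_col: str = "pv_estimated") -> pd.Series:
    """Per-sex z-scores of estimated PV over all visits of a cohort.

    The mean and SD are computed across every estimate of the same sex in
    ``frame`` (cohort-level standardization).
    """
    if pv_col not in frame:
        raise KeyError(f"column {pv_col!r} missing")
    out = pd.Series(np.nan, index=frame.index, name="pv_z")
    for _, idx in frame.groupby("sex").groups.items():
        vals = frame.loc[idx, pv_col].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if sd > 0:
            out.loc[idx] = (vals - float(np.mean(vals))) / sd
        else:
            out.loc[idx] = 0.0
    return out


def samples_from_frame(frame: pd.DataFrame) -> list[CBCSample]:
    """Convert a sample table to validated :class:`CBCSample` objects."""
    samples = []
    for _, row in frame.iterrows():
        weight = row.get("weight")
        pv = row.get("pv_measured")
        samples.append(
            CBCSample(
                subject_id=str(row["subject_id"]),
                sex=Sex.coerce(row["sex"]),
                age=float(row["age"]),
                height=float(row["height"]),
                weight=None if pd.isna(weight) else float(weight),
                visit_index=int(row["visit_index"]),
                hb=float(row["hb"]),
                hct=float(row["hct"]),
                rbc=float(row["rbc"]),
                ret_pct=float(row["ret_pct"]),
                mcv=float(row["mcv"]),
                mchc=float(row["mchc"]),
                pv_measured=None if pd.isna(pv) else float(pv),
            )
        )
    return samples


def frame_from_samples(samples: Sequence[CBCSample]) -> pd.DataFrame:
    frame = pd.DataFrame([s.as_row() for s in samples])
    return frame[list(SAMPLE_COLUMNS)]
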