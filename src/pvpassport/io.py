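"""CSV and config file I/O.

Sample tables use a documented dialect: UTF-8, '.' decimal, header names
matching :data:`pvpassport.domain.SAMPLE_COLUMNS`.  Units are fixed
([Hb] g·dL⁻¹, HCT %, RBC 10⁶·µL⁻¹, RET% %, MCV fL, MCHC g·dL⁻¹, PV mL).
Real visit dates are accepted via a ``visit_date`` column and mapped to
ordinal visit indices per subject; no computation uses elapsed time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .domain import SAMPLE_COLUMNS, Sex
from .limits import DEFAULT_PRIORS, PopulationPrior

REQUIRED_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "height",
    "visit_index",
    "hb",
    "hct",
    "rbc",
    "ret_pct",
    "mcv",
    "mchc",
)

_NUMERIC_COLUMNS = (
    "age",
    "height",
    "weight",
    "visit_index",
    "hb",
    "hct",
    "rbc",
    "ret_pct",
    "mcv",
    "mchc",
    "pv_measured",
)


class SampleFileError(ValueError):
    """Malformed sample CSV (message carries the offending line number)."""


def read_samples(path) -> pd.DataFrame:
    """Read and validate a longitudinal sample table.

    Raises :class:`SampleFileError` naming the first offending CSV line
    for malformed rows, and for empty files.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise SampleFileError(f"{path}: no samples")
    if "visit_index" not in frame.columns and "visit_date" in frame.columns:
        frame["visit_date"] = pd.to_datetime(frame["visit_date"])
        frame = frame.sort_values(["subject_id", "visit_date"])
        frame["visit_index"] = frame.groupby("subject_id").cumcount() + 1
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SampleFileError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for col in _NUMERIC_COLUMNS:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise SampleFileError(
                f"{path}, line {line}: non-numeric value "
                f"{frame.loc[bad.idxmax(), col]!r} in column {col!r}"
            )
        frame[col] = coerced
    nan_required = [
        c for c in REQUIRED_COLUMNS if c in _NUMERIC_COLUMNS
    ]
    for col in nan_required:
        if frame[col].isna().any():
            line = int(frame[col].isna().idxmax()) + 2
            raise SampleFileError(
                f"{path}, line {line}: missing value in column {col!r}"
            )
    frame["sex"] = frame["sex"].map(lambda s: Sex.coerce(s).value)
    frame["visit_index"] = frame["visit_index"].astype(int)
    if "weight" not in frame.columns:
        frame["weight"] = float("nan")
    if "pv_measured" not in frame.columns:
        frame["pv_measured"] = float("nan")
    frame = frame.sort_values(["subject_id", "visit_index"]).reset_index(
        drop=True
    )
    dup = frame.duplicated(["subject_id", "visit_index"])
    if dup.any():
        raise SampleFileError(
            f"{path}: duplicate visit_index within subject "
            f"{frame.loc[dup.idxmax(), 'subject_id']!r}"
        )
    return frame


def write_samples(frame: pd.DataFrame, path) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    frame[cols + extra].to_csv(path, index=False)


def write_ground_truth(truth, path) -> None:
    truth.to_frame().to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_priors(path_or_dict) -> dict[tuple[str, Sex], PopulationPrior]:
    """Priors from a YAML config (``priors: {marker: {sex: {...}}}``).

    Unspecified marker × sex combinations fall back to the defaults.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            blob = yaml.safe_load(fh) or {}
    else:
        blob = dict(path_or_dict)
    priors = dict(DEFAULT_PRIORS)
    for marker, by_sex in (blob.get("priors") or {}).items():
        for sex_key, params in by_sex.items():
            sex = Sex.coerce(sex_key)
            priors[(marker, sex)] = PopulationPrior(
                marker=marker,
                sex=sex,
                mu_pop=float(params["mu"]),
                sigma_between=float(params["sigma_between"]),
                sigma_within=float(params["sigma_within"]),
            )
    return priors


def load_weights(path_or_dict) -> Optional[dict[Sex, float]]:
    """Per-sex weighting indices from a YAML config (``weights:`` block)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            blob = yaml.safe_load(fh) or {}
    else:
        blob = dict(path_or_dict)
    weights = blob.get("weights")
    if weights is None:
        return None
    return {Sex.coerce(k): float(v) for k, v in weights.items()}
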