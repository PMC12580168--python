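"""Cohort-level assembly: limits, PV estimates, corrections, flags.

``build_profiles`` turns a sample table plus a fitted PV model into one
:class:`SubjectProfile` per subject: prequential individual limits for
[Hb] and OFF-score, per-visit PV estimates with per-sex cohort z-scores,
PV-corrected [Hb] limits, and reclassified atypical findings.
``run_pipeline`` adds file and figure output around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .correction import (
    CorrectedLimitPair,
    PVShift,
    correction_series,
    correction_table,
    reclassify_flags,
)
from .domain import Flag, LimitPair, Sex, cohort_pv_z, compute_off_score
from .limits import DEFAULT_PRIORS, PopulationPrior, flag_atpf, profile_limits
from .pvmodel import DEFAULT_WEIGHTS, PVModel

logger = logging.getLogger("pvpassport")


@dataclass
class SubjectProfile:
    """Ordered per-subject series with limits, PV estimates and flags."""

    subject_id: str
    sex: Sex
    samples: pd.DataFrame
    hb: np.ndarray
    offs: np.ndarray
    limits_hb: list[LimitPair]
    limits_offs: list[LimitPair]
    pv_estimates: np.ndarray
    pv_z: np.ndarray
    shifts: list[PVShift]
    corrected_limits_hb: list[CorrectedLimitPair]
    flags_hb: list[Flag]
    flags_offs: list[Flag]
    new_outliers: np.ndarray

    def correction_table(self) -> pd.DataFrame:
        table = correction_table(
            self.samples["visit_index"],
            self.hb,
            self.pv_estimates,
            self.shifts,
            self.limits_hb,
            self.corrected_limits_hb,
            self.flags_hb,
            self.new_outliers,
        )
        table.insert(0, "subject_id", self.subject_id)
        table["pv_z"] = self.pv_z
        return table


def build_profiles(
    samples: pd.DataFrame,
    model: PVModel,
    priors: Optional[dict[tuple[str, Sex], PopulationPrior]] = None,
    specificity: float = 0.99,
    weights: Optional[dict[Sex, float]] = None,
) -> list[SubjectProfile]:
    """Assemble per-subject passport profiles from a cohort table.

    Limits for visit *i* use history strictly before *i*; ATPF flags are
    assessed against the original limits and then reclassified as
    PV-explained where the value falls inside the corrected limits.
    OFF-score limits are computed and flagged but never corrected.
    """
    if priors is None:
        priors = DEFAULT_PRIORS
    if weights is None:
        weights = DEFAULT_WEIGHTS
    samples = samples.sort_values(["subject_id", "visit_index"])
    pv_all = model.predict_frame(samples)
    samples = samples.assign(pv_estimated=pv_all)
    samples = samples.assign(pv_z=cohort_pv_z(samples))

    profiles: list[SubjectProfile] = []
    for subject_id, grp in samples.groupby("subject_id", sort=True):
        sex = Sex.coerce(grp["sex"].iloc[0])
        hb = grp["hb"].to_numpy(dtype=float)
        offs = np.asarray(
            compute_off_score(hb, grp["ret_pct"].to_numpy(dtype=float))
        )
        limits_hb = profile_limits(priors[("hb", sex)], hb, specificity)
        limits_offs = profile_limits(priors[("offs", sex)], offs, specificity)
        pv = grp["pv_estimated"].to_numpy(dtype=float)
        shifts, corrected = correction_series(pv, limits_hb, sex, weights)
        flags_hb = [flag_atpf(v, l) for v, l in zip(hb, limits_hb)]
        flags_offs = [flag_atpf(v, l) for v, l in zip(offs, limits_offs)]
        flags_hb, new_outliers = reclassify_flags(
            hb, limits_hb, corrected, flags_hb
        )
        profiles.append(
            SubjectProfile(
                subject_id=str(subject_id),
                sex=sex,
                samples=grp.reset_index(drop=True),
                hb=hb,
                offs=offs,
                limits_hb=limits_hb,
                limits_offs=limits_offs,
                pv_estimates=pv,
                pv_z=grp["pv_z"].to_numpy(dtype=float),
                shifts=shifts,
                corrected_limits_hb=corrected,
                flags_hb=flags_hb,
                flags_offs=flags_offs,
                new_outliers=new_outliers,
            )
        )
    return profiles


def summarize_profiles(profiles: list[SubjectProfile]) -> dict:
    """Cohort counts: samples, ATPFs, PV-explained ATPFs, new outliers."""
    n_samples = sum(len(p.hb) for p in profiles)
    n_atpf = sum(p.flags_hb.count(Flag.ATPF) for p in profiles)
    n_explained = sum(
        p.flags_hb.count(Flag.ATPF_EXPLAINED_BY_PV) for p in profiles
    )
    n_offs_atpf = sum(p.flags_offs.count(Flag.ATPF) for p in profiles)
    n_new = int(sum(p.new_outliers.sum() for p in profiles))
    return {
        "n_subjects": len(profiles),
        "n_samples": n_samples,
        "n_hb_atpf": n_atpf,
        "n_hb_atpf_explained_by_pv": n_explained,
        "n_offs_atpf": n_offs_atpf,
        "n_new_outliers": n_new,
    }


@dataclass
class RunConfig:
    """Everything one end-to-end pipeline run needs."""

    input_path: Path
    output_dir: Path
    model_path: Optional[Path] = None
    regressor_kind: str = "tree_ensemble"
    weight_free: bool = False
    seed: int = 0
    specificity: float = 0.99
    weights: Optional[dict[Sex, float]] = None
    priors: Optional[dict] = None
    render: bool = True


def run_pipeline(config: RunConfig, model: Optional[PVModel] = None) -> dict:
    """Full run: read cohort, estimate PV, correct limits, write artifacts.

    Per subject: a correction CSV and (optionally) two figures — the
    corrected-limits view and the PV-overlay view.  Returns the cohort
    summary counts.  Partial outputs are removed on failure.
    """
    from . import plotting  # deferred: matplotlib import is slow
    from .io import read_samples

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        samples = read_samples(config.input_path)
        logger.info("loaded %d samples from %s", len(samples), config.input_path)
        if model is None:
            if config.model_path is None:
                raise ValueError("either a model or a model_path is required")
            model = PVModel.load(config.model_path)
        profiles = build_profiles(
            samples,
            model,
            priors=config.priors,
            specificity=config.specificity,
            weights=config.weights,
        )
        tables = []
        for p in profiles:
            table = p.correction_table()
            tables.append(table)
            csv_path = out_dir / f"{p.subject_id}_correction.csv"
            table.to_csv(csv_path, index=False)
            written.append(csv_path)
            if config.render:
                for view, fn in (
                    ("corrected", plotting.plot_corrected_limits),
                    ("pv_overlay", plotting.plot_pv_overlay),
                ):
                    fig_path = out_dir / f"{p.subject_id}_{view}.png"
                    fig = fn(p)
                    fig.savefig(fig_path, dpi=120)
                    plotting.close(fig)
                    written.append(fig_path)
        combined = pd.concat(tables, ignore_index=True)
        combined_path = out_dir / "corrections.csv"
        combined.to_csv(combined_path, index=False)
        written.append(combined_path)
        summary = summarize_profiles(profiles)
        logger.info(
            "profiles: %(n_subjects)d subjects, %(n_samples)d samples, "
            "%(n_hb_atpf)d [Hb] ATPFs, %(n_hb_atpf_explained_by_pv)d "
            "explained by PV, %(n_new_outliers)d new outliers",
            summary,
        )
        return summary
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
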