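"""Plasma-volume correction of individual hemoglobin reference limits.

The procedure converts successive PV estimates into a relative fluid
shift, scales it by a per-sex weighting index (the R² of the PV ↔ [Hb]
regression, i.e. the fraction of [Hb] variation attributable to PV), and
translates both [Hb] limits by ``−ΔPV_weighted × midpoint``.  The interval
is translated, never rescaled: its width is preserved exactly.  A PV
expansion (hemodilution, ΔPV > 0) therefore lowers both limits, tracking
the expected dilution of [Hb]; a contraction raises them.

Corrections are per-visit, relative to the immediately preceding visit,
and do not accumulate.  The first visit of a profile has no predecessor:
its shift is 0 and its corrected limits equal the originals.  OFF-score
limits are never corrected (the reticulocyte term is PV-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain import Flag, LimitPair, Sex
from .pvmodel import DEFAULT_WEIGHTS


@dataclass(frozen=True)
class PVShift:
    """Relative and weighted PV change between two successive visits."""

    delta_pv_relative: float
    delta_pv_weighted: float
    reference_visit: int


@dataclass(frozen=True)
class CorrectedLimitPair:
    """Translated [Hb] limits with the original interval width.

    The pair is defined by its lower bound, the original width and the
    signed shift; ``upper`` is derived as ``lower + width`` so that
    interval preservation is exact by construction rather than subject to
    floating-point rounding of two independently shifted bounds.
    """

    lower: float
    width: float
    shift_applied: float

    @property
    def upper(self) -> float:
        return self.lower + self.width

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def delta_pv_relative(pv_prev: float, pv_curr: float) -> float:
    """Relative PV difference between two successive visits."""
    if not pv_prev > 0:
        raise ValueError(f"previous PV must be > 0, got {pv_prev}")
    return (pv_curr - pv_prev) / pv_prev


def weight_shift(
    delta_rel: float,
    sex: Sex,
    weights: Optional[dict] = None,
) -> float:
    """Scale ΔPV_relative by the per-sex weighting index R².

    Defaults: 0.28 for men, 0.42 for women.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    sex = Sex.coerce(sex)
    try:
        w = float(weights[sex])
    except KeyError as exc:
        raise KeyError(f"no weighting index configured for sex {sex}") from exc
    if not 0 <= w <= 1:
        raise ValueError(f"weighting index must be in [0, 1], got {w}")
    return delta_rel * w


def correct_limits(original: LimitPair, delta_weighted: float) -> CorrectedLimitPair:
    """Translate limits by ``−ΔPV_weighted × (lower+upper)/2``.

    Both bounds move by the same signed shift; the original interval
    width is unchanged.
    """
    shift = -delta_weighted * original.midpoint
    return CorrectedLimitPair(
        lower=original.lower + shift,
        width=original.width,
        shift_applied=shift,
    )


def correction_series(
    pv_estimates: Sequence[float],
    limits: Sequence[LimitPair],
    sex: Sex,
    weights: Optional[dict] = None,
) -> tuple[list[PVShift], list[CorrectedLimitPair]]:
    """Per-visit shifts and corrected limits for one subject's series.

    Visit *i* (i ≥ 2) references visit *i−1*'s PV estimate; the first
    visit gets shift 0.
    """
    pv = list(pv_estimates)
    limits = list(limits)
    if len(pv) != len(limits):
        raise ValueError("pv_estimates and limits must have equal length")
    shifts: list[PVShift] = []
    corrected: list[CorrectedLimitPair] = []
    for i, pair in enumerate(limits):
        if i == 0:
            shifts.append(PVShift(0.0, 0.0, reference_visit=0))
            corrected.append(correct_limits(pair, 0.0))
            continue
        d_rel = delta_pv_relative(pv[i - 1], pv[i])
        d_w = weight_shift(d_rel, sex, weights)
        shifts.append(PVShift(d_rel, d_w, reference_visit=i))
        corrected.append(correct_limits(pair, d_w))
    return shifts, corrected


def reclassify_flags(
    values: Sequence[float],
    limits: Sequence[LimitPair],
    corrected: Sequence[CorrectedLimitPair],
    flags: Sequence[Flag],
) -> tuple[list[Flag], np.ndarray]:
    """Reclassify ATPFs explained by PV and report new-outlier diagnostics.

    A visit flagged against the original limits whose value lies within
    the corrected limits becomes ``atpf_explained_by_pv``.  A visit inside
    the original limits but outside the corrected ones keeps flag ``none``
    but is reported in the returned boolean diagnostic array (ideally all
    False: the translation should not manufacture outliers).

    The first visit has no predecessor, hence shift 0 and an unchanged
    flag by construction.
    """
    n = len(values)
    if not (len(limits) == len(corrected) == len(flags) == n):
        raise ValueError("per-visit series must have equal length")
    out_flags: list[Flag] = []
    new_outliers = np.zeros(n, dtype=bool)
    for i in range(n):
        v = float(values[i])
        flag = flags[i]
        inside_corrected = corrected[i].contains(v)
        if flag is Flag.ATPF and inside_corrected:
            out_flags.append(Flag.ATPF_EXPLAINED_BY_PV)
        else:
            out_flags.append(flag)
            if flag is Flag.NONE and not inside_corrected:
                new_outliers[i] = True
    return out_flags, new_outliers


def correction_table(
    visit_index: Sequence[int],
    values: Sequence[float],
    pv_estimates: Sequence[float],
    shifts: Sequence[PVShift],
    limits: Sequence[LimitPair],
    corrected: Sequence[CorrectedLimitPair],
    flags: Sequence[Flag],
    new_outliers: Sequence[bool],
) -> pd.DataFrame:
    """Per-visit correction table (full precision; round only at display)."""
    return pd.DataFrame(
        {
            "visit_index": list(visit_index),
            "hb": list(values),
            "pv_estimated": list(pv_estimates),
            "delta_pv_relative": [s.delta_pv_relative for s in shifts],
            "delta_pv_weighted": [s.delta_pv_weighted for s in shifts],
            "shift_applied": [c.shift_applied for c in corrected],
            "lower_original": [l.lower for l in limits],
            "upper_original": [l.upper for l in limits],
            "lower_corrected": [c.lower for c in corrected],
            "upper_corrected": [c.upper for c in corrected],
            "flag": [f.value for f in flags],
            "new_outlier": list(new_outliers),
        }
    )
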