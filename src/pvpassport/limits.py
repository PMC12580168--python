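"""Sequential individual reference limits for passport markers.

A two-level (between-subject / within-subject) normal model yields, for
each new sample, a predictive interval conditioned on the subject's own
history.  With history ``x_1..x_n`` and population prior
``N(mu_pop, sigma_between²)`` on the subject mean, the posterior mean of
the subject level is the precision-weighted blend

    m_n = (n·x̄/σ_w² + μ/σ_b²) / (n/σ_w² + 1/σ_b²)

and the next observation is predicted as ``N(m_n, σ_w² + var(m_n))``.
Limits narrow as evidence accumulates — the adaptive-threshold behaviour
individual passport monitoring relies on.  Limits for visit *i* are always
computed from history strictly before *i* (prequential), matching how each
new sample is tested against prior evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .domain import Flag, LimitPair, Sex


@dataclass(frozen=True)
class PopulationPrior:
    """Population-level prior for one marker and sex.

    ``sigma_between`` is the SD of true subject means around ``mu_pop``;
    ``sigma_within`` the within-subject SD (biological + analytical).
    """

    marker: str
    sex: Sex
    mu_pop: float
    sigma_between: float
    sigma_within: float

    def __post_init__(self) -> None:
        if not self.sigma_between > 0 or not self.sigma_within > 0:
            raise ValueError("prior SDs must be > 0")


# Order-of-magnitude hematology norms; configurable via config files.
DEFAULT_PRIORS: dict[tuple[str, Sex], PopulationPrior] = {
    ("hb", Sex.MALE): PopulationPrior("hb", Sex.MALE, 15.2, 0.9, 0.45),
    ("hb", Sex.FEMALE): PopulationPrior("hb", Sex.FEMALE, 13.4, 0.9, 0.45),
    ("offs", Sex.MALE): PopulationPrior("offs", Sex.MALE, 90.0, 12.0, 8.0),
    ("offs", Sex.FEMALE): PopulationPrior("offs", Sex.FEMALE, 80.0, 12.0, 8.0),
}


def sequential_limits(
    prior: PopulationPrior,
    history: Sequence[float],
    specificity: float = 0.99,
) -> LimitPair:
    """Predictive-interval limits for the next observation given history.

    With empty history this reduces to the population predictive interval
    ``mu_pop ± z·sqrt(sigma_within² + sigma_between²)``.
    """
    if not 0 < specificity < 1:
        raise ValueError(f"specificity must be in (0, 1), got {specificity}")
    history = np.asarray(list(history), dtype=float)
    n = history.size
    sw2 = prior.sigma_within**2
    sb2 = prior.sigma_between**2
    precision = n / sw2 + 1.0 / sb2
    if n:
        m = (n * history.mean() / sw2 + prior.mu_pop / sb2) / precision
    else:
        m = prior.mu_pop
    v = sw2 + 1.0 / precision
    z = stats.norm.ppf((1.0 + specificity) / 2.0)
    half = z * np.sqrt(v)
    return LimitPair(m - half, m + half, specificity)


def profile_limits(
    prior: PopulationPrior,
    values: Sequence[float],
    specificity: float = 0.99,
) -> list[LimitPair]:
    """Prequential limits: the pair for visit *i* uses values before *i*."""
    values = list(values)
    return [
        sequential_limits(prior, values[:i], specificity)
        for i in range(len(values))
    ]


def flag_atpf(value: float, limits: LimitPair) -> Flag:
    """Atypical finding iff the value falls strictly outside the limits.

    Boundary values are inside (closed interval).
    """
    if value < limits.lower or value > limits.upper:
        return Flag.ATPF
    return Flag.NONE
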