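"""Synthetic longitudinal CBC cohorts with ground-truth plasma volume.

The generator builds each subject from mass-conservation physiology:

* total hemoglobin mass ``Hbmass`` (g) and plasma volume ``PV`` (mL) are
  the independent state variables;
* red-cell volume is tied to Hbmass through a per-subject cellular
  hemoglobin concentration (``rcv = Hbmass / (MCHC_cell/100)``);
* blood volume is ``BV = PV + rcv`` and, pre-noise,
  ``[Hb] = 100 · Hbmass / BV`` (g·dL⁻¹ with volumes in mL, mass in g).

PV follows a subject-level AR(1) process around an anthropometric
baseline, so month-to-month fluid shifts dilute or concentrate every
concentration-based marker coherently, exactly the confounding the
passport correction addresses.  Stylized event templates (acute
hyperhydration, exercise hemoconcentration, altitude, blood transfusion,
rhEPO) perturb the state variables while maintaining conservation.
Analyzer noise is multiplicative Gaussian per marker.

The default cohort mirrors a monthly one-year monitoring design:
40 subjects (27 men, 13 women), 12 visits.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain import SAMPLE_COLUMNS, Sex

EVENT_KINDS = (
    "hyperhydration",
    "exercise_hemoconcentration",
    "altitude",
    "transfusion",
    "rhepo",
)

#: Events that act on plasma volume; their magnitude is capped so PV
#: excursions stay within the ~25% acute physiological range.
_PV_EVENT_KINDS = ("hyperhydration", "exercise_hemoconcentration", "altitude")
MAX_PV_EVENT_MAGNITUDE = 0.25

#: Typical hematology-analyzer imprecision (coefficient of variation).
DEFAULT_ANALYTIC_CV = {
    "hb": 0.01,
    "hct": 0.01,
    "mcv": 0.008,
    "rbc": 0.005,
    "ret_pct": 0.02,
}

# Per-sex baseline physiology.  Plasma volume comes from a linear
# allometric formula in height and weight; hemoglobin mass scales with
# body weight (endurance-trained norms).  Constants chosen so cohort
# [Hb] means land on 15.2 (men) / 13.4 (women) g·dL⁻¹.
_BASELINES = {
    Sex.MALE: {
        "pv_intercept": 3600.0,  # mL at reference anthropometrics
        "height_ref": 180.0,
        "weight_ref": 75.0,
        "height_mean": 180.0,
        "height_sd": 6.0,
        "weight_mean": 75.0,
        "weight_sd": 8.0,
        "hbmass_per_kg": 13.3,  # g per kg body weight
        "pv_resid_sd": 150.0,
        "hbmass_resid_sd": 35.0,
    },
    Sex.FEMALE: {
        "pv_intercept": 2800.0,
        "height_ref": 167.0,
        "weight_ref": 62.0,
        "height_mean": 167.0,
        "height_sd": 6.0,
        "weight_mean": 62.0,
        "weight_sd": 7.0,
        "hbmass_per_kg": 10.1,
        "pv_resid_sd": 130.0,
        "hbmass_resid_sd": 30.0,
    },
}
_PV_PER_CM = 25.0  # mL per cm of height
_PV_PER_KG = 15.0  # mL per kg of weight


@dataclass(frozen=True)
class Event:
    """One intervention applied to (a subset of) the cohort.

    ``magnitude`` is a fraction (0.10 = 10%); ``visit`` is 1-based;
    ``subjects`` lists 0-based subject indices, or None for everyone.
    """

    kind: str
    visit: int
    magnitude: float
    subjects: Optional[tuple[int, ...]] = None


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated cohort."""

    n_subjects: int = 40
    n_visits: int = 12  # monthly over one year
    female_fraction: float = 13 / 40
    seed: int = 0
    pv_ar1_rho: float = 0.3  # month-to-month PV autocorrelation
    pv_cv: float = 0.05  # stationary CV of PV fluctuations
    hbmass_cv: float = 0.01  # within-subject Hbmass variation
    analytic_cv: dict = field(
        default_factory=lambda: dict(DEFAULT_ANALYTIC_CV)
    )
    pv_measurement_cv: float = 0.02  # CO-rebreathing-like measurement error
    include_pv_measured: bool = True
    events: list[Event] = field(default_factory=list)
    # event dynamics
    altitude_duration: int = 3  # visits with reduced PV
    altitude_hbmass_ramp: float = 0.01  # per-visit Hbmass gain, caps at 3 visits
    transfusion_ret_suppression: float = 0.4  # RET% multiplier, 2 visits
    rhepo_ret_boost: float = 2.0  # RET% multiplier, 2 visits

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_visits < 1:
            raise ValueError("cohort must have >= 1 subject and visit")
        for ev in self.events:
            if ev.kind not in EVENT_KINDS:
                raise ValueError(
                    f"unknown event kind {ev.kind!r}; expected one of "
                    f"{EVENT_KINDS}"
                )
            if not 1 <= ev.visit <= self.n_visits:
                raise ValueError(
                    f"event visit {ev.visit} outside 1..{self.n_visits}"
                )
            if ev.magnitude < 0:
                raise ValueError("event magnitude must be >= 0")
            if (
                ev.kind in _PV_EVENT_KINDS
                and ev.magnitude > MAX_PV_EVENT_MAGNITUDE
            ):
                raise ValueError(
                    f"{ev.kind} magnitude {ev.magnitude} exceeds the "
                    f"{MAX_PV_EVENT_MAGNITUDE:.0%} acute PV bound"
                )


@dataclass
class GroundTruth:
    """Per-visit generative state for every subject.

    Red-cell volume is derived from Hbmass via the per-subject cellular
    hemoglobin concentration, so conservation (``BV = PV + rcv`` and
    ``[Hb] = 100·Hbmass/BV`` pre-noise) holds by construction.
    """

    subject_ids: list[str]
    sex: np.ndarray  # (n,) of "male"/"female"
    age: np.ndarray
    height: np.ndarray
    weight: np.ndarray
    pv: np.ndarray  # (n, m) mL
    hbmass: np.ndarray  # (n, m) g
    mchc_cell: np.ndarray  # (n,) g·dL⁻¹ of packed cells
    ret_mult: np.ndarray  # (n, m) multiplicative RET% modifier

    @property
    def rcv(self) -> np.ndarray:
        """Red-cell volume, mL."""
        return self.hbmass / (self.mchc_cell[:, None] / 100.0)

    @property
    def bv(self) -> np.ndarray:
        return self.pv + self.rcv

    @property
    def hb_prenoise(self) -> np.ndarray:
        return 100.0 * self.hbmass / self.bv

    @property
    def hct_prenoise(self) -> np.ndarray:
        return 100.0 * self.rcv / self.bv

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            subject_ids=list(self.subject_ids),
            sex=self.sex.copy(),
            age=self.age.copy(),
            height=self.height.copy(),
            weight=self.weight.copy(),
            pv=self.pv.copy(),
            hbmass=self.hbmass.copy(),
            mchc_cell=self.mchc_cell.copy(),
            ret_mult=self.ret_mult.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        n, m = self.pv.shape
        rcv = self.rcv
        rows = []
        for i in range(n):
            for j in range(m):
                rows.append(
                    {
                        "subject_id": self.subject_ids[i],
                        "visit_index": j + 1,
                        "pv_true": self.pv[i, j],
                        "hbmass_true": self.hbmass[i, j],
                        "rcv_true": rcv[i, j],
                    }
                )
        return pd.DataFrame(rows)


def inject_event(
    truth: GroundTruth,
    visit: int,
    kind: str,
    magnitude: float,
    subjects: Optional[Sequence[int]] = None,
    *,
    altitude_duration: int = 3,
    altitude_hbmass_ramp: float = 0.01,
    transfusion_ret_suppression: float = 0.4,
    rhepo_ret_boost: float = 2.0,
) -> GroundTruth:
    """Return a copy of ``truth`` with one event applied.

    Dynamics (1-based ``visit``; ``magnitude`` a fraction):

    * ``hyperhydration`` — PV scaled by (1 + m) at that visit only.
    * ``exercise_hemoconcentration`` — PV scaled by (1 − m) at that
      visit only (transient fluid loss).
    * ``altitude`` — PV scaled by (1 − m) for ``altitude_duration``
      visits; Hbmass ramps up slowly afterwards.
    * ``transfusion`` — Hbmass (and hence red-cell volume) scaled by
      (1 + m) from that visit on; PV unchanged; RET% suppressed for two
      visits (erythropoietic feedback).
    * ``rhepo`` — RET% boosted for two visits, then Hbmass ramps up to
      (1 + m) over three visits and persists.
    """
    n, m_visits = truth.pv.shape
    if not 1 <= visit <= m_visits:
        raise ValueError(f"event visit {visit} outside 1..{m_visits}")
    if kind not in EVENT_KINDS:
        raise ValueError(
            f"unknown event kind {kind!r}; expected one of {EVENT_KINDS}"
        )
    out = truth.copy()
    idx = np.arange(n) if subjects is None else np.asarray(list(subjects))
    j = visit - 1
    if kind == "hyperhydration":
        out.pv[idx, j] *= 1.0 + magnitude
    elif kind == "exercise_hemoconcentration":
        out.pv[idx, j] *= 1.0 - magnitude
    elif kind == "altitude":
        end = min(j + altitude_duration, m_visits)
        out.pv[np.ix_(idx, range(j, end))] *= 1.0 - magnitude
        for k in range(1, m_visits - j):
            gain = 1.0 + altitude_hbmass_ramp * min(k, 3)
            out.hbmass[idx, j + k] *= gain
    elif kind == "transfusion":
        out.hbmass[np.ix_(idx, range(j, m_visits))] *= 1.0 + magnitude
        end = min(j + 2, m_visits)
        out.ret_mult[np.ix_(idx, range(j, end))] *= transfusion_ret_suppression
    elif kind == "rhepo":
        end = min(j + 2, m_visits)
        out.ret_mult[np.ix_(idx, range(j, end))] *= rhepo_ret_boost
        for k in range(1, m_visits - j):
            out.hbmass[idx, j + k] *= 1.0 + magnitude * min(k / 3.0, 1.0)
    return out


def generate_cohort(config: ScenarioConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cohort; returns (sample table, ground truth).

    Deterministic: the same config (including seed) yields bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_visits

    n_female = int(round(config.female_fraction * n))
    sex = np.array(
        [Sex.MALE.value] * (n - n_female) + [Sex.FEMALE.value] * n_female
    )
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]

    age = rng.uniform(18.0, 38.0, size=n)
    height = np.empty(n)
    weight = np.empty(n)
    pv0 = np.empty(n)
    hbmass0 = np.empty(n)
    for s in (Sex.MALE, Sex.FEMALE):
        mask = sex == s.value
        k = int(mask.sum())
        b = _BASELINES[s]
        h = rng.normal(b["height_mean"], b["height_sd"], size=k)
        w = rng.normal(b["weight_mean"], b["weight_sd"], size=k)
        height[mask] = h
        weight[mask] = w
        pv0[mask] = (
            b["pv_intercept"]
            + _PV_PER_CM * (h - b["height_ref"])
            + _PV_PER_KG * (w - b["weight_ref"])
            + rng.normal(0.0, b["pv_resid_sd"], size=k)
        )
        hbmass0[mask] = b["hbmass_per_kg"] * w + rng.normal(
            0.0, b["hbmass_resid_sd"], size=k
        )
    mchc_cell = rng.normal(33.5, 0.8, size=n)

    # PV path: stationary log-AR(1) around the anthropometric baseline.
    sigma = config.pv_cv
    rho = config.pv_ar1_rho
    x = np.zeros((n, m))
    if sigma > 0:
        x[:, 0] = rng.normal(0.0, sigma, size=n)
        innov_sd = sigma * np.sqrt(max(1.0 - rho**2, 0.0))
        for j in range(1, m):
            x[:, j] = rho * x[:, j - 1] + rng.normal(0.0, innov_sd, size=n)
    else:
        # keep the rng stream length independent of sigma
        rng.normal(0.0, 1.0, size=n)
        for j in range(1, m):
            rng.normal(0.0, 1.0, size=n)
    pv = pv0[:, None] * np.exp(x - sigma**2 / 2.0)

    hbmass = hbmass0[:, None] * (
        1.0 + rng.normal(0.0, 1.0, size=(n, m)) * config.hbmass_cv
    )

    truth = GroundTruth(
        subject_ids=subject_ids,
        sex=sex,
        age=age,
        height=height,
        weight=weight,
        pv=pv,
        hbmass=hbmass,
        mchc_cell=mchc_cell,
        ret_mult=np.ones((n, m)),
    )
    for ev in config.events:
        truth = inject_event(
            truth,
            ev.visit,
            ev.kind,
            ev.magnitude,
            ev.subjects,
            altitude_duration=config.altitude_duration,
            altitude_hbmass_ramp=config.altitude_hbmass_ramp,
            transfusion_ret_suppression=config.transfusion_ret_suppression,
            rhepo_ret_boost=config.rhepo_ret_boost,
        )

    samples = _derive_samples(truth, config, rng)
    return samples, truth


def _noise(rng, shape, cv: float) -> np.ndarray:
    if cv <= 0:
        rng.normal(0.0, 1.0, size=shape)  # keep stream alignment
        return np.ones(shape)
    return 1.0 + rng.normal(0.0, 1.0, size=shape) * cv


def _derive_samples(
    truth: GroundTruth, config: ScenarioConfig, rng
) -> pd.DataFrame:
    n, m = truth.pv.shape
    cv = {**DEFAULT_ANALYTIC_CV, **config.analytic_cv}

    mcv_subj = rng.normal(88.0, 3.0, size=n)
    ret0 = np.exp(rng.normal(np.log(1.0), 0.35, size=n))
    ret_bio = np.exp(rng.normal(0.0, 0.15, size=(n, m)))

    hb = truth.hb_prenoise * _noise(rng, (n, m), cv["hb"])
    hct = truth.hct_prenoise * _noise(rng, (n, m), cv["hct"])
    mcv = mcv_subj[:, None] * _noise(rng, (n, m), cv["mcv"])
    ret = (
        ret0[:, None]
        * truth.ret_mult
        * ret_bio
        * _noise(rng, (n, m), cv["ret_pct"])
    )
    ret = np.clip(ret, 1e-3, 99.0)
    rbc = hct * 10.0 / mcv * _noise(rng, (n, m), cv["rbc"])
    mchc = hb / hct * 100.0

    if config.include_pv_measured:
        pv_meas = truth.pv * _noise(rng, (n, m), config.pv_measurement_cv)
    else:
        pv_meas = np.full((n, m), np.nan)

    rows = []
    for i in range(n):
        for j in range(m):
            rows.append(
                {
                    "subject_id": truth.subject_ids[i],
                    "sex": truth.sex[i],
                    "age": truth.age[i],
                    "height": truth.height[i],
                    "weight": truth.weight[i],
                    "visit_index": j + 1,
                    "hb": hb[i, j],
                    "hct": hct[i, j],
                    "rbc": rbc[i, j],
                    "ret_pct": ret[i, j],
                    "mcv": mcv[i, j],
                    "mchc": mchc[i, j],
                    "pv_measured": pv_meas[i, j],
                }
            )
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


# ---------------------------------------------------------------------------
# Cohort presets


def study_cohort_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """Clean monitoring cohort: 40 subjects, 12 monthly visits, no events."""
    return ScenarioConfig(seed=seed, **overrides)


def dilution_scenario_config(
    seed: int = 0,
    n_subjects: int = 200,
    event_visit: int = 9,
    magnitude: float = 0.15,
    **overrides,
) -> ScenarioConfig:
    """Acute hyperhydration (pure PV expansion) at one visit, all subjects."""
    return ScenarioConfig(
        n_subjects=n_subjects,
        seed=seed,
        events=[Event("hyperhydration", event_visit, magnitude)],
        **overrides,
    )


def transfusion_scenario_config(
    seed: int = 0,
    n_subjects: int = 200,
    event_visit: int = 9,
    magnitude: float = 0.10,
    **overrides,
) -> ScenarioConfig:
    """Blood transfusion (+Hbmass, PV unchanged) at one visit, all subjects."""
    return ScenarioConfig(
        n_subjects=n_subjects,
        seed=seed,
        events=[Event("transfusion", event_visit, magnitude)],
        **overrides,
    )


#: Mix of interventions used for the default training cohort, emulating a
#: heterogeneous reference population (controls plus fluid-shift and
#: erythropoietic scenarios).
TRAINING_MIX = (
    ("control", 0.40, 0.0),
    ("hyperhydration", 0.12, 0.12),
    ("exercise_hemoconcentration", 0.12, 0.10),
    ("altitude", 0.12, 0.08),
    ("transfusion", 0.12, 0.10),
    ("rhepo", 0.12, 0.06),
)


def training_cohort_config(
    seed: int = 0, n_subjects: int = 34, n_visits: int = 12
) -> ScenarioConfig:
    """Heterogeneous cohort for estimator training (~400 data points).

    Subjects are partitioned across the scenario mix; each non-control
    subject receives one event at a mid-study visit chosen pseudo-randomly
    from the seed.
    """
    schedule_rng = np.random.default_rng((seed * 9973 + 11) % (2**31))
    counts = [int(round(f * n_subjects)) for _, f, _ in TRAINING_MIX]
    while sum(counts) > n_subjects:
        counts[0] -= 1
    while sum(counts) < n_subjects:
        counts[0] += 1
    events: list[Event] = []
    i = 0
    for (kind, _, mag), c in zip(TRAINING_MIX, counts):
        for _ in range(c):
            if kind != "control":
                visit = int(schedule_rng.integers(4, n_visits + 1))
                events.append(Event(kind, visit, mag, subjects=(i,)))
            i += 1
    return ScenarioConfig(
        n_subjects=n_subjects,
        n_visits=n_visits,
        seed=seed,
        events=events,
    )
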