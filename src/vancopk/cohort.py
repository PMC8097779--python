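"""Synthetic infant cohorts for the vancomycin population-PK pipeline.

The study population this generator emulates is a hospital cohort of 94
infants (0-1 year, many of them neonates) on intravenous vancomycin for
septicemia, sampled sparsely through therapeutic drug monitoring: roughly
two concentrations per infant (205 in total), taken as steady-state troughs
(immediately pre-dose) and peaks (shortly after the end of an infusion).

Covariates are drawn to match the cohort's published summary structure:
weight median 4 kg (1.4-18), serum creatinine median 18.25 umol/L (5.5-50),
ages 1-345 days with a neonate/infant mix, height median 52 cm, and a strong
weight-age-height correlation induced by sampling weight around an
age-dependent growth curve and height from weight.  Concentrations are then
simulated from a specified population model (lognormal eta on clearance,
proportional residual error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import pk
from .data import DEFAULT_LLOQ, Event, PKDataset, SubjectRecord

__all__ = [
    "CohortDesign",
    "sample_covariates",
    "build_regimen",
    "simulate_observations",
    "make_cohort",
]


def _median_weight_curve(age_days: float) -> float:
    """Smooth infant growth curve used as the age-conditional weight median."""
    return 3.0 + 6.0 * (age_days / 345.0) ** 0.75


_AGE_REF = 88.5  # cohort median age, d


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic cohort: demographics, regimen and sampling.

    ``obs_mix`` gives the proportions of subjects contributing 1, 2 and 3
    samples; the default (6, 65, 23 out of 94) yields exactly 205 samples at
    n = 94.  ``spread`` scales every dispersion parameter: 0 collapses all
    continuous covariates onto the cohort medians.

    The default regimen (10 mg/kg infused over 1 h every 6 h, the routine
    infant schedule) reproduces the cohort's observed concentration
    distribution under the final model (median ~10.6 mg/L, range broadly
    within 3.31-51.93, almost nothing below the 2 mg/L assay limit).
    Troughs are drawn immediately before a dose at or after the 5th
    interval (approximate steady state); peaks 0.5 h after the end of an
    infusion.
    """

    n_subjects: int = 94
    obs_mix: tuple[float, float, float] = (6.0 / 94.0, 65.0 / 94.0, 23.0 / 94.0)
    seed: int = 0
    spread: float = 1.0
    # demographics
    neonate_fraction: float = 0.4  # age <= 28 d
    male_fraction: float = 58.0 / 94.0
    weight_median: float = 4.0  # kg at the median age
    weight_log_sd: float = 0.25
    weight_range: tuple[float, float] = (1.4, 18.0)
    height_log_sd: float = 0.04
    height_range: tuple[float, float] = (37.0, 78.0)
    scr_median: float = 18.25  # umol/L
    scr_log_sd: float = 0.35
    scr_range: tuple[float, float] = (5.5, 50.0)
    ga_mean: float = 37.18  # gestational age, weeks
    ga_sd: float = 3.71
    ga_range: tuple[float, float] = (25.7, 41.4)
    ceftriaxone_prevalence: float = 0.3
    other_cotherapy_prevalence: float = 0.1
    # dosing and sampling
    dose_per_kg: float = 10.0  # mg/kg per dose
    interval: float = 6.0  # h
    infusion_duration: float = 1.0  # h
    n_doses: int = 7
    steady_state_interval: int = 5  # first sampled interval
    peak_offset: float = 0.5  # h after end of infusion

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.interval <= 0 or self.dose_per_kg <= 0:
            raise ValueError("interval and dose_per_kg must be positive")


def _truncated_lognormal(rng, median: float, log_sd: float, lo: float, hi: float) -> float:
    if log_sd <= 0:
        return min(max(median, lo), hi)
    for _ in range(200):
        v = median * math.exp(log_sd * rng.standard_normal())
        if lo <= v <= hi:
            return v
    return min(max(median, lo), hi)


def _truncated_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd <= 0:
        return min(max(mean, lo), hi)
    for _ in range(200):
        v = mean + sd * rng.standard_normal()
        if lo <= v <= hi:
            return v
    return min(max(mean, lo), hi)


def sample_covariates(design: CohortDesign, rng: np.random.Generator | None = None) -> list[SubjectRecord]:
    """Draw ``n_subjects`` infant covariate records (deterministic given seed)."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    sp = design.spread
    subjects = []
    for i in range(design.n_subjects):
        if sp == 0:
            age = _AGE_REF
        elif rng.uniform() < design.neonate_fraction:
            age = rng.uniform(1.0, 28.0)
        else:
            age = rng.uniform(29.0, 345.0)
        w_med = design.weight_median * _median_weight_curve(age) / _median_weight_curve(_AGE_REF)
        weight = _truncated_lognormal(rng, w_med, design.weight_log_sd * sp, *design.weight_range)
        h_med = 52.0 * (weight / 4.0) ** 0.35
        height = _truncated_lognormal(rng, h_med, design.height_log_sd * sp, *design.height_range)
        scr = _truncated_lognormal(rng, design.scr_median, design.scr_log_sd * sp, *design.scr_range)
        ga = _truncated_normal(rng, design.ga_mean, design.ga_sd * sp, *design.ga_range)
        if sp == 0:
            sex, cef, other = "male", 0, {}
        else:
            sex = "male" if rng.uniform() < design.male_fraction else "female"
            cef = int(rng.uniform() < design.ceftriaxone_prevalence)
            other = {
                name: int(rng.uniform() < design.other_cotherapy_prevalence)
                for name in ("meropenem", "gentamicin", "furosemide", "ibuprofen", "dexamethasone")
            }
        subjects.append(
            SubjectRecord(
                subject_id=str(i + 1),
                weight=weight,
                scr=scr,
                age=age,
                height=height,
                gestational_age=ga,
                sex=sex,
                ceftriaxone=cef,
                alt=_truncated_lognormal(rng, 20.0, 0.6 * sp, 3.0, 156.0),
                ast=_truncated_lognormal(rng, 34.5, 0.5 * sp, 13.0, 241.0),
                bun=_truncated_lognormal(rng, 2.75, 0.45 * sp, 0.6, 9.5),
                total_protein=_truncated_normal(rng, 53.0, 8.0 * sp, 32.4, 78.0),
                albumin=_truncated_normal(rng, 35.0, 5.0 * sp, 18.45, 43.0),
                **other,
            )
        )
    return subjects


def build_regimen(
    subject: SubjectRecord,
    dose_per_kg: float,
    interval: float,
    infusion_duration: float,
    n_doses: int,
) -> list[Event]:
    """Weight-based multiple-dose regimen: doses at 0, tau, 2*tau, ...

    Amounts are dose_per_kg * weight, unrounded (simulation fidelity is
    preferred over clinical rounding).
    """
    if dose_per_kg <= 0 or interval <= 0 or infusion_duration <= 0:
        raise ValueError("dose_per_kg, interval and infusion_duration must be positive")
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    amount = dose_per_kg * subject.weight
    return [
        Event(subject.subject_id, m * interval, "dose", amount=amount, infusion_duration=infusion_duration)
        for m in range(n_doses)
    ]


def _obs_counts(design: CohortDesign, rng: np.random.Generator) -> np.ndarray:
    """Deterministically allocate 1/2/3-sample subjects, then shuffle."""
    n = design.n_subjects
    w = np.asarray(design.obs_mix, dtype=float)
    w = w / w.sum()
    counts = np.floor(w * n).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    rem = n - counts.sum()
    frac = w * n - np.floor(w * n)
    for idx in np.argsort(-frac)[:rem]:
        counts[idx] += 1
    alloc = np.repeat([1, 2, 3], counts)
    rng.shuffle(alloc)
    return alloc


def _schedule(design: CohortDesign, subject: SubjectRecord, n_obs: int, flip: bool) -> list[Event]:
    """Trough/peak sampling times for one subject at approximate steady state."""
    tau = design.interval
    m = design.steady_state_interval
    trough1 = m * tau  # the new infusion contributes nothing at its own start
    peak1 = m * tau + design.infusion_duration + design.peak_offset
    trough2 = (m + 1) * tau
    if n_obs == 1:
        picks = [(peak1, "peak")] if flip else [(trough1, "trough")]
    elif n_obs == 2:
        picks = [(trough1, "trough"), (peak1, "peak")]
    else:
        picks = [(trough1, "trough"), (peak1, "peak"), (trough2, "trough")]
    return [
        Event(subject.subject_id, t, "observation", observation_label=lab)
        for t, lab in picks
    ]


def simulate_observations(
    ds: PKDataset,
    pop: pk.PopulationParams,
    seed: int | np.random.Generator = 0,
    residual: str = "exponential",
) -> PKDataset:
    """Fill every observation event with a model-simulated concentration.

    Per subject, one eta ~ N(0, omega2_cl) multiplies clearance; the
    individual concentration at each scheduled time comes from the closed
    one-compartment solution; residual error is applied multiplicatively —
    ``exponential`` (default), y = f * exp(eps), which keeps concentrations
    strictly positive, or ``proportional``, y = f * (1 + eps), floored at a
    tiny positive value (``additive``/``combined`` add a N(0, sigma2_add)
    term).  Deterministic given the seed.  Raises if a sampling time
    precedes the subject's first dose.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out_events: list[Event] = []
    ds = ds.sorted()
    for sid, subject in ds.subjects.items():
        events = [e for e in ds.events if e.subject_id == sid]
        doses = [e for e in events if e.kind == "dose"]
        obs = [e for e in events if e.kind == "observation"]
        if obs and (not doses or min(o.time for o in obs) < min(d.time for d in doses)):
            raise ValueError(f"subject {sid}: sampling time precedes the first dose")
        typ = pk.typical_params(subject, pop)
        eta = math.sqrt(pop.omega2_cl) * rng.standard_normal() if pop.omega2_cl > 0 else 0.0
        ind = pk.individual_params(typ, eta)
        times = np.array([o.time for o in obs])
        f = pk.concentration(ind, doses, times) if len(times) else np.array([])
        if residual == "exponential":
            eps = math.sqrt(pop.sigma2_prop) * rng.standard_normal(len(times))
            y = f * np.exp(eps)
        elif residual == "proportional":
            eps = math.sqrt(pop.sigma2_prop) * rng.standard_normal(len(times))
            y = f * (1.0 + eps)
        elif residual == "additive":
            y = f + math.sqrt(pop.sigma2_add) * rng.standard_normal(len(times))
        elif residual == "combined":
            y = f * (1.0 + math.sqrt(pop.sigma2_prop) * rng.standard_normal(len(times)))
            y = y + math.sqrt(pop.sigma2_add) * rng.standard_normal(len(times))
        else:
            raise ValueError(f"unknown residual model {residual!r}")
        y = np.maximum(y, 1e-12)
        out_events.extend(doses)
        for o, conc in zip(obs, y):
            out_events.append(
                Event(sid, o.time, "observation", concentration=float(conc),
                      observation_label=o.observation_label,
                      below_loq=bool(conc <= DEFAULT_LLOQ))
            )
    return PKDataset(subjects=dict(ds.subjects), events=out_events).sorted()


def make_cohort(
    design: CohortDesign,
    pop: pk.PopulationParams = pk.FINAL_MODEL_PARAMS,
    residual: str = "exponential",
) -> PKDataset:
    """Full synthetic study: covariates, regimens, sampling, concentrations."""
    rng = np.random.default_rng(design.seed)
    subjects = sample_covariates(design, rng)
    counts = _obs_counts(design, rng)
    events: list[Event] = []
    for i, subject in enumerate(subjects):
        events.extend(
            build_regimen(subject, design.dose_per_kg, design.interval,
                          design.infusion_duration, design.n_doses)
        )
        events.extend(_schedule(design, subject, int(counts[i]), flip=bool(i % 2)))
    skeleton = PKDataset(subjects={s.subject_id: s for s in subjects}, events=events)
    return simulate_observations(skeleton, pop, rng, residual=residual)
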