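"""Synthetic EHR cohort generator with planted latent subtypes.

Real UK primary-care dementia extracts are access-restricted, so every
downstream stage of the pipeline is exercised on cohorts generated here. Each
patient is drawn from one of a small number of :class:`SubtypeProfile` latent
classes controlling comorbidity and symptom probabilities, demographics, and
five class-dependent clinical outcomes (MMSE decline, time to assisted living,
mortality, consultation rates, cholinesterase-inhibitor duration).

The generative model is a deliberate stand-in, not an attempt to model UK
coding practice: comorbidities are independent Bernoulli given class with
event dates uniform before diagnosis, post-diagnosis symptoms are Bernoulli
per grouped category, survival times are exponential, consultation counts are
Poisson, and MMSE trajectories are linear with Gaussian noise. See
docs/methods.md for what this does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import COMORBIDITY_PREFIX, DIAGNOSIS_CODE, SYMPTOM_PREFIX

DEFAULT_STUDY_WINDOW = ("1997-01-01", "2016-06-01")

#: Representative raw symptom codes emitted per grouped category. The
#: neuropsychological representatives deliberately avoid depression/anxiety so
#: planted category prevalences are not distorted by the explained-symptom
#: attribution rule; that rule is exercised via explicit contamination instead.
CATEGORY_SYMPTOM_CODES: dict[str, tuple[str, ...]] = {
    "memory": ("memory",),
    "confusion": ("confusion",),
    "neuropsychological": ("apathy", "hallucinations", "agitation", "mood disorders"),
    "motor": ("difficulty walking", "orientation"),
}

SMOKING_CATS = ("non-smoker", "ex-smoker", "current smoker", "missing")
DRINKING_CATS = (
    "non-drinker", "ex-drinker", "occasional drinker", "current drinker", "missing",
)


@dataclass(frozen=True)
class SubtypeProfile:
    """Generative parameters of one latent disease subtype."""

    class_id: int
    name: str
    mixing_weight: float
    comorbidity_probs: dict[str, float]
    symptom_probs: dict[str, float]
    age_distribution: tuple[float, ...]  # over the five age bands
    gender_prob_female: float
    smoking_probs: dict[str, float]
    drinking_probs: dict[str, float]
    mmse_decline_mean: float  # points/year
    mmse_decline_sd: float
    assisted_living_hazard: float  # events/year
    mortality_hazard: float
    consultation_rate: float  # visits/year
    chei_duration_mean: float  # years

    def validate(self) -> None:
        probs = (
            list(self.comorbidity_probs.values())
            + list(self.symptom_probs.values())
            + [self.gender_prob_female]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError(f"profile {self.name}: probability outside [0,1]")
        for dist, name in (
            (self.age_distribution, "age_distribution"),
            (tuple(self.smoking_probs.values()), "smoking_probs"),
            (tuple(self.drinking_probs.values()), "drinking_probs"),
        ):
            if any(p < 0 for p in dist) or abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"profile {self.name}: {name} is not a distribution")
        if min(self.assisted_living_hazard, self.mortality_hazard,
               self.consultation_rate, self.chei_duration_mean) <= 0:
            raise ValueError(f"profile {self.name}: rates must be positive")
        if self.mmse_decline_sd < 0:
            raise ValueError(f"profile {self.name}: mmse_decline_sd must be >= 0")


def validate_profiles(profiles: list[SubtypeProfile]) -> None:
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles:
        p.validate()
    total = sum(p.mixing_weight for p in profiles)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixing weights sum to {total}, expected 1")


def _profile(class_id, name, weight, comorb, sympt, ages, female, smoking,
             drinking, decline, decline_sd, al, mort, consult, chei,
             comorbidity_base=0.08):
    """Helper: comorbidities default to a low base rate unless overridden."""
    from .features import COMORBIDITIES

    cp = {c: comorbidity_base for c in COMORBIDITIES}
    cp.update(comorb)
    return SubtypeProfile(
        class_id=class_id, name=name, mixing_weight=weight,
        comorbidity_probs=cp, symptom_probs=sympt,
        age_distribution=ages, gender_prob_female=female,
        smoking_probs=dict(zip(SMOKING_CATS, smoking)),
        drinking_probs=dict(zip(DRINKING_CATS, drinking)),
        mmse_decline_mean=decline, mmse_decline_sd=decline_sd,
        assisted_living_hazard=al, mortality_hazard=mort,
        consultation_rate=consult, chei_duration_mean=chei,
    )


def default_profiles() -> list[SubtypeProfile]:
    """Five planted subtypes mirroring the cluster archetypes reported for
    UK primary-care Alzheimer's cohorts.

    Each class carries at least one signature feature with a between-class
    probability gap of at least 0.6, and the anxiety/depression/early-onset
    class declines roughly three times faster than the others.
    """
    base = 0.05
    return [
        _profile(
            0, "anxiety depression early onset", 0.18,
            comorb={"depression": 0.90, "anxiety": 0.85},
            sympt={"memory": 0.60, "confusion": 0.20,
                   "neuropsychological": 0.90, "motor": 0.05},
            ages=(0.45, 0.28, 0.12, 0.09, 0.06), female=0.75,
            smoking=(0.15, 0.10, 0.70, 0.05),
            drinking=(0.12, 0.05, 0.20, 0.33, 0.30),
            decline=3.0, decline_sd=0.5, al=0.25, mort=0.16, consult=8.0, chei=1.5,
            comorbidity_base=base,
        ),
        _profile(
            1, "typical AD hypertension", 0.25,
            comorb={"hypertension": 0.90, "kidney disease": 0.55},
            sympt={"memory": 0.92, "confusion": 0.10,
                   "neuropsychological": 0.10, "motor": 0.03},
            ages=(0.08, 0.20, 0.25, 0.26, 0.21), female=0.66,
            smoking=(0.75, 0.15, 0.05, 0.05),
            drinking=(0.30, 0.08, 0.15, 0.02, 0.45),
            decline=1.0, decline_sd=0.5, al=0.10, mort=0.12, consult=4.0, chei=3.0,
            comorbidity_base=base,
        ),
        _profile(
            2, "typical AD cancer", 0.20,
            comorb={"cancer": 0.90, "hearing loss": 0.60},
            sympt={"memory": 0.92, "confusion": 0.10,
                   "neuropsychological": 0.12, "motor": 0.03},
            ages=(0.08, 0.16, 0.22, 0.26, 0.28), female=0.28,
            smoking=(0.50, 0.40, 0.05, 0.05),
            drinking=(0.22, 0.12, 0.21, 0.02, 0.43),
            decline=1.0, decline_sd=0.5, al=0.11, mort=0.15, consult=4.5, chei=2.8,
            comorbidity_base=base,
        ),
        _profile(
            3, "non-typical AD", 0.20,
            comorb={},
            sympt={"memory": 0.10, "confusion": 0.88,
                   "neuropsychological": 0.88, "motor": 0.70},
            ages=(0.15, 0.20, 0.22, 0.23, 0.20), female=0.66,
            smoking=(0.60, 0.30, 0.05, 0.05),
            drinking=(0.30, 0.07, 0.16, 0.02, 0.45),
            decline=1.5, decline_sd=0.5, al=0.18, mort=0.14, consult=6.0, chei=2.2,
            comorbidity_base=base,
        ),
        _profile(
            4, "CVD", 0.17,
            comorb={"atrial fibrillation": 0.88, "heart failure": 0.80,
                    "atherosclerosis": 0.75, "haemorrhagic stroke": 0.40,
                    "diabetes": 0.55, "hyperglycaemia": 0.45},
            sympt={"memory": 0.55, "confusion": 0.25,
                   "neuropsychological": 0.25, "motor": 0.10},
            ages=(0.06, 0.14, 0.22, 0.28, 0.30), female=0.55,
            smoking=(0.40, 0.50, 0.05, 0.05),
            drinking=(0.35, 0.12, 0.10, 0.02, 0.41),
            decline=1.2, decline_sd=0.5, al=0.16, mort=0.25, consult=7.0, chei=2.5,
            comorbidity_base=base,
        ),
    ]


@dataclass
class SyntheticCohort:
    """Raw EHR-like tables plus ground truth for a generated cohort."""

    events: pd.DataFrame        # patient_id, code, date
    demographics: pd.DataFrame  # patient_id, birth_year, gender, practice_id,
                                # smoking, drinking, obs_start, obs_end
    true_labels: pd.Series      # patient_id -> class_id
    diagnosis_dates: pd.Series
    followup_years: pd.Series   # observation end minus diagnosis, in years
    profiles: list[SubtypeProfile] = field(repr=False, default_factory=list)

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(d / "events.csv", index=False)
        self.demographics.to_csv(d / "demographics.csv", index=False)
        truth = pd.DataFrame({
            "patient_id": self.true_labels.index,
            "class_id": self.true_labels.values,
        })
        truth.to_csv(d / "truth.csv", index=False)


# --------------------------------------------------------------------------- #
# Cohort generation
# --------------------------------------------------------------------------- #

def generate_cohort(
    profiles: list[SubtypeProfile] | None = None,
    n_patients: int = 2000,
    n_practices: int = 40,
    seed: int = 0,
    study_window: tuple = DEFAULT_STUDY_WINDOW,
    contamination_fraction: float = 0.05,
    missing_demographics_fraction: float = 0.01,
) -> SyntheticCohort:
    """Generate events.csv / demographics.csv-shaped tables with planted classes.

    Comorbidity events are dated before the diagnosis, symptom events after,
    so the temporal attribution rules operate as on real data. A small
    ``contamination_fraction`` of patients additionally receive a
    post-diagnosis depression *symptom* together with a pre-diagnosis
    depression *comorbidity*, exercising the explained-symptom rule. A small
    fraction of patients have missing birth year or gender to exercise cohort
    exclusion.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if n_practices < 2:
        raise ValueError("n_practices must be >= 2")
    profiles = default_profiles() if profiles is None else profiles
    validate_profiles(profiles)

    rng = np.random.default_rng(seed)
    window_start = pd.Timestamp(study_window[0])
    window_end = pd.Timestamp(study_window[1])
    span_days = (window_end - window_start).days

    weights = np.array([p.mixing_weight for p in profiles])
    class_idx = rng.choice(len(profiles), size=n_patients, p=weights)
    patient_ids = np.array([f"P{i:06d}" for i in range(n_patients)])
    practice_ids = rng.integers(0, n_practices, size=n_patients)

    band_ages = [(42, 73), (74, 78), (79, 82), (83, 87), (88, 95)]

    demo_rows = []
    ev_pid: list[str] = []
    ev_code: list[str] = []
    ev_date: list[pd.Timestamp] = []
    dx_dates = {}
    followups = {}

    contaminate = rng.random(n_patients) < contamination_fraction
    drop_birth = rng.random(n_patients) < missing_demographics_fraction / 2
    drop_gender = rng.random(n_patients) < missing_demographics_fraction / 2

    for i, pid in enumerate(patient_ids):
        prof = profiles[class_idx[i]]

        # diagnosis date with >= ~1.5y margin inside the study window
        margin = int(1.5 * 365.25)
        dx_day = rng.integers(margin, span_days - margin)
        dx = window_start + pd.Timedelta(days=int(dx_day))
        dx_dates[pid] = dx

        pre_years = 1.0 + rng.exponential(3.0)
        post_years = 1.0 + min(rng.exponential(4.0), 12.0)
        obs_start = max(window_start, dx - pd.Timedelta(days=int(pre_years * 365.25)))
        obs_end = min(window_end, dx + pd.Timedelta(days=int(post_years * 365.25)))
        followups[pid] = (obs_end - dx).days / 365.25

        band = rng.choice(5, p=np.asarray(prof.age_distribution))
        lo, hi = band_ages[band]
        age = rng.integers(lo, hi + 1)
        birth_year = dx.year - int(age)

        gender = "female" if rng.random() < prof.gender_prob_female else "male"
        smoking = rng.choice(SMOKING_CATS, p=[prof.smoking_probs[c] for c in SMOKING_CATS])
        drinking = rng.choice(DRINKING_CATS, p=[prof.drinking_probs[c] for c in DRINKING_CATS])
        demo_rows.append({
            "patient_id": pid,
            "birth_year": "" if drop_birth[i] else birth_year,
            "gender": "" if drop_gender[i] else gender,
            "practice_id": int(practice_ids[i]),
            "smoking": "" if smoking == "missing" else smoking,
            "drinking": "" if drinking == "missing" else drinking,
            "obs_start": obs_start.date().isoformat(),
            "obs_end": obs_end.date().isoformat(),
        })

        ev_pid.append(pid); ev_code.append(DIAGNOSIS_CODE); ev_date.append(dx)

        pre_span = max((dx - obs_start).days - 1, 1)
        post_span = max((obs_end - dx).days - 1, 1)
        for comorb, p in prof.comorbidity_probs.items():
            if rng.random() < p:
                offset = 1 + int(rng.random() * pre_span)
                ev_pid.append(pid)
                ev_code.append(COMORBIDITY_PREFIX + comorb)
                ev_date.append(dx - pd.Timedelta(days=offset))
        for category, p in prof.symptom_probs.items():
            if rng.random() < p:
                codes = CATEGORY_SYMPTOM_CODES[category]
                name = codes[rng.integers(len(codes))]
                offset = 1 + int(rng.random() * post_span)
                ev_pid.append(pid)
                ev_code.append(SYMPTOM_PREFIX + name)
                ev_date.append(dx + pd.Timedelta(days=offset))
        if contaminate[i]:
            # symptom that the attribution rule must reject
            ev_pid.append(pid)
            ev_code.append(SYMPTOM_PREFIX + "depression")
            ev_date.append(dx + pd.Timedelta(days=1 + int(rng.random() * post_span)))
            ev_pid.append(pid)
            ev_code.append(COMORBIDITY_PREFIX + "depression")
            ev_date.append(dx - pd.Timedelta(days=1 + int(rng.random() * pre_span)))

    events = pd.DataFrame({
        "patient_id": ev_pid,
        "code": ev_code,
        "date": [d.date().isoformat() for d in ev_date],
    })
    demographics = pd.DataFrame(demo_rows)
    true_labels = pd.Series(class_idx, index=patient_ids, name="class_id")
    return SyntheticCohort(
        events=events,
        demographics=demographics,
        true_labels=true_labels,
        diagnosis_dates=pd.Series(dx_dates, name="diagnosis_date"),
        followup_years=pd.Series(followups, name="followup_years"),
        profiles=list(profiles),
    )


# --------------------------------------------------------------------------- #
# Outcome generation
# --------------------------------------------------------------------------- #

@dataclass
class OutcomeTable:
    """Per-patient outcome measurements plus the raw MMSE visit series."""

    table: pd.DataFrame        # indexed by patient_id
    mmse_series: pd.DataFrame  # patient_id, years_from_diagnosis, score

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(d / "outcomes.csv")
        self.mmse_series.to_csv(d / "mmse_series.csv", index=False)


def generate_outcomes(
    cohort: SyntheticCohort,
    profiles: list[SubtypeProfile] | None = None,
    followup_years: float = 8.0,
    seed: int = 0,
    mmse_noise_sd: float = 1.0,
    mmse_baseline: tuple[float, float] = (26.0, 2.0),
    missed_fraction: float = 0.10,
    chei_sd: float = 0.5,
) -> OutcomeTable:
    """Draw the five class-dependent outcomes for every generated patient.

    Per patient: MMSE scores at one pre-diagnosis visit then annual visits,
    declining linearly at a class-specific rate with Gaussian noise;
    exponential times to assisted living and death right-censored at the end
    of follow-up (assisted living additionally censored by death);
    Poisson consultation and missed-appointment counts; and a Normal
    cholinesterase-inhibitor treatment duration truncated at censoring.
    """
    if followup_years <= 0:
        raise ValueError("followup_years must be > 0")
    profiles = cohort.profiles if profiles is None else profiles
    if not profiles:
        raise ValueError("profiles required")
    by_id = {p.class_id: p for p in profiles}

    rng = np.random.default_rng(seed)
    rows = []
    mmse_pid: list[str] = []
    mmse_t: list[float] = []
    mmse_score: list[float] = []

    for pid, class_id in cohort.true_labels.items():
        prof = by_id[int(class_id)]
        censor = float(min(followup_years, cohort.followup_years[pid]))

        rate = max(rng.normal(prof.mmse_decline_mean, prof.mmse_decline_sd), 0.0)
        baseline = rng.normal(*mmse_baseline)
        visits = [-0.2] + [float(t) for t in np.arange(1.0, censor + 1e-9)]
        if len(visits) < 2:  # very short follow-up: one post-diagnosis visit
            visits.append(censor)
        for t in visits:
            mmse_pid.append(pid)
            mmse_t.append(t)
            mmse_score.append(baseline - rate * t + rng.normal(0.0, mmse_noise_sd))

        death_raw = rng.exponential(1.0 / prof.mortality_hazard)
        death_event = death_raw <= censor
        death_time = min(death_raw, censor)

        al_raw = rng.exponential(1.0 / prof.assisted_living_hazard)
        al_censor = min(death_time, censor)
        al_event = al_raw <= al_censor
        al_time = min(al_raw, al_censor)

        exposure = max(death_time, 1e-6)
        consults = rng.poisson(prof.consultation_rate * exposure)
        missed = rng.poisson(missed_fraction * prof.consultation_rate * exposure)

        chei = float(np.clip(rng.normal(prof.chei_duration_mean, chei_sd), 0.0, censor))

        rows.append({
            "patient_id": pid,
            "class_id": int(class_id),
            "true_decline_rate": rate,
            "time_to_death": death_time,
            "death_event": bool(death_event),
            "time_to_assisted_living": al_time,
            "assisted_living_event": bool(al_event),
            "consultations_per_year": consults / exposure,
            "missed_per_year": missed / exposure,
            "chei_duration": chei,
            "followup_years": censor,
        })

    table = pd.DataFrame(rows).set_index("patient_id")
    mmse = pd.DataFrame({
        "patient_id": mmse_pid,
        "years_from_diagnosis": mmse_t,
        "score": mmse_score,
    })
    return OutcomeTable(table=table, mmse_series=mmse)
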