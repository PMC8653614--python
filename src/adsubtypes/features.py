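"""Cohort selection and clinical feature construction.

Builds the patients x features binary matrix used for clustering from
longitudinal event tables (patient_id, code, date) and a demographics table.
Three feature roles are distinguished:

* ``symptom``      -- four grouped symptom categories (memory, confusion,
                      neuropsychological, motor), flagged only when the symptom
                      is recorded after the dementia diagnosis and cannot be
                      explained by a pre-existing comorbidity.
* ``comorbidity``  -- thirteen diagnoses recorded strictly before diagnosis.
* ``demographic``  -- age band at diagnosis (quintile edges), gender, smoking
                      and drinking status, one-hot encoded with explicit
                      missing-value conventions (no smoking record means
                      non-smoker; no drinking record means "not specified").

With the default dictionary this yields exactly 21 parent variables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------- #
# Default clinical dictionaries
# --------------------------------------------------------------------------- #

#: Symptoms of Alzheimer's disease from the literature (raw, pre-grouping).
SYMPTOMS: tuple[str, ...] = (
    "agitation", "anxiety", "apathy", "confusion", "delirium", "delusion",
    "depression", "difficulty walking", "eating", "fainting", "falls",
    "hallucinations", "incontinence", "language", "memory", "mood disorders",
    "orientation", "paranoia", "seizure", "sleep",
)

#: Raw symptoms folded into the "neuropsychological" category. "aggression" is
#: accepted as a synonym-level code even though it is not in SYMPTOMS.
NEUROPSYCH_SYMPTOMS: frozenset[str] = frozenset({
    "aggression", "agitation", "anxiety", "apathy", "delirium", "delusion",
    "depression", "hallucinations", "sleep", "eating", "paranoia",
    "mood disorders",
})

#: Raw symptoms folded into the "motor" category.
MOTOR_SYMPTOMS: frozenset[str] = frozenset({"difficulty walking", "orientation"})

#: Raw symptoms that belong to no grouped category (too low prevalence and no
#: natural grouping); they count towards cohort inclusion but not the matrix.
UNGROUPED_SYMPTOMS: frozenset[str] = frozenset({
    "fainting", "falls", "incontinence", "language", "seizure",
})

SYMPTOM_CATEGORIES: tuple[str, ...] = (
    "memory", "confusion", "neuropsychological", "motor",
)

#: Comorbidities retained in the default dictionary. Hypercholesterolemia is
#: deliberately excluded (prevalence too low to be informative).
COMORBIDITIES: tuple[str, ...] = (
    "anxiety", "atherosclerosis", "atrial fibrillation", "cancer",
    "depression", "diabetes", "haemorrhagic stroke", "hearing loss",
    "heart failure", "hyperglycaemia", "hypertension", "kidney disease",
    "rheumatoid arthritis",
)

#: Symptom -> set of comorbidities that "explain" it: a symptom record is not
#: attributed to the dementia when the same condition was already diagnosed.
DEFAULT_EXPLANATION_MAP: dict[str, frozenset[str]] = {
    "depression": frozenset({"depression"}),
    "anxiety": frozenset({"anxiety"}),
}

#: Age-at-diagnosis quintile edges (inclusive band bounds; last band open).
AGE_BAND_EDGES: tuple[int, ...] = (74, 79, 83, 88)
AGE_BAND_LABELS: tuple[str, ...] = ("42-73", "74-78", "79-82", "83-87", "88+")

GENDER_LEVELS: tuple[str, ...] = ("female", "male")
SMOKING_LEVELS: tuple[str, ...] = ("non-smoker", "ex-smoker", "current smoker")
DRINKING_LEVELS: tuple[str, ...] = (
    "non-drinker", "ex-drinker", "occasional drinker", "current drinker",
    "drinking status not specified",
)

SMOKING_MISSING_LEVEL = "non-smoker"
DRINKING_MISSING_LEVEL = "drinking status not specified"

DIAGNOSIS_CODE = "dx:AD"
SYMPTOM_PREFIX = "sx:"
COMORBIDITY_PREFIX = "cm:"

ONE_YEAR_DAYS = 365.25


def default_symptom_map() -> dict[str, str]:
    """Map event codes to raw symptom names (``sx:memory`` -> ``memory``)."""
    names = set(SYMPTOMS) | {"aggression"}
    return {SYMPTOM_PREFIX + s: s for s in sorted(names)}


def default_comorbidity_map() -> dict[str, str]:
    return {COMORBIDITY_PREFIX + c: c for c in COMORBIDITIES}


def symptom_category_map(include_confusion_in_neuropsych: bool = False) -> dict[str, str | None]:
    """Raw symptom name -> grouped category (None when ungrouped).

    "confusion" is both its own category and, optionally, part of the
    neuropsychological group; the default keeps it as its own category only.
    Callers needing the dual mapping should treat the returned value for
    "confusion" together with the flag.
    """
    mapping: dict[str, str | None] = {}
    for s in set(SYMPTOMS) | {"aggression"}:
        if s == "memory":
            mapping[s] = "memory"
        elif s == "confusion":
            mapping[s] = "confusion"
        elif s in NEUROPSYCH_SYMPTOMS:
            mapping[s] = "neuropsychological"
        elif s in MOTOR_SYMPTOMS:
            mapping[s] = "motor"
        else:
            mapping[s] = None
    return mapping


# --------------------------------------------------------------------------- #
# Containers
# --------------------------------------------------------------------------- #

@dataclass
class FeatureMatrix:
    """Patients x one-hot clinical features with per-column metadata.

    Attributes
    ----------
    values : DataFrame
        Binary (0/1) matrix indexed by patient id.
    meta : DataFrame
        Indexed by column name with columns ``parent`` (parent variable) and
        ``role`` (symptom | comorbidity | demographic).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def parents(self) -> list[str]:
        seen: list[str] = []
        for p in self.meta["parent"]:
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    def columns_for(self, parent: str) -> list[str]:
        return list(self.meta.index[self.meta["parent"] == parent])

    def validate(self) -> None:
        vals = self.values.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("metadata does not match matrix columns")
        for parent in self.parents:
            cols = self.columns_for(parent)
            if len(cols) > 1:  # one-hot group must select exactly one level
                sums = self.values[cols].sum(axis=1)
                if not (sums == 1).all():
                    raise ValueError(f"one-hot group {parent!r} rows do not sum to 1")

    def parent_codes(self) -> pd.DataFrame:
        """Collapse one-hot groups back to one integer code column per parent."""
        out = {}
        for parent in self.parents:
            cols = self.columns_for(parent)
            if len(cols) == 1:
                out[parent] = self.values[cols[0]].to_numpy()
            else:
                out[parent] = self.values[cols].to_numpy().argmax(axis=1)
        return pd.DataFrame(out, index=self.values.index)

    def indicator(self, complete: bool = True) -> pd.DataFrame:
        """Indicator matrix for correspondence analysis.

        With ``complete=True`` every single-column binary parent is expanded to
        a presence/absence column pair so each parent contributes exactly one
        count per patient (complete disjunctive coding).
        """
        if not complete:
            return self.values.copy()
        blocks = []
        for parent in self.parents:
            cols = self.columns_for(parent)
            block = self.values[cols]
            if len(cols) == 1:
                absent = (1 - block[cols[0]]).rename(f"{cols[0]}::absent")
                block = pd.concat([block, absent], axis=1)
            blocks.append(block)
        return pd.concat(blocks, axis=1)

    def to_csv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path)
        self.meta.to_csv(meta_path)

    @classmethod
    def from_csv(cls, values_path, meta_path) -> "FeatureMatrix":
        values = pd.read_csv(values_path, index_col=0)
        meta = pd.read_csv(meta_path, index_col=0)
        return cls(values=values, meta=meta)


@dataclass
class CohortSelection:
    """Cohort table plus an audit of exclusion counts at every filter."""

    table: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)


# --------------------------------------------------------------------------- #
# Cohort selection
# --------------------------------------------------------------------------- #

def select_cohort(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    study_window: tuple = ("1997-01-01", "2016-06-01"),
    diagnosis_code: str = DIAGNOSIS_CODE,
    min_diagnosis_age: int = 40,
) -> CohortSelection:
    """Apply the eligibility rules and compute per-patient observation windows.

    Rules: a dementia diagnosis event; diagnosis after ``min_diagnosis_age``;
    at least one year of follow-up both before and after diagnosis; at least
    one recorded symptom or comorbidity; non-missing birth year and gender.
    Rows with unparseable dates are dropped (counted, logged). An empty input
    yields an empty cohort.
    """
    excl: dict[str, int] = {}
    window_start = pd.Timestamp(study_window[0])
    window_end = pd.Timestamp(study_window[1])

    events = events.copy()
    n0 = len(events)
    events["date"] = pd.to_datetime(events["date"], errors="coerce")
    bad = events["date"].isna()
    excl["malformed_event_dates"] = int(bad.sum())
    if excl["malformed_event_dates"]:
        logger.warning("dropped %d event rows with malformed dates", excl["malformed_event_dates"])
    events = events[~bad]

    demo = demographics.copy()
    demo["birth_year"] = pd.to_numeric(demo.get("birth_year"), errors="coerce")
    gender = demo.get("gender")
    if gender is None:
        demo["gender"] = np.nan
    demo["gender"] = demo["gender"].replace("", np.nan)
    missing_demo = demo["birth_year"].isna() | demo["gender"].isna()
    excl["missing_birth_year_or_gender"] = int(missing_demo.sum())
    demo = demo[~missing_demo].set_index("patient_id")

    dx = (
        events[events["code"] == diagnosis_code]
        .groupby("patient_id")["date"].min()
        .rename("diagnosis_date")
    )
    candidates = demo.join(dx, how="inner")
    excl["no_diagnosis_event"] = int(len(demo) - len(candidates))

    if candidates.empty:
        cols = ["diagnosis_date", "birth_year", "gender", "practice_id",
                "observation_start", "observation_end", "age_at_diagnosis"]
        return CohortSelection(pd.DataFrame(columns=cols), excl)

    # observation window: latest of (patient obs start, window start) to
    # earliest of (patient obs end, window end)
    obs_start = pd.to_datetime(candidates.get("obs_start"), errors="coerce")
    obs_end = pd.to_datetime(candidates.get("obs_end"), errors="coerce")
    candidates["observation_start"] = obs_start.fillna(window_start).clip(lower=window_start)
    candidates["observation_end"] = obs_end.fillna(window_end).clip(upper=window_end)

    age = candidates["diagnosis_date"].dt.year - candidates["birth_year"]
    candidates["age_at_diagnosis"] = age
    too_young = age < min_diagnosis_age
    excl["diagnosis_before_min_age"] = int(too_young.sum())
    candidates = candidates[~too_young]

    pre = (candidates["diagnosis_date"] - candidates["observation_start"]).dt.days
    post = (candidates["observation_end"] - candidates["diagnosis_date"]).dt.days
    short = (pre < ONE_YEAR_DAYS) | (post < ONE_YEAR_DAYS)
    excl["under_one_year_followup"] = int(short.sum())
    candidates = candidates[~short]

    clinical = events["code"].str.startswith((SYMPTOM_PREFIX, COMORBIDITY_PREFIX))
    has_clinical = set(events.loc[clinical, "patient_id"])
    empty_record = ~candidates.index.isin(has_clinical)
    excl["no_symptom_or_comorbidity"] = int(empty_record.sum())
    candidates = candidates[~empty_record]

    keep = ["diagnosis_date", "birth_year", "gender", "practice_id",
            "observation_start", "observation_end", "age_at_diagnosis"]
    table = candidates[[c for c in keep if c in candidates.columns]].copy()
    logger.info("cohort selection: %d patients retained, exclusions=%s", len(table), excl)
    return CohortSelection(table, excl)


# --------------------------------------------------------------------------- #
# Symptom attribution and grouping
# --------------------------------------------------------------------------- #

def attribute_symptoms(
    patient_events: pd.DataFrame,
    diagnosis_date,
    symptom_map: dict[str, str] | None = None,
    explanation_map: dict[str, frozenset[str]] | None = None,
    comorbidity_map: dict[str, str] | None = None,
) -> dict[str, int]:
    """Flag raw symptoms for one patient under the temporal attribution rules.

    A symptom is flagged 1 iff (a) its earliest record falls strictly after
    the diagnosis date and (b) no comorbidity that explains it was recorded
    before that earliest record. Pre-diagnosis symptom records never count.
    """
    symptom_map = default_symptom_map() if symptom_map is None else symptom_map
    comorbidity_map = default_comorbidity_map() if comorbidity_map is None else comorbidity_map
    explanation_map = DEFAULT_EXPLANATION_MAP if explanation_map is None else explanation_map
    diagnosis_date = pd.Timestamp(diagnosis_date)

    ev = patient_events.copy()
    ev["date"] = pd.to_datetime(ev["date"])

    comorb_first: dict[str, pd.Timestamp] = {}
    sympt_first_after: dict[str, pd.Timestamp] = {}
    for code, grp in ev.groupby("code"):
        if code in comorbidity_map:
            comorb_first[comorbidity_map[code]] = grp["date"].min()
        elif code in symptom_map:
            after = grp.loc[grp["date"] > diagnosis_date, "date"]
            if len(after):
                sympt_first_after[symptom_map[code]] = after.min()

    flags: dict[str, int] = {}
    for name, first in sympt_first_after.items():
        explained = any(
            comorb_first.get(c) is not None and comorb_first[c] < first
            for c in explanation_map.get(name, ())
        )
        flags[name] = 0 if explained else 1
    return flags


def group_symptoms(
    symptom_flags: dict[str, int] | pd.Series,
    include_confusion_in_neuropsych: bool = False,
) -> dict[str, int]:
    """Collapse raw symptom flags into the four grouped category flags."""
    if isinstance(symptom_flags, pd.Series):
        symptom_flags = symptom_flags.to_dict()
    mapping = symptom_category_map()
    categories = {c: 0 for c in SYMPTOM_CATEGORIES}
    for name, value in symptom_flags.items():
        if name not in mapping:
            raise KeyError(f"unknown symptom name in flags: {name!r}")
        if not value:
            continue
        cat = mapping[name]
        if cat is not None:
            categories[cat] = 1
        if name == "confusion" and include_confusion_in_neuropsych:
            categories["neuropsychological"] = 1
    return categories


def symptom_category_flags(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    symptom_map: dict[str, str] | None = None,
    explanation_map: dict[str, frozenset[str]] | None = None,
    include_confusion_in_neuropsych: bool = False,
) -> pd.DataFrame:
    """Attribution + grouping for every cohort patient (rows align to cohort)."""
    ev = events[events["patient_id"].isin(cohort.index)]
    grouped = dict(tuple(ev.groupby("patient_id")))
    empty = ev.iloc[0:0]
    rows = {}
    for pid, row in cohort.iterrows():
        raw = attribute_symptoms(
            grouped.get(pid, empty), row["diagnosis_date"],
            symptom_map=symptom_map, explanation_map=explanation_map,
        )
        rows[pid] = group_symptoms(raw, include_confusion_in_neuropsych)
    return pd.DataFrame.from_dict(rows, orient="index").reindex(cohort.index).fillna(0).astype(int)


def comorbidity_flags(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    comorbidity_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-patient flags for comorbidities recorded strictly before diagnosis."""
    comorbidity_map = default_comorbidity_map() if comorbidity_map is None else comorbidity_map
    names = sorted(set(comorbidity_map.values()))
    ev = events[events["patient_id"].isin(cohort.index)].copy()
    ev = ev[ev["code"].isin(comorbidity_map)]
    ev["date"] = pd.to_datetime(ev["date"])
    ev["name"] = ev["code"].map(comorbidity_map)
    ev = ev.merge(
        cohort["diagnosis_date"], left_on="patient_id", right_index=True,
    ).reset_index(drop=True)
    ev = ev[ev["date"] < ev["diagnosis_date"]]
    flags = (
        ev.groupby(["patient_id", "name"]).size().unstack(fill_value=0).clip(upper=1)
    )
    return flags.reindex(index=cohort.index, columns=names, fill_value=0).astype(int)


# --------------------------------------------------------------------------- #
# Feature matrix assembly
# --------------------------------------------------------------------------- #

def _age_band(age: float, edges=AGE_BAND_EDGES, labels=AGE_BAND_LABELS) -> str:
    for edge, label in zip(edges, labels):
        if age < edge:
            return label
    return labels[-1]


def build_feature_matrix(
    cohort: pd.DataFrame,
    symptom_categories: pd.DataFrame,
    comorbidities: pd.DataFrame,
    demographics: pd.DataFrame,
    age_band_edges: tuple[int, ...] = AGE_BAND_EDGES,
    age_band_labels: tuple[str, ...] = AGE_BAND_LABELS,
) -> FeatureMatrix:
    """Assemble the binary matrix: 4 symptom categories, 13 comorbidities,
    age band / gender / smoking / drinking one-hot groups (21 parents).
    """
    demo = demographics.set_index("patient_id") if "patient_id" in demographics.columns else demographics
    missing = [p for p in cohort.index if p not in demo.index]
    if missing:
        raise KeyError(f"{len(missing)} cohort patients absent from demographics")
    demo = demo.loc[cohort.index]

    blocks: list[pd.DataFrame] = []
    meta_rows: list[tuple[str, str, str]] = []  # (column, parent, role)

    sym = symptom_categories.reindex(cohort.index).fillna(0).astype(int)
    sym = sym[list(SYMPTOM_CATEGORIES)]
    blocks.append(sym)
    meta_rows += [(c, c, "symptom") for c in sym.columns]

    com = comorbidities.reindex(cohort.index).fillna(0).astype(int)
    blocks.append(com)
    meta_rows += [(c, c, "comorbidity") for c in com.columns]

    bands = cohort["age_at_diagnosis"].map(
        lambda a: _age_band(a, age_band_edges, age_band_labels)
    )
    onehots = [
        ("age band", bands, list(age_band_labels)),
        ("gender", demo["gender"].str.lower(), list(GENDER_LEVELS)),
        ("smoking", demo.get("smoking", pd.Series(index=cohort.index, dtype=object))
                        .replace("", np.nan).fillna(SMOKING_MISSING_LEVEL),
         list(SMOKING_LEVELS)),
        ("drinking", demo.get("drinking", pd.Series(index=cohort.index, dtype=object))
                         .replace("", np.nan).fillna(DRINKING_MISSING_LEVEL),
         list(DRINKING_LEVELS)),
    ]
    for parent, series, levels in onehots:
        unknown = set(series.dropna()) - set(levels)
        if unknown:
            raise ValueError(f"unknown {parent} levels: {sorted(unknown)}")
        block = pd.DataFrame(
            {f"{parent}={lvl}": (series == lvl).astype(int) for lvl in levels},
            index=cohort.index,
        )
        blocks.append(block)
        meta_rows += [(c, parent, "demographic") for c in block.columns]

    values = pd.concat(blocks, axis=1)
    meta = pd.DataFrame(meta_rows, columns=["column", "parent", "role"]).set_index("column")
    fm = FeatureMatrix(values=values, meta=meta)
    fm.validate()
    return fm


# --------------------------------------------------------------------------- #
# Practice-level train/test split
# --------------------------------------------------------------------------- #

def split_by_practice(
    cohort: pd.DataFrame,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[pd.Index, pd.Index]:
    """Hold out all patients from ceil(fraction x n_practices) random practices.

    Sampling whole practices mimics replication in an external data set.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    practices = np.sort(cohort["practice_id"].unique())
    if len(practices) < 2:
        raise ValueError("need at least 2 practices to split")
    n_test = math.ceil(test_fraction * len(practices))
    rng = np.random.default_rng(seed)
    test_practices = set(rng.choice(practices, size=n_test, replace=False))
    mask = cohort["practice_id"].isin(test_practices)
    return cohort.index[~mask], cohort.index[mask]
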