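import numpy as np
import pandas as pd
import pytest

from adsubtypes import features, mca, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Planted 5-class cohort, small enough for fast unit tests."""
    return synthetic.generate_cohort(n_patients=600, n_practices=12, seed=11)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    sel = features.select_cohort(small_cohort.events, small_cohort.demographics)
    sym = features.symptom_category_flags(small_cohort.events, sel.table)
    com = features.comorbidity_flags(small_cohort.events, sel.table)
    fm = features.build_feature_matrix(sel.table, sym, com, small_cohort.demographics)
    truth = small_cohort.true_labels.loc[sel.table.index]
    return fm, truth, sel


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size planted cohort matching the study's synthetic conditions."""
    return synthetic.generate_cohort(n_patients=2000, n_practices=40, seed=1)


@pytest.fixture(scope="session")
def study_features(study_cohort):
    sel = features.select_cohort(study_cohort.events, study_cohort.demographics)
    sym = features.symptom_category_flags(study_cohort.events, sel.table)
    com = features.comorbidity_flags(study_cohort.events, sel.table)
    fm = features.build_feature_matrix(sel.table, sym, com,
                                       study_cohort.demographics)
    truth = study_cohort.true_labels.loc[sel.table.index]
    return fm, truth, sel


@pytest.fixture(scope="session")
def study_mca(study_features):
    fm, truth, _ = study_features
    fit = mca.fit_mca(fm)
    n_comp = mca.select_components(fit)
    return fit, n_comp


@pytest.fixture(scope="session")
def small_coords(small_features):
    fm, truth, _ = small_features
    fit = mca.fit_mca(fm)
    n_comp = max(mca.select_components(fit), 4)
    return fit.row_coordinates.iloc[:, :n_comp].to_numpy(), truth.to_numpy()


def make_events(rows):
    """rows: list of (patient_id, code, date) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "code", "date"])


def make_demo(rows):
    cols = ["patient_id", "birth_year", "gender", "practice_id",
            "smoking", "drinking", "obs_start", "obs_end"]
    return pd.DataFrame(rows, columns=cols[: len(rows[0])])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
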