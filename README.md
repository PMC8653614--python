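# adsubtypes

Discovery and evaluation of clinical subtypes of Alzheimer's disease (AD)
from categorical EHR feature tables.

Alzheimer's disease is clinically heterogeneous: patients differ in symptom
profile, comorbidity burden, age of onset and rate of progression. Routinely
collected primary-care records make it possible to subtype patients on their
full clinical picture rather than on cognition or imaging alone — but
different clustering algorithms carve the same cohort differently, so any
claimed subtype needs systematic evaluation. This package implements that
whole workflow as a tested, reusable pipeline, for epidemiologists and health
data scientists working with event-level EHR extracts:

1. **Feature construction** — cohort eligibility rules, temporal symptom
   attribution (a symptom counts only if recorded after diagnosis and not
   explained by a prior comorbidity), grouping of raw symptoms into four
   categories, and one-hot encoding into a patients × 21-variable binary
   matrix (4 symptom categories, 13 comorbidities, age band / gender /
   smoking / drinking).
2. **MCA** — multiple correspondence analysis of the indicator matrix
   embeds the binary profiles in a Euclidean space via the weighted SVD of
   the centred indicator matrix; components retained at the scree elbow.
3. **Four clustering methods** — k-means (best of 100 restarts; k by majority
   vote of WSS elbow, silhouette and BIC over k = 2–14), kernel k-means with
   an exponential Hamming-distance kernel K(x,y) = exp(−γ·d_H(x,y)) on the
   raw categories, affinity propagation with a preference sweep and a
   net-similarity elbow, and latent class analysis by EM with BIC over
   k = 2–8.
4. **Four evaluation measures** — cluster *structure* (silhouette
   s = (b−a)/max(a,b)), *stability* (clusterwise bootstrap Jaccard over 100
   resamples, ≥ 0.75 considered stable), *replicability* (decision-tree gold
   labels versus independent re-clustering of held-out practices), and
   *clinical utility* (does cluster membership predict MMSE decline and time
   to assisted living better than every individual feature — adjusted R² and
   Cox proportional hazards).
5. **Outcomes and comparison** — per-cluster MMSE slopes, Kaplan–Meier
   curves and log-rank tests for death and assisted living, consultation
   rates and ChEI treatment duration; cluster naming by significantly
   deviating features ("Typical AD", "Non-typical AD", "anxiety +
   depression", …); alluvial-ready flow tables and cross-method
   consistent-cluster detection.

Because the real data source (UK primary-care EHR) is access-restricted, the
package includes a synthetic cohort generator that plants latent subtypes
with class-dependent outcomes. It is first-class, tested code: every stage of
the pipeline runs against it, and recovery of the planted structure is part
of the test suite. See `docs/methods.md` for the model, its assumptions and
what passing tests do and do not show about real data.

## Worked example

```python
from adsubtypes import synthetic, features, mca, clustering, evaluation
from scipy.spatial.distance import pdist, squareform

cohort = synthetic.generate_cohort(n_patients=2000, n_practices=40, seed=1)
sel = features.select_cohort(cohort.events, cohort.demographics)
sym = features.symptom_category_flags(cohort.events, sel.table)
com = features.comorbidity_flags(cohort.events, sel.table)
fm = features.build_feature_matrix(sel.table, sym, com, cohort.demographics)
print(f"cohort: {len(sel.table)} patients, {fm.n_parents} parent variables")

fit = mca.fit_mca(fm)
n_comp = mca.select_components(fit)
print(f"MCA: {n_comp} components retained "
      f"({fit.explained_inertia[:n_comp].sum():.1%} of inertia)")

X = fit.row_coordinates.iloc[:, :n_comp].to_numpy()
report = clustering.select_k(X, range(2, 15), n_restarts=100, seed=1)
sol = clustering.run_kmeans(X, report.chosen_k, n_restarts=100, seed=1)
print(f"k-means: k={report.chosen_k} chosen by {report.rule_choices}")

D = squareform(pdist(X))
print(f"mean silhouette: {evaluation.silhouette(D, sol.labels).mean:.3f}")

from sklearn.metrics import adjusted_rand_score
truth = cohort.true_labels.loc[sel.table.index]
print(f"ARI vs planted subtypes: {adjusted_rand_score(truth, sol.labels):.3f}")
```

prints

```
cohort: 1977 patients, 21 parent variables
MCA: 4 components retained (38.2% of inertia)
k-means: k=5 chosen by {'wss_elbow': 5, 'silhouette': 5, 'bic': 5}
mean silhouette: 0.517
ARI vs planted subtypes: 0.904
```

Reading the output: 23 of the 2,000 generated patients fall to the
eligibility filters (missing demographics, no recorded symptom or
comorbidity); the scree elbow keeps 4 MCA components — one fewer than the
number of planted classes, as expected for 5 groups; all three k-selection
rules agree on k = 5; and the partition recovers the planted subtypes with
adjusted Rand index 0.90, with the residual disagreement concentrated in the
two "typical AD" classes that differ only in comorbidity profile.

## Command line

Each stage is a subcommand over CSV/JSON files, so stages can be re-run in
isolation; `run-all` executes the whole study from one config:

```bash
adsubtypes simulate --n-patients 2000 --seed 1 --out data/
adsubtypes features --events data/events.csv --demographics data/demographics.csv --out feat/
adsubtypes mca --features-csv feat/feature_matrix.csv --meta-csv feat/feature_meta.csv --out mca/
adsubtypes cluster --coords mca/mca_coordinates.csv --method kmeans --seed 1 --out cl/
adsubtypes run-all --seed 1 --out runs/
```

`run-all` writes a run directory with the feature matrix, MCA coordinates
and scree data, per-method labels and diagnostics, stability/replicability
reports, per-cluster outcome tables, KM curves, characterisation tables,
cluster names, the alluvial flow table and a collating `summary.json`.

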