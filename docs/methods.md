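# Methods

`adsubtypes` implements a complete pipeline for discovering and evaluating
clinical subtypes of Alzheimer's disease (AD) from categorical EHR-style
feature tables: feature construction with temporal attribution rules, MCA,
four clustering methods with their model-selection procedures, a four-metric
evaluation framework (structure, stability, replicability, clinical utility),
per-cluster outcome comparison, and cross-method consistency analysis. Because
UK primary-care dementia extracts are access-restricted, the package ships a
synthetic cohort generator that plants latent subtypes; every downstream stage
is exercised and tested against it.

## Feature construction

Inputs are a longitudinal event table (`patient_id, code, date`) and a
demographics table. Eligibility requires: a dementia diagnosis event,
diagnosis after age 40, at least one year of observation before and after
diagnosis, at least one recorded symptom or comorbidity, and non-missing birth
year and gender. Exclusion counts are logged at every filter (a CONSORT-style
audit is written by the pipeline).

Three feature roles enter the matrix (21 parent variables by default):

* **Symptoms** are attributed to the dementia only when (a) the earliest
  record falls *strictly after* the diagnosis date (a record on the diagnosis
  day does not count — ties are not attributed) and (b) no comorbidity that
  explains the symptom (e.g. a prior depression diagnosis for a depression
  symptom) was recorded before it. Raw symptoms are grouped into four
  categories: memory; confusion; neuropsychological (aggression, agitation,
  anxiety, apathy, delirium, delusion, depression, hallucinations, sleep,
  eating, paranoia, mood disorders); and motor (difficulty walking,
  orientation problems). Confusion is kept as its own category by default; a
  switch additionally folds it into the neuropsychological group. Symptoms
  with no natural group (fainting, falls, incontinence, language, seizure)
  count toward eligibility but not toward the matrix.
* **Comorbidities** (13): anxiety, atherosclerosis, atrial fibrillation,
  cancer, depression, diabetes, haemorrhagic stroke, hearing loss, heart
  failure, hyperglycaemia, hypertension, kidney disease, rheumatoid
  arthritis. Only records strictly before diagnosis count, so the flags are
  not consequences of the disease. Hypercholesterolemia is excluded from the
  default dictionary (prevalence too low to be informative).
* **Demographics**: age at diagnosis banded at 42–73 / 74–78 / 79–82 / 83–87 /
  88+ (the cohort quintile edges, configurable); gender; smoking (missing →
  non-smoker); drinking (missing → "drinking status not specified"). All are
  one-hot encoded; each group sums to exactly one per patient.

The replication split holds out all patients of `ceil(0.25 × n_practices)`
randomly chosen practices, mimicking an external data set with its own
practice-level coding idiosyncrasies.

## MCA

Indicator-matrix correspondence analysis of the complete disjunctive table
(single-column binary features are expanded to presence/absence pairs so every
parent contributes one count per patient). The generalized SVD of the centred,
mass-standardised matrix gives principal inertias and row principal
coordinates; total inertia satisfies the identity J/Q − 1 (J categories, Q
parents), verified numerically in the tests. Zero-mass categories are dropped
with a warning; component signs are fixed by forcing the first nonzero column
loading positive. No Benzécri/Greenacre correction is applied by default (the
correction is available as an option); principal coordinates already weight
components by inertia, so they are used unscaled downstream. The retained
component count is the scree elbow — the maximum second difference of the
explained-inertia profile — which on the default synthetic cohort at n = 2,000
retains 4 components (K − 1 informative dimensions for 5 planted classes). At
small n (≲ 600) the profile is flatter and the elbow may retain fewer; the
pipeline enforces a floor of 2.

MCA is fitted once on the entire cohort; clustering then operates on the
training rows only. This keeps training and held-out patients in one
embedding, which the replicability protocol relies on (no supplementary
projection is performed anywhere).

## Clustering methods

All methods are deterministic given their seed; assignment ties break to the
lowest cluster index; empty clusters during Lloyd iterations are re-seeded
with the point farthest from its centroid; the within-restart objective is
asserted non-increasing at every iteration.

* **k-means** on MCA coordinates: Lloyd's algorithm with k-means++
  initialisation, best of 100 restarts by total within-cluster sum of squares.
  k is chosen over 2–14 by majority vote of three rules — the WSS elbow
  (maximum second difference), the maximum mean silhouette, and the minimum
  BIC — with ties broken by the silhouette. The BIC uses the spherical-
  Gaussian (x-means) formulation with pooled variance over n − k degrees of
  freedom and a cluster-share entropy term; the naive variance plug-in
  degenerates to always choosing the largest k. A run is flagged
  "no structure" when the silhouette profile is uniformly tiny (< 0.1) or flat
  (range < 20% of its maximum), since a flat profile gives no basis for
  choosing any k.
* **Kernel k-means** on the raw categorical features (no MCA):
  K(x, y) = exp(−γ·d_H(x, y)) with d_H the Hamming distance over *parent
  variables* (a categorical parent counts once however it is one-hot coded)
  and γ = 1/Q by default. This kernel is positive semidefinite because the
  Hamming distance is a sum of per-variable conditionally negative definite
  terms. Lloyd updates use the kernel-distance identity
  d²(x, C) = K(x,x) − 2·mean_{y∈C} K(x,y) + mean_{y,z∈C} K(y,z); with a linear
  kernel the procedure reproduces plain k-means labels exactly from a shared
  initialisation (asserted in the tests). k is selected over 2–8 by the same
  three-rule vote, with the silhouette computed on the kernel-induced
  distance.
* **Affinity propagation** on negative squared Euclidean similarities of the
  MCA coordinates: standard responsibility/availability message passing
  (damping 0.9, max 1000 iterations, convergence window 50; on
  non-convergence the current state is returned with a flag rather than an
  error). Exemplars are refined to the member maximising within-cluster
  similarity. The preference is swept over a geometric grid spanning
  −|99th-percentile similarity| down to −50·|minimum similarity|: with ~2,000
  points the preference must fall far below any single similarity before K
  becomes small, so the textbook [min, median] span never leaves K ≳ 10. Net
  similarity is the sum of each point's similarity to its exemplar (exemplars
  contribute zero), which is comparable across preferences at fixed K. The
  chosen solution sits at the elbow of net similarity versus K: the interior K
  minimising the ratio of the gain per added cluster after K to the gain
  before K. This scale-invariant rule recovers the planted K where both the
  raw second difference (biased to the steep end) and a normalized-chord rule
  (biased by how far into large K the grid reaches) fail.
* **Latent class analysis**: by default a diagonal-covariance Gaussian mixture
  on the MCA coordinates (the study protocol applies MCA before LCA), fitted
  by EM with 5 random starts per k, k = 2–8 by minimum BIC, patients assigned
  to the maximum-posterior class. A classical independent-Bernoulli latent
  class model on the raw one-hot matrix is available as a mode; it is the one
  used for the planted-Bernoulli recovery tests, where BIC selects the
  generating k. On MCA coordinates of binary data (a discrete point cloud)
  Gaussian BIC tends to favour the upper end of the k range — a known property
  of the paper-faithful mode, not a defect.

## Evaluation framework

* **Structure**: silhouette s(i) = (b − a)/max(a, b) on a dissimilarity
  matrix; singleton clusters score 0; verified to 1e-12 against a brute-force
  reference and cross-checked against an independent implementation.
* **Stability**: 100 bootstrap resamples are re-clustered with frozen
  hyperparameters; each original cluster (restricted to the unique resampled
  points) takes its best Jaccard overlap with any bootstrap cluster
  (clusterwise maximum matching; a one-to-one Hungarian variant is available);
  the per-bootstrap means are averaged and compared with the conventional 0.75
  stability threshold. Bootstrap duplicates are kept as distinct observations
  when re-clustering; Jaccard is computed on unique original indices.
  Re-clustering inside the bootstrap uses 10 k-means restarts rather than 100
  — the problem-size choice for the default protocol; the spread of best-of-10
  versus best-of-100 WSS is far below the Jaccard resolution at these sizes.
* **Replicability**: a cost-complexity-pruned decision tree (pruning strength
  chosen on an internal 80/20 split of the training set) learns the training
  clustering and gold-labels the held-out practices; the held-out set is
  independently re-clustered; concordance is the aligned agreement fraction
  over all test patients (no abstentions). The tree is trained on the MCA
  coordinates — the space in which the k-means partition is defined — because
  a single axis-aligned tree cannot represent a 21-variable voting boundary
  on the raw one-hot features (its cross-validated accuracy plateaus near
  0.91 there, capping concordance below the partition's actual
  reproducibility).
* **Clinical utility**: for every parent variable and for cluster membership
  (one-hot against the largest cluster), a univariable linear model of the
  per-patient MMSE slope (adjusted R²) and a Cox proportional-hazards model
  of time to assisted living (Breslow ties; partial log-likelihood used for
  ranking). Cluster labels that outrank every single feature carry predictive
  information beyond any one variable.
* **Label alignment** (required by stability, replicability and the flow
  tables): Hungarian assignment maximising agreement on the contingency
  table; unmatched clusters keep fresh labels. All metrics are invariant to
  cluster relabeling.

## Outcomes

Per-patient MMSE slope by ordinary least squares over all visits (equal to
the two-point slope when only two visits exist; patients with fewer than two
dated scores are excluded and counted). Kaplan–Meier curves with Greenwood
95% bands, pairwise and multi-group log-rank tests, and Cox models come from
standard survival machinery; monotone-likelihood/separation is flagged and
the affected confidence bounds reported as unbounded rather than raised.
Per-cluster means of consultation and missed-appointment rates, ChEI duration
and MMSE slope carry normal-approximation 95% confidence intervals.

## Characterisation and comparison

Each cluster is tested feature-by-feature against the rest of the cohort with
a continuity-corrected two-proportion test, Bonferroni-adjusted over the full
clusters × features family (family size asserted exactly; Bonferroni is
deliberate — cluster names are clinical claims, so conservatism beats power;
an unadjusted mode exists for exploration). Naming: significantly elevated
memory with no other elevated symptom category → "Typical AD"; every symptom
category elevated except memory → "Non-typical AD"; otherwise the top
deviating features by prevalence difference. Clusters under 5 patients are
reported with a warning and their tests skipped.

Cross-method comparison exports the per-patient label matrix and all pairwise
contingency tables in long format (ready for alluvial plotting), and the
consistent-cluster search intersects, across methods, the patients of every
cluster whose elevated-feature set contains a given signature (default:
depression + anxiety + earliest onset band + current smoker).

## Synthetic cohort generator

The generator is the package's study bed, not a model of UK coding practice.
Five default profiles mirror the cluster archetypes reported for primary-care
AD cohorts: an anxiety/depression/early-onset/smoking class (18%, ~3× MMSE
decline, highest consultation rate, shortest ChEI duration), typical AD with
hypertension and kidney disease (25%), typical AD with cancer and hearing
loss (20%, male-dominated), non-typical AD (20%, elevated confusion /
neuropsychological / motor symptoms with spared memory), and a CVD class
(17%, oldest onset, highest mortality). Signature features carry
between-class probability gaps of 0.6–0.85; the profiles were calibrated once
against the information bound of the generative model (a Bayes-optimal
classifier on the planted parameters reaches 96.5% accuracy), so the planted
partition is actually recoverable — with weaker signatures no method could
reach high agreement with truth even in principle.

Mechanics: class ← mixing weights; practice uniform; diagnosis date uniform
inside the 1997–2016 study window with ≥ 1.5-year margins; observation spans
1 + Exp(3) years before and 1 + min(Exp(4), 12) after diagnosis; comorbidity
events uniform before diagnosis, symptom events (one representative code per
grouped category) after it. A small contamination fraction (5%) receives a
post-diagnosis depression symptom *plus* a pre-diagnosis depression
comorbidity, exercising the explained-symptom rule; 1% of patients have a
missing birth year or gender, exercising cohort exclusion. Outcomes given
class: linear MMSE trajectories (baseline N(26, 2), class decline rate,
Gaussian visit noise sd 1, one visit just before diagnosis then annual),
exponential times to assisted living and death (right-censored at the end of
follow-up, assisted living also censored by death), Poisson consultation
counts, missed appointments as a 10% Poisson thinning of the consultation
rate (the study design has no separate missed-appointment parameter), and
Normal ChEI durations truncated at censoring.

What the generator does *not* emulate: within-class correlation between
comorbidities, coding intensity differences across practices, informative
censoring, drift of symptom prevalence over the disease course, and
measurement error in event dates. Passing tests therefore demonstrate that
the pipeline's machinery is correct and its statistics calibrated under a
known truth — not that real EHR cohorts contain five clean subtypes.
Exponential hazards are the simplest model consistent with KM-based
comparisons; a Weibull shape would be the first extension.

## Numerical choices and degenerate inputs

EM: tolerance 1e-6, max 500 iterations, components with weight < 1/n trigger
a restart. k-means: convergence on label fixed-point, max 300 iterations.
MCA rank cut-off: singular values below max(J, n)·eps·σ₁ (absolute floor
1e-12). Affinity propagation adds a deterministic 1e-12-scale jitter to break
exact symmetry ties. Empty inputs yield empty cohorts, not errors; malformed
dates are dropped row-wise with logged counts; a single-cluster silhouette,
a zero-event Cox model and a single-group log-rank are errors; an all-censored
KM curve is a warning.

## Default problem sizes

The shipped protocol runs at n = 2,000 patients, 40 practices, 100 k-means
restarts, 100 bootstrap resamples (10 restarts within each), a 15-point
preference grid, and k ranges 2–14 (k-means), 2–8 (kernel k-means, LCA).
These sizes keep a full end-to-end run on one CPU to roughly ten minutes while
leaving every selection rule and threshold at its protocol value; the paper's
original cohort (~8,000 patients) runs with the same code by raising
`n_patients`.

## Known limitations

Gaussian-mode LCA inherits the misfit of a continuous mixture applied to a
discrete embedded cloud (see above). Affinity propagation is O(n²) in memory
and time per iteration, the practical ceiling on cohort size. The two
"typical AD" classes differ mainly in comorbidity profile, so k-means
occasionally trades a few patients between them — visible as ARI ≈ 0.90–0.92
rather than 1.0. The consistent-cluster rule uses strict intersection across
methods; a union-based variant would report larger, noisier sets.
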