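"""End-to-end study orchestration driven by a single declarative config.

Stages: synthetic cohort generation (or user-supplied tables in the same
schema) -> cohort selection and feature construction -> MCA -> four
clustering methods -> evaluation (structure, stability, replicability) ->
outcomes and clinical utility -> characterisation and cross-method
comparison. Every stage writes its outputs to the run directory so each can
be re-run in isolation; a summary JSON collates the headline quantities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from . import clustering, comparison, evaluation, features, mca, outcomes, synthetic

logger = logging.getLogger(__name__)

CONSISTENT_SIGNATURE = frozenset({
    "depression", "anxiety", "age band=42-73", "smoking=current smoker",
})


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "runs"
    n_patients: int = 2000
    n_practices: int = 40
    followup_years: float = 8.0
    test_fraction: float = 0.25
    kmeans_k_range: tuple[int, int] = (2, 14)
    kernel_k_range: tuple[int, int] = (2, 8)
    lca_k_range: tuple[int, int] = (2, 8)
    n_restarts: int = 100
    bootstrap_restarts: int = 10
    n_bootstraps: int = 100
    lca_mode: str = "gaussian"
    kernel_gamma: float | None = None
    ap_grid_size: int = 15
    ap_damping: float = 0.9
    alpha: float = 0.05
    methods: tuple[str, ...] = ("kmeans", "kernel_kmeans", "affinity_propagation", "lca")
    stability_methods: tuple[str, ...] = ("kmeans",)
    events_path: str | None = None       # external input instead of synthesis
    demographics_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kmeans_k_range", "kernel_k_range", "lca_k_range",
                    "methods", "stability_methods"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        for p in (self.events_path, self.demographics_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class StudyResult:
    run_dir: Path
    summary: dict = field(default_factory=dict)


def _krange(pair) -> range:
    lo, hi = pair
    return range(lo, hi + 1)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Index,)):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full pipeline; outputs and summary land in the run directory."""
    config.validate()
    run_dir = Path(config.out_dir) / f"run_seed{config.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "config"
    try:
        _write_json(run_dir / "config.json", asdict(config))

        # ------------------------------------------------------------- data
        stage = "simulate"
        if config.events_path is not None:
            events = pd.read_csv(config.events_path)
            demographics = pd.read_csv(config.demographics_path)
            truth = None
        else:
            cohort_sim = synthetic.generate_cohort(
                n_patients=config.n_patients, n_practices=config.n_practices,
                seed=config.seed,
            )
            cohort_sim.write(run_dir)
            events, demographics = cohort_sim.events, cohort_sim.demographics
            truth = cohort_sim.true_labels

        # --------------------------------------------------------- features
        stage = "features"
        selection = features.select_cohort(events, demographics)
        cohort = selection.table
        sym = features.symptom_category_flags(events, cohort)
        com = features.comorbidity_flags(events, cohort)
        fm = features.build_feature_matrix(cohort, sym, com, demographics)
        fm.to_csv(run_dir / "feature_matrix.csv", run_dir / "feature_meta.csv")
        _write_json(run_dir / "cohort_audit.json", selection.exclusions)
        summary["n_cohort"] = len(cohort)
        summary["n_parent_variables"] = fm.n_parents
        summary["exclusions"] = selection.exclusions

        train_ids, test_ids = features.split_by_practice(
            cohort, config.test_fraction, seed=config.seed,
        )
        summary["n_train"] = len(train_ids)
        summary["n_test"] = len(test_ids)
        fm_train = features.FeatureMatrix(fm.values.loc[train_ids], fm.meta)
        fm_test = features.FeatureMatrix(fm.values.loc[test_ids], fm.meta)

        # -------------------------------------------------------------- MCA
        # fitted once on the entire cohort so train and held-out patients
        # share one embedding; clustering itself only sees the training rows
        stage = "mca"
        mca_fit = mca.fit_mca(fm)
        n_comp = max(mca.select_components(mca_fit), 2)
        all_coords = mca_fit.row_coordinates.iloc[:, :n_comp]
        coords = all_coords.loc[train_ids]
        all_coords.to_csv(run_dir / "mca_coordinates.csv")
        mca_fit.scree().to_csv(run_dir / "mca_scree.csv", index=False)
        summary["mca_components_retained"] = n_comp

        # -------------------------------------------------------- clustering
        stage = "cluster"
        X = coords.to_numpy()
        D = squareform(pdist(X))
        solutions: dict[str, clustering.ClusterSolution] = {}
        diagnostics: dict[str, dict] = {}

        if "kmeans" in config.methods:
            report = clustering.select_k(
                X, _krange(config.kmeans_k_range),
                n_restarts=config.n_restarts, seed=config.seed,
            )
            sol = clustering.run_kmeans(
                X, report.chosen_k, n_restarts=config.n_restarts, seed=config.seed,
            )
            solutions["kmeans"] = sol
            diagnostics["kmeans"] = {
                "chosen_k": report.chosen_k,
                "rule_choices": report.rule_choices,
                "curves": report.to_frame().to_dict(orient="list"),
            }

        kernel_D = None
        if "kernel_kmeans" in config.methods:
            kernel_train = clustering.hamming_kernel(fm_train, gamma=config.kernel_gamma)
            kernel_D = clustering.kernel_induced_distances(kernel_train)
            kreport = clustering.select_k(
                X, _krange(config.kernel_k_range),
                runner=lambda k: clustering.run_kernel_kmeans(
                    kernel_train, k, n_restarts=max(config.n_restarts // 4, 1),
                    seed=config.seed + k,
                ),
                dissimilarity=kernel_D,
            )
            sol = clustering.run_kernel_kmeans(
                kernel_train, kreport.chosen_k,
                n_restarts=max(config.n_restarts // 4, 1), seed=config.seed,
            )
            solutions["kernel_kmeans"] = sol
            diagnostics["kernel_kmeans"] = {
                "chosen_k": kreport.chosen_k,
                "rule_choices": kreport.rule_choices,
            }

        if "affinity_propagation" in config.methods:
            S = clustering.negative_squared_distances(X)
            sweep = clustering.sweep_preference(
                S, n_grid=config.ap_grid_size, damping=config.ap_damping,
            )
            solutions["affinity_propagation"] = sweep.chosen
            diagnostics["affinity_propagation"] = {
                "chosen_k": sweep.chosen.k,
                "chosen_preference": sweep.chosen_preference,
                "sweep": sweep.rows.to_dict(orient="list"),
            }

        if "lca" in config.methods:
            lca_data = X if config.lca_mode == "gaussian" else fm_train.values.to_numpy()
            sol = clustering.run_latent_class(
                lca_data, _krange(config.lca_k_range), seed=config.seed,
                mode=config.lca_mode,
            )
            solutions["lca"] = sol
            diagnostics["lca"] = {"chosen_k": sol.k, "bic": sol.extras["bic"]}

        labels_frame = pd.DataFrame(
            {m: s.labels for m, s in solutions.items()}, index=train_ids,
        )
        labels_frame.to_csv(run_dir / "cluster_labels.csv")
        _write_json(run_dir / "cluster_diagnostics.json", diagnostics)
        summary["chosen_k"] = {m: s.k for m, s in solutions.items()}
        if truth is not None:
            summary["ari_vs_truth"] = {
                m: float(adjusted_rand_score(truth.loc[train_ids], s.labels))
                for m, s in solutions.items()
            }

        # -------------------------------------------------------- evaluation
        stage = "evaluate"
        sil = {
            m: evaluation.silhouette(
                kernel_D if m == "kernel_kmeans" and kernel_D is not None else D,
                s.labels,
            ).mean
            for m, s in solutions.items()
        }
        summary["mean_silhouette"] = sil

        stability: dict[str, float] = {}
        for m in config.stability_methods:
            if m not in solutions:
                continue
            proc = _frozen_procedure(m, solutions[m].k, config, fm_train)
            rep = evaluation.bootstrap_stability(
                X, proc, n_bootstraps=config.n_bootstraps, seed=config.seed,
                reference_labels=solutions[m].labels,
            )
            stability[m] = rep.overall_mean_jaccard
            _write_json(run_dir / f"stability_{m}.json", {
                "overall_mean_jaccard": rep.overall_mean_jaccard,
                "per_cluster": rep.per_cluster_mean_jaccard,
                "stable": rep.stable_flag,
            })
        summary["stability_mean_jaccard"] = stability

        test_coords = all_coords.loc[test_ids].to_numpy()
        repl = {}
        if "kmeans" in solutions:
            k = solutions["kmeans"].k
            rep = evaluation.replicability(
                coords, solutions["kmeans"].labels, all_coords.loc[test_ids],
                lambda _: clustering.run_kmeans(
                    test_coords, k, n_restarts=config.n_restarts,
                    seed=config.seed + 1,
                ).labels,
                seed=config.seed,
            )
            repl["kmeans"] = rep.concordance_fraction
            rep.confusion_table.to_csv(run_dir / "replicability_confusion_kmeans.csv")
        summary["replicability_concordance"] = repl

        # ---------------------------------------------------------- outcomes
        stage = "outcomes"
        if config.events_path is None:
            otab = synthetic.generate_outcomes(
                cohort_sim, followup_years=config.followup_years,
                seed=config.seed + 7,
            )
            otab.write(run_dir)
            slopes, _ = outcomes.mmse_slopes(otab.mmse_series)
            train_out = otab.table.loc[train_ids]
            km_sol = solutions.get("kmeans")
            if km_sol is not None:
                summ = outcomes.outcome_summary(
                    train_out, km_sol.labels, mmse_slope=slopes,
                )
                summ.means.to_csv(run_dir / "outcome_means_kmeans.csv", index=False)
                summ.km_curves.to_csv(run_dir / "km_curves_kmeans.csv", index=False)
                summ.pairwise_logrank.to_csv(
                    run_dir / "logrank_kmeans.csv", index=False,
                )
                util = outcomes.utility_comparison(
                    fm_train, km_sol.labels, train_out, mmse_slope=slopes,
                )
                util.table.drop(
                    columns=["hazard_ratios", "hr_ci_lower", "hr_ci_upper"]
                ).to_csv(run_dir / "utility_kmeans.csv")
                summary["utility"] = {
                    "r2_ranking": util.r2_ranking[:5],
                    "cox_ranking": util.cox_ranking[:5],
                    "cluster_top_r2": util.cluster_top_r2,
                    "cluster_top_cox": util.cluster_top_cox,
                }

        # -------------------------------------------------------- comparison
        stage = "compare"
        chars = {
            m: comparison.characterize(fm_train, s.labels, alpha=config.alpha)
            for m, s in solutions.items()
        }
        _write_json(run_dir / "cluster_names.json",
                    {m: c.names for m, c in chars.items()})
        pd.concat(
            [c.table.assign(method=m) for m, c in chars.items()],
            ignore_index=True,
        ).to_csv(run_dir / "characterisation.csv", index=False)
        summary["cluster_names"] = {m: c.names for m, c in chars.items()}

        if len(solutions) >= 2:
            flow = comparison.cross_method_flow(
                list(solutions.values()), patient_index=train_ids,
            )
            flow.pairwise.to_csv(run_dir / "flow_table.csv", index=False)
            members, per_method = comparison.consistent_cluster(
                list(solutions.values()), chars, set(CONSISTENT_SIGNATURE),
                patient_index=train_ids,
            )
            summary["consistent_cluster"] = {
                "n_patients": len(members),
                "per_method_clusters": per_method,
            }

        stage = "summary"
        _write_json(run_dir / "summary.json", summary)
        return StudyResult(run_dir=run_dir, summary=summary)
    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs kept in %s",
                         stage, run_dir)
        raise


def _frozen_procedure(method: str, k: int, config: RunConfig, fm_train):
    """Re-clustering closure with frozen hyperparameters for the bootstrap."""
    seed = config.seed + 101
    if method == "kmeans":
        return lambda Xb: clustering.run_kmeans(
            Xb, k, n_restarts=config.bootstrap_restarts, seed=seed,
        ).labels
    if method == "lca":
        return lambda Xb: clustering.run_latent_class(
            Xb, k_range=[k], seed=seed, mode="gaussian",
        ).labels
    if method == "affinity_propagation":
        raise ValueError(
            "affinity propagation stability requires a similarity-space "
            "procedure; use bootstrap_stability directly"
        )
    raise ValueError(f"no frozen procedure for {method!r}")
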