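"""End-to-end experiment drivers.

Each driver generates (or loads) its inputs, trains the models, evaluates
them, and returns a JSON-serializable report. The central comparison is
*direct* management prediction (a classifier trained on the management
labels) against *inferred* management (a diagnosis classifier whose
predicted diagnosis distribution is marginalized against the empirical
management-given-diagnosis priors of the training split). All drivers are
deterministic given their seed list: every stochastic stage derives child
seeds from the experiment seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as ag
from .classifiers import (
    ALL_TASKS,
    DIAGNOSIS_TASK,
    MANAGEMENT_TASK,
    TrainingConfig,
    predict_proba,
    train_model,
)
from .cohort import (
    Cohort,
    GeneratorConfig,
    RaterPanel,
    design_matrix,
    generate_exact_cohort,
)
from .distances import MEASURES, distance_profile
from .labels import DEFAULT_LABEL_SPACE
from .metrics import auroc_one_vs_rest, classwise_metrics, confusion_matrix
from .priors import (
    collapse_management_to_binary,
    decide_label,
    estimate_priors,
    map_diagnosis_to_binary,
    marginalize_management,
)

logger = logging.getLogger("lesionmgmt")

MODALITY_COMBOS: tuple[str, ...] = ("C", "CM", "D", "DM", "CD", "CDM")


@dataclass(frozen=True)
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    comparison: str = "all"  # "binary" evaluates only the binary mappings
    seeds: tuple[int, ...] = (0,)
    modalities: tuple[str, ...] = MODALITY_COMBOS
    model_modalities: str = "CDM"
    cv3: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        bad = set(self.modalities) - set(MODALITY_COMBOS)
        if bad:
            raise ValueError(f"unknown modality combinations {sorted(bad)}")


def derive_seed(seed: int, stage: int) -> int:
    """A reproducible child seed (< 2^31) for a named pipeline stage."""
    child = np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31)
    return int(child)


def _onehot_targets(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((labels.size, k))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _train_single(
    X: np.ndarray, labels: np.ndarray, task: str, training: TrainingConfig, seed: int,
    modalities: str,
):
    cfg = replace(training, task_list=(task,), seed=seed)
    return train_model(X, {task: labels}, cfg, modalities=modalities)


def _evaluate_arm(
    name: str,
    probs: np.ndarray,
    true_mgmt: np.ndarray,
    diagnosis: np.ndarray,
) -> dict:
    """All-label metrics for one arm: decisions, confusion with diagnosis
    breakdown, class-wise metrics, AUROC, over-excision and error counts."""
    space = DEFAULT_LABEL_SPACE
    decided = decide_label(probs)
    cm = confusion_matrix(
        true_mgmt,
        decided,
        space.n_management,
        class_names=space.management_labels,
        breakdown_by=diagnosis,
        breakdown_names=space.diagnosis_labels,
    )
    auroc = auroc_one_vs_rest(true_mgmt, probs)
    mets = classwise_metrics(cm, auroc)
    exc = space.management_index["EXC"]
    over_excision = int(((true_mgmt != exc) & (decided == exc)).sum())
    malignant = map_diagnosis_to_binary(diagnosis).astype(bool)
    malignancy_miss = int((malignant & (decided != exc)).sum())
    correct = decided == true_mgmt
    return {
        "name": name,
        "decided": decided,
        "correct": correct,
        "confusion": cm,
        "metrics": mets,
        "over_excision": over_excision,
        "malignancy_miss": malignancy_miss,
        "accuracy": mets.overall_accuracy,
    }


def _arm_summary(arm: dict) -> dict:
    out = arm["metrics"].to_dict()
    out["over_excision"] = arm["over_excision"]
    out["malignancy_miss"] = arm["malignancy_miss"]
    out["confusion"] = arm["confusion"].counts.tolist()
    return out


def _binary_eval(name: str, pred_binary: np.ndarray, true_binary: np.ndarray) -> dict:
    cm = confusion_matrix(true_binary, pred_binary, 2, class_names=("NOEXC", "EXC"))
    mets = classwise_metrics(cm)
    return {
        "name": name,
        "accuracy": mets.overall_accuracy,
        "mean_sensitivity": mets.macro_sensitivity,
        "confusion": cm.counts.tolist(),
        "correct": pred_binary == true_binary,
    }


def _compare_distances(
    pred_probs: np.ndarray, infr_probs: np.ndarray, targets: np.ndarray, seed: int
) -> dict:
    """Four distance profiles per arm, Wilcoxon + Cohen's d + sub-sampling
    CIs comparing the two arms per measure."""
    out = {}
    for i, measure in enumerate(MEASURES):
        prof_pred = distance_profile(pred_probs, targets, measure)
        prof_infr = distance_profile(infr_probs, targets, measure)
        test = ag.wilcoxon_signed_rank(prof_pred.values, prof_infr.values)
        d = ag.cohens_d(prof_infr.values, prof_pred.values)
        out[measure] = {
            "mean_pred": prof_pred.mean,
            "mean_infr": prof_infr.mean,
            "wilcoxon": test.to_dict(),
            "cohens_d_infr_minus_pred": d,
            "ci_pred": ag.resample_summary(
                prof_pred.values, seed=derive_seed(seed, 100 + i)
            ).to_dict(),
            "ci_infr": ag.resample_summary(
                prof_infr.values, seed=derive_seed(seed, 200 + i)
            ).to_dict(),
        }
    return out


def direct_vs_inferred_once(
    generator: GeneratorConfig,
    training: TrainingConfig,
    seed: int,
    with_distances: bool = True,
) -> dict:
    """One seed of the central comparison on a freshly generated cohort."""
    gen = replace(generator, seed=derive_seed(seed, 0))
    cohort = generate_exact_cohort(gen)
    return direct_vs_inferred_on_split(
        cohort.split("train"), cohort.split("test"), training, seed, with_distances
    )


def direct_vs_inferred_on_split(
    train: Cohort,
    test: Cohort,
    training: TrainingConfig,
    seed: int,
    with_distances: bool = True,
    modalities: str = "CDM",
) -> dict:
    space = DEFAULT_LABEL_SPACE
    Xtr = design_matrix(train, modalities)
    Xte = design_matrix(test, modalities)

    diag_model = _train_single(
        Xtr, train.diagnosis, DIAGNOSIS_TASK, training, derive_seed(seed, 1), modalities
    )
    mgmt_model = _train_single(
        Xtr, train.management, MANAGEMENT_TASK, training, derive_seed(seed, 2), modalities
    )
    priors = estimate_priors(train.diagnosis, train.management)

    diag_probs = predict_proba(diag_model, Xte)[DIAGNOSIS_TASK]
    pred_probs = predict_proba(mgmt_model, Xte)[MANAGEMENT_TASK]
    infr_probs = marginalize_management(diag_probs, priors)

    true_mgmt = test.management
    arm_pred = _evaluate_arm("MGMT_pred_all", pred_probs, true_mgmt, test.diagnosis)
    arm_infr = _evaluate_arm("MGMT_infr_all", infr_probs, true_mgmt, test.diagnosis)

    true_binary = collapse_management_to_binary(true_mgmt)
    infr_binary = map_diagnosis_to_binary(decide_label(diag_probs, tie_rule="first"))
    pred_binary = decide_label(collapse_management_to_binary(pred_probs), tie_rule="first")
    bin_pred = _binary_eval("MGMT_pred_binary", pred_binary, true_binary)
    bin_infr = _binary_eval("MGMT_infr_binary", infr_binary, true_binary)

    disc_pred_only = int((arm_pred["correct"] & ~arm_infr["correct"]).sum())
    disc_infr_only = int((arm_infr["correct"] & ~arm_pred["correct"]).sum())
    mcnemar = ag.mcnemar_mid_p(disc_infr_only, disc_pred_only)

    result = {
        "seed": seed,
        "accuracy_pred": arm_pred["accuracy"],
        "accuracy_infr": arm_infr["accuracy"],
        "accuracy_gap": arm_pred["accuracy"] - arm_infr["accuracy"],
        "binary_accuracy_pred": bin_pred["accuracy"],
        "binary_accuracy_infr": bin_infr["accuracy"],
        "over_excision_pred": arm_pred["over_excision"],
        "over_excision_infr": arm_infr["over_excision"],
        "malignancy_miss_pred": arm_pred["malignancy_miss"],
        "malignancy_miss_infr": arm_infr["malignancy_miss"],
        "mcnemar_pred_vs_infr": mcnemar.to_dict(),
        "arms": {
            "MGMT_pred_all": _arm_summary(arm_pred),
            "MGMT_infr_all": _arm_summary(arm_infr),
            "MGMT_pred_binary": {k: bin_pred[k] for k in ("accuracy", "mean_sensitivity", "confusion")},
            "MGMT_infr_binary": {k: bin_infr[k] for k in ("accuracy", "mean_sensitivity", "confusion")},
        },
        "priors": priors.table.tolist(),
    }
    if with_distances:
        targets = _onehot_targets(true_mgmt, space.n_management)
        result["distances"] = _compare_distances(
            pred_probs, infr_probs, targets, seed
        )
    return result


def three_fold_indices(management: np.ndarray, seed: int) -> list[np.ndarray]:
    """Three folds stratified by management label."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[], [], []]
    for m in np.unique(management):
        idx = rng.permutation(np.flatnonzero(management == m))
        for f, part in enumerate(np.array_split(idx, 3)):
            folds[f].extend(part.tolist())
    return [np.sort(np.asarray(f)) for f in folds]


def run_direct_vs_inferred(config: ExperimentConfig) -> dict:
    """The central comparison over all configured seeds (optionally with a
    management-stratified 3-fold cross-validation per seed)."""
    per_seed = []
    for seed in config.seeds:
        logger.info("direct-vs-inferred: seed %d", seed)
        if config.cv3:
            gen = replace(config.generator, seed=derive_seed(seed, 0))
            cohort = generate_exact_cohort(gen)
            folds = three_fold_indices(cohort.management, derive_seed(seed, 3))
            fold_results = []
            for f in range(3):
                test_idx = folds[f]
                train_idx = np.concatenate([folds[g] for g in range(3) if g != f])
                fold_results.append(
                    direct_vs_inferred_on_split(
                        cohort.subset(train_idx),
                        cohort.subset(test_idx),
                        config.training,
                        derive_seed(seed, 10 + f),
                        with_distances=False,
                    )
                )
            per_seed.append(
                {
                    "seed": seed,
                    "folds": fold_results,
                    "accuracy_pred": float(np.mean([r["accuracy_pred"] for r in fold_results])),
                    "accuracy_infr": float(np.mean([r["accuracy_infr"] for r in fold_results])),
                    "accuracy_gap": float(np.mean([r["accuracy_gap"] for r in fold_results])),
                }
            )
        else:
            per_seed.append(
                direct_vs_inferred_once(config.generator, config.training, seed)
            )
    gaps = np.array([r["accuracy_gap"] for r in per_seed])
    report = {
        "experiment": "direct_vs_inferred",
        "config": config_to_dict(config),
        "per_seed": per_seed,
        "mean_accuracy_pred": float(np.mean([r["accuracy_pred"] for r in per_seed])),
        "mean_accuracy_infr": float(np.mean([r["accuracy_infr"] for r in per_seed])),
        "mean_accuracy_gap": float(gaps.mean()),
        "positive_gap_seeds": int((gaps > 0).sum()),
        "n_seeds": len(config.seeds),
    }
    if not config.cv3:
        report["fewer_over_excision_seeds"] = int(
            sum(r["over_excision_pred"] < r["over_excision_infr"] for r in per_seed)
        )
    return report


def multitask_comparison_once(
    generator: GeneratorConfig, training: TrainingConfig, seed: int, modalities: str = "CDM"
) -> dict:
    """Single- versus 9-task management prediction on one generated cohort,
    plus the malignancy-miss comparison between the direct and inferred arms."""
    gen = replace(generator, seed=derive_seed(seed, 0))
    cohort = generate_exact_cohort(gen)
    train, test = cohort.split("train"), cohort.split("test")
    Xtr, Xte = design_matrix(train, modalities), design_matrix(test, modalities)

    targets = {f"criterion_{k}": train.criteria[:, k - 1] for k in range(1, 8)}
    targets[DIAGNOSIS_TASK] = train.diagnosis
    targets[MANAGEMENT_TASK] = train.management

    multi_cfg = replace(training, task_list=ALL_TASKS, seed=derive_seed(seed, 4))
    multi = train_model(Xtr, targets, multi_cfg, modalities=modalities)
    multi_probs = predict_proba(multi, Xte)

    single = _train_single(
        Xtr, train.management, MANAGEMENT_TASK, training, derive_seed(seed, 2), modalities
    )
    single_probs = predict_proba(single, Xte)[MANAGEMENT_TASK]

    priors = estimate_priors(train.diagnosis, train.management)
    infr_probs = marginalize_management(multi_probs[DIAGNOSIS_TASK], priors)

    arm_multi = _evaluate_arm(
        "MGMT_pred_multi", multi_probs[MANAGEMENT_TASK], test.management, test.diagnosis
    )
    arm_single = _evaluate_arm("MGMT_pred_single", single_probs, test.management, test.diagnosis)
    arm_infr = _evaluate_arm("MGMT_infr_multi", infr_probs, test.management, test.diagnosis)

    diag_decided = decide_label(multi_probs[DIAGNOSIS_TASK], tie_rule="first")
    diag_cm = confusion_matrix(test.diagnosis, diag_decided, DEFAULT_LABEL_SPACE.n_diagnosis)
    diag_metrics = classwise_metrics(
        diag_cm, auroc_one_vs_rest(test.diagnosis, multi_probs[DIAGNOSIS_TASK])
    )
    # diagnose-then-infer misses a malignant case when the predicted
    # diagnosis is benign (its binary-mapped management would be NOEXC)
    malignant = map_diagnosis_to_binary(test.diagnosis).astype(bool)
    miss_infr_binary = int((malignant & (map_diagnosis_to_binary(diag_decided) == 0)).sum())

    return {
        "seed": seed,
        "accuracy_multi": arm_multi["accuracy"],
        "accuracy_single": arm_single["accuracy"],
        "accuracy_infr": arm_infr["accuracy"],
        "malignancy_miss_pred": arm_multi["malignancy_miss"],
        "malignancy_miss_infr": miss_infr_binary,
        "malignancy_miss_infr_marginalized": arm_infr["malignancy_miss"],
        "diagnosis_accuracy_multi": diag_metrics.overall_accuracy,
        "arms": {
            "MGMT_pred_multi": _arm_summary(arm_multi),
            "MGMT_pred_single": _arm_summary(arm_single),
            "MGMT_infr_multi": _arm_summary(arm_infr),
        },
    }


def run_multitask_comparison(config: ExperimentConfig) -> dict:
    per_seed = [
        multitask_comparison_once(config.generator, config.training, s) for s in config.seeds
    ]
    multi = np.array([r["accuracy_multi"] for r in per_seed])
    single = np.array([r["accuracy_single"] for r in per_seed])
    return {
        "experiment": "multitask_comparison",
        "config": config_to_dict(config),
        "per_seed": per_seed,
        "mean_accuracy_multi": float(multi.mean()),
        "mean_accuracy_single": float(single.mean()),
        "mean_multi_minus_single": float((multi - single).mean()),
        "direct_fewer_malignancy_miss_seeds": int(
            sum(r["malignancy_miss_pred"] <= r["malignancy_miss_infr"] for r in per_seed)
        ),
        "n_seeds": len(config.seeds),
    }


def modality_ablation_once(
    generator: GeneratorConfig,
    training: TrainingConfig,
    seed: int,
    combos: tuple[str, ...] = MODALITY_COMBOS,
) -> dict:
    """Train one multi-task model per modality combination and compare the
    management predictions pairwise with the mid-p McNemar test."""
    gen = replace(generator, seed=derive_seed(seed, 0))
    cohort = generate_exact_cohort(gen)
    train, test = cohort.split("train"), cohort.split("test")
    targets = {f"criterion_{k}": train.criteria[:, k - 1] for k in range(1, 8)}
    targets[DIAGNOSIS_TASK] = train.diagnosis
    targets[MANAGEMENT_TASK] = train.management

    arms = {}
    correct = {}
    for i, combo in enumerate(combos):
        cfg = replace(training, task_list=ALL_TASKS, seed=derive_seed(seed, 20 + i))
        model = train_model(design_matrix(train, combo), targets, cfg, modalities=combo)
        probs = predict_proba(model, design_matrix(test, combo))[MANAGEMENT_TASK]
        arm = _evaluate_arm(combo, probs, test.management, test.diagnosis)
        arms[combo] = _arm_summary(arm)
        correct[combo] = arm["correct"]

    k = len(combos)
    grid = np.ones((k, k))
    for i, a in enumerate(combos):
        for j, b in enumerate(combos):
            if i < j:
                n01 = int((correct[a] & ~correct[b]).sum())
                n10 = int((~correct[a] & correct[b]).sum())
                p = ag.mcnemar_mid_p(n01, n10).p_value
                grid[i, j] = grid[j, i] = p
    return {
        "seed": seed,
        "combos": list(combos),
        "arms": arms,
        "accuracies": {c: arms[c]["overall_accuracy"] for c in combos},
        "mcnemar_grid": grid.tolist(),
    }


def run_modality_ablation(config: ExperimentConfig) -> dict:
    per_seed = [
        modality_ablation_once(config.generator, config.training, s, config.modalities)
        for s in config.seeds
    ]
    mean_acc = {
        c: float(np.mean([r["accuracies"][c] for r in per_seed])) for c in config.modalities
    }
    return {
        "experiment": "modality_ablation",
        "config": config_to_dict(config),
        "per_seed": per_seed,
        "mean_accuracies": mean_acc,
        "n_seeds": len(config.seeds),
    }


def run_panel_agreement(
    panel: RaterPanel,
    model_preds: np.ndarray,
    diag_truth_binary: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Agreement of binary model recommendations with a rater panel.

    Builds both reference labelings — the majority-vote aggregate
    (MGMT_GT_agg) and, when the true diagnoses are given, the malignancy
    mapping (MGMT_GT_true) — and computes the full kappa protocol suite.
    """
    model_preds = np.asarray(model_preds, dtype=np.int64)
    if model_preds.size != panel.n_cases:
        raise ValueError("model predictions must cover every panel case")
    gt_agg = ag.majority_vote(panel)
    pair_mean, pair_sd = ag.pairwise_cohen_summary(panel)
    loo_mean, loo_sd, loo_excluded = ag.loo_cohen_protocol(panel)
    loo_fleiss = ag.panel_model_fleiss(panel, model_preds, subset_size=None)
    sub_fleiss = ag.panel_model_fleiss(
        panel, model_preds, subset_size=min(9, panel.n_raters - 1), n_reps=1000, seed=seed
    )
    report = {
        "experiment": "panel_agreement",
        "n_raters": panel.n_raters,
        "n_cases": panel.n_cases,
        "accuracy_vs_gt_agg": float((model_preds == gt_agg).mean()),
        "cohen_kappa_model_vs_agg": ag.cohens_kappa(model_preds, gt_agg),
        "pairwise_cohen_mean": pair_mean,
        "pairwise_cohen_sd": pair_sd,
        "loo_cohen_mean": loo_mean,
        "loo_cohen_sd": loo_sd,
        "loo_cohen_excluded": loo_excluded,
        "panel_fleiss": ag.fleiss_kappa(panel),
        "panel_model_fleiss_loo_mean": loo_fleiss[0],
        "panel_model_fleiss_loo_sd": loo_fleiss[1],
        "panel_model_fleiss_9plus1_mean": sub_fleiss[0],
        "panel_model_fleiss_9plus1_sd": sub_fleiss[1],
    }
    if diag_truth_binary is not None:
        gt_true = np.asarray(diag_truth_binary, dtype=np.int64)
        report["accuracy_vs_gt_true"] = float((model_preds == gt_true).mean())
        report["cohen_kappa_model_vs_true"] = ag.cohens_kappa(model_preds, gt_true)
    return report


_MALIGNANT_TOKENS = {"mel", "melanoma", "malignant", "mlgn", "1"}
_BENIGN_TOKENS = {"nev", "nevus", "benign", "bngn", "0"}


def read_mclass_responses(
    responses_path: str | Path, truth_path: str | Path
) -> tuple[RaterPanel, np.ndarray]:
    """Read a rater-response benchmark: a rectangular CSV of binary
    recommendations (first column rater_id, one column per case id) and a
    two-column truth CSV (case_id, diagnosis), where the diagnosis is a
    melanoma/nevus (or malignant/benign) token mapped to 1/0."""
    try:
        panel = RaterPanel.from_csv(responses_path)
    except ValueError as err:
        raise ValueError(f"malformed response matrix {responses_path}: {err}") from err
    truth_df = pd.read_csv(truth_path)
    if truth_df.shape[1] < 2:
        raise ValueError(f"truth file {truth_path} needs case_id and diagnosis columns")
    truth_map = {}
    for lineno, row in enumerate(truth_df.itertuples(index=False), start=2):
        token = str(row[1]).strip().lower()
        if token in _MALIGNANT_TOKENS:
            truth_map[str(row[0])] = 1
        elif token in _BENIGN_TOKENS:
            truth_map[str(row[0])] = 0
        else:
            raise ValueError(f"{truth_path}:{lineno}: unknown diagnosis token {row[1]!r}")
    missing = [c for c in panel.case_ids if c not in truth_map]
    if missing:
        raise ValueError(f"truth file lacks cases {missing[:5]} (and possibly more)")
    truth = np.array([truth_map[c] for c in panel.case_ids], dtype=np.int64)
    return panel, truth


def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["generator"] = config.generator.to_dict()
    return d


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
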