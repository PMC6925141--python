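"""End-to-end orchestration of the two-level pipeline.

``run_pipeline`` executes the whole study in memory on a synthetic
cohort: generate phantoms, preprocess slices, train the slice-network
ensemble on the training set while monitoring the validation set,
aggregate validation slice probabilities into patient feature vectors,
fit the feature selector and random forest on validation patients, and
finally evaluate — per-member slice-level AUC and ensemble patient-level
AUC, each with a bootstrap CI — on the held-out test set only.

A single global seed fans out deterministically to the cohort generator,
the ensemble members, the selector/forest and the bootstrap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml

from . import aggregation, evaluation, preprocess, slice_model, synthetic
from .aggregation import (ProbabilitySetPair, extract_patient_features,
                          fit_feature_selector, fit_patient_classifier,
                          predict_patient)
from .slice_model import (ArchitectureConfig, SliceProbability,
                          TrainingConfig, predict_slices, train_ensemble)
from .synthetic import CohortSpec, tiny_cohort_spec

log = logging.getLogger("dwiprost")


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    n_cnns: int = 5
    top_k: int = aggregation.TOP_K
    cutoff: float = aggregation.PROBABILITY_CUTOFF
    n_boot: int = 2000
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cohort"]["composition"] = {k: list(v) for k, v in
                                      d["cohort"]["composition"].items()}
        for key in ("tumor_slices_per_pca_patient", "lesion_axes_px"):
            d["cohort"][key] = list(d["cohort"][key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cohort"]["composition"] = {k: tuple(v) for k, v in
                                      d["cohort"]["composition"].items()}
        for key in ("tumor_slices_per_pca_patient", "lesion_axes_px"):
            d["cohort"][key] = tuple(d["cohort"][key])
        return cls(cohort=CohortSpec(**d["cohort"]),
                   arch=ArchitectureConfig(**d["arch"]),
                   training=TrainingConfig(**d["training"]),
                   **{k: d[k] for k in ("n_cnns", "top_k", "cutoff", "n_boot", "seed")})


def tiny_config(seed: int = 0, max_epochs: int = 10) -> PipelineConfig:
    """The CPU-scale preset: <=40 patients, 8-layer network, 10 epochs.

    The reduced network trains with learning rate 0.01 and dropout 0.25:
    at this problem size the full-scale settings (lr 0.001, dropout 0.90)
    are tuned for a cohort two orders of magnitude larger.
    """
    return PipelineConfig(
        cohort=tiny_cohort_spec(seed=seed),
        arch=slice_model.reduced_architecture(dropout_rate=0.25),
        training=TrainingConfig(lr0=0.01, max_epochs=max_epochs, seed=seed),
        n_boot=500,
        seed=seed,
    )


def _group_slices(records: Sequence[dict], sets: Dict[str, str]):
    """Partition preprocessed slice records by set membership."""
    out = {"train": [], "validation": [], "test": []}
    for r in records:
        out[sets[r["patient_id"]]].append(r)
    return out


def patient_probability_pairs(
    slice_probs_per_member: Sequence[Sequence[SliceProbability]],
) -> Dict[str, List[ProbabilitySetPair]]:
    """Group each member's slice probabilities into per-patient (P, N) pairs."""
    pairs: Dict[str, List[ProbabilitySetPair]] = {}
    for k, member_probs in enumerate(slice_probs_per_member):
        by_pid: Dict[str, list] = {}
        for sp in member_probs:
            by_pid.setdefault(sp.patient_id, []).append(sp)
        for pid, sps in by_pid.items():
            pairs.setdefault(pid, []).append(
                aggregation.collect_probability_sets(sps, cnn_index=k))
    return pairs


def run_pipeline(config: PipelineConfig, permute_labels: bool = False,
                 n_null_permutations: int = 0) -> dict:
    """Run the full study on a synthetic cohort; returns a results dict.

    With ``permute_labels`` the patient labels used to train the
    selector/forest and to score the test set are randomly permuted
    (seeded) — a null control whose patient-level AUC should hover
    around 0.5. With ``n_null_permutations > 0`` the trained slice stage
    is kept and the patient-level stage is refitted that many times on
    permuted validation labels; the mean test AUC of these null fits is
    reported as ``null_patient_auc``.
    """
    t0 = time.time()
    cohort_spec = synthetic.CohortSpec(**{**asdict(config.cohort),
                                          "seed": config.seed})
    cohort_spec.composition = {k: tuple(v) for k, v in
                               config.cohort.composition.items()}
    studies, assignment = synthetic.generate_cohort(cohort_spec)
    log.info("cohort: %d patients, %d slices (%.1fs)", len(studies),
             sum(s.n_slices for s in studies), time.time() - t0)

    records, stats = preprocess.preprocess_cohort(studies)
    sets = assignment.assignment
    grouped = _group_slices(records, sets)
    stacks = {s: np.stack([r["stack"] for r in grouped[s]]) for s in grouped}
    labels = {s: np.array([r["label"] for r in grouped[s]]) for s in grouped}
    log.info("preprocessed: %s slices per set (%.1fs)",
             {s: len(v) for s, v in grouped.items()}, time.time() - t0)

    models, histories = train_ensemble(
        stacks["train"], labels["train"], stacks["validation"], labels["validation"],
        arch=config.arch, config=config.training,
        n_members=config.n_cnns, base_seed=config.seed + 100)
    log.info("ensemble trained (%.1fs)", time.time() - t0)

    member_probs = {}
    for part in ("validation", "test"):
        ids = [r["patient_id"] for r in grouped[part]]
        sidx = [r["slice_index"] for r in grouped[part]]
        member_probs[part] = [predict_slices(m, stacks[part], ids, sidx)
                              for m in models]

    patient_labels = {s.patient_id: s.patient_label for s in studies}
    rng = np.random.default_rng(config.seed + 999)
    if permute_labels:
        pids = sorted(patient_labels)
        permuted = rng.permutation([patient_labels[p] for p in pids])
        patient_labels = dict(zip(pids, (int(v) for v in permuted)))

    def features_of(part: str):
        pairs = patient_probability_pairs(member_probs[part])
        pids = sorted(pairs)
        mat = np.stack([
            extract_patient_features(pairs[p], n_cnns=config.n_cnns,
                                     k=config.top_k, cutoff=config.cutoff)
            for p in pids])
        y = np.array([patient_labels[p] for p in pids])
        return pids, mat, y

    val_ids, val_feats, val_y = features_of("validation")
    n_folds = min(10, int(np.bincount(val_y, minlength=2).min()))
    selected = fit_feature_selector(val_feats, val_y, n_folds=max(2, n_folds),
                                    seed=config.seed + 7)
    classifier = fit_patient_classifier(val_feats, val_y, selected=selected,
                                        n_folds=max(2, n_folds),
                                        seed=config.seed + 7)
    log.info("selector kept %d/%d features; forest %s (%.1fs)",
             selected.indices.size, val_feats.shape[1],
             classifier.cv_best_params, time.time() - t0)

    test_ids, test_feats, test_y = features_of("test")
    patient_scores = np.atleast_1d(predict_patient(classifier, test_feats))

    slice_y = labels["test"]
    slice_results = []
    for k in range(config.n_cnns):
        scores = np.array([sp.p for sp in member_probs["test"][k]])
        res = evaluation.evaluate(scores, slice_y, level="slice",
                                  n_boot=config.n_boot, seed=config.seed + 31 + k)
        slice_results.append(res)
    patient_result = evaluation.evaluate(patient_scores, test_y, level="patient",
                                         n_boot=config.n_boot, seed=config.seed + 63)

    null_aucs = []
    for b in range(n_null_permutations):
        y_perm = rng.permutation(val_y)
        while len(np.unique(y_perm)) < 2:  # pragma: no cover - both classes present
            y_perm = rng.permutation(val_y)
        sel_b = fit_feature_selector(val_feats, y_perm, n_folds=max(2, n_folds),
                                     seed=config.seed + 200 + b)
        clf_b = fit_patient_classifier(val_feats, y_perm, selected=sel_b,
                                       n_folds=max(2, n_folds),
                                       seed=config.seed + 200 + b)
        scores_b = np.atleast_1d(predict_patient(clf_b, test_feats))
        null_aucs.append(evaluation.roc_auc(scores_b, test_y).auc)
    log.info("evaluation done (%.1fs total)", time.time() - t0)
    return {
        "slice_auc": [r.auc for r in slice_results],
        "slice_ci": [(r.ci_low, r.ci_high) for r in slice_results],
        "patient_auc": patient_result.auc,
        "patient_ci": (patient_result.ci_low, patient_result.ci_high),
        "n_features": int(val_feats.shape[1]),
        "n_selected": int(selected.indices.size),
        "selected": selected,
        "classifier": classifier,
        "models": models,
        "histories": histories,
        "patient_scores": dict(zip(test_ids, patient_scores.tolist())),
        "test_patient_labels": dict(zip(test_ids, test_y.tolist())),
        "norm_stats": stats,
        "null_patient_auc": float(np.mean(null_aucs)) if null_aucs else None,
        "null_patient_aucs": null_aucs,
        "runtime_s": time.time() - t0,
    }
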