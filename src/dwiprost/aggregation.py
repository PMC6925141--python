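"""Slice-to-patient aggregation: probability filtering, first-order
statistics, feature selection and the patient-level random forest.

Each of the five slice networks emits, for every slice ``j`` of a patient,
a PCa probability ``p_ij`` and its complement ``n_ij``. Per network the
two probability sets are filtered — keep at most the top five values
above the 0.74 cutoff (grid-searched on the validation set in the
original study) — and summarized by nine first-order statistics each:
mean, standard deviation, variance, median, sum, maximum (PCa set only)
or minimum (non-PCa set only), skewness, kurtosis, and range. Five
networks x two sets x nine statistics = 90 features per patient. A
decision-tree feature selector (importances aggregated over 10-fold CV)
prunes the vector, and a random forest trained on the validation
patients produces the patient-level PCa probability.

Statistic conventions: population moments (divide by n), Fisher-Pearson
skewness ``m3 / m2^1.5``, Fisher (excess) kurtosis ``m4 / m2^2 - 3``;
constant sets define both as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

PROBABILITY_CUTOFF = 0.74
TOP_K = 5
N_CNNS = 5
STAT_NAMES_PCA = ("mean", "std", "var", "median", "sum", "max", "skew", "kurt", "range")
STAT_NAMES_NON = ("mean", "std", "var", "median", "sum", "min", "skew", "kurt", "range")


@dataclass
class ProbabilitySetPair:
    """Per-patient slice probabilities from one ensemble member."""

    cnn_index: int
    patient_id: str
    P: np.ndarray  # PCa probabilities, ordered by slice index
    N: np.ndarray  # non-PCa probabilities (complements)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.P.size == 0 or self.P.shape != self.N.shape:
            raise ValueError("P and N must be nonempty and equally sized")
        if np.any((self.P < 0) | (self.P > 1)) or np.any((self.N < 0) | (self.N > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.max(np.abs(self.P + self.N - 1.0)) > 1e-6:
            raise ValueError("p + n must equal 1 within 1e-6")


def collect_probability_sets(slice_probs, cnn_index: int = 0) -> ProbabilitySetPair:
    """Build the (P, N) pair from one network's SliceProbability records."""
    records = sorted(slice_probs, key=lambda s: s.slice_index)
    if not records:
        raise ValueError("no slice probabilities supplied")
    pid = records[0].patient_id
    return ProbabilitySetPair(
        cnn_index=cnn_index,
        patient_id=pid,
        P=np.array([r.p for r in records]),
        N=np.array([r.n for r in records]),
    )


def filter_top_k(
    probs: np.ndarray, k: int = TOP_K, cutoff: float = PROBABILITY_CUTOFF
) -> np.ndarray:
    """Keep the top ``k`` probabilities strictly above ``cutoff``.

    Returned sorted descending. If no value exceeds the cutoff the single
    maximum is retained so the downstream statistics stay defined.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability set")
    kept = np.sort(probs[probs > cutoff])[::-1][:k]
    if kept.size == 0:
        kept = np.array([probs.max()])
    return kept


def _moments(x: np.ndarray) -> Tuple[float, float, float, float]:
    m = x.mean()
    d = x - m
    m2 = float((d**2).mean())
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    return m, m2, m3, m4


def first_order_features(p_set: np.ndarray, n_set: np.ndarray) -> np.ndarray:
    """The 18 first-order statistics of one network's filtered sets.

    Nine from the PCa set (with maximum as the extremum) followed by nine
    from the non-PCa set (with minimum).
    """
    out = []
    for x, use_max in ((np.asarray(p_set, float), True), (np.asarray(n_set, float), False)):
        if x.size == 0:
            raise ValueError("empty probability set")
        m, m2, m3, m4 = _moments(x)
        # sets that are constant up to rounding count as zero-variance
        degenerate = m2 <= 1e-12
        skew = m3 / m2**1.5 if not degenerate else 0.0
        kurt = m4 / m2**2 - 3.0 if not degenerate else 0.0
        extremum = x.max() if use_max else x.min()
        out.extend([m, np.sqrt(m2), m2, float(np.median(x)), float(x.sum()),
                    float(extremum), skew, kurt, float(x.max() - x.min())])
    return np.array(out)


def feature_names(n_cnns: int = N_CNNS) -> List[str]:
    names = []
    for i in range(1, n_cnns + 1):
        names += [f"cnn{i}_pca_{s}" for s in STAT_NAMES_PCA]
        names += [f"cnn{i}_non_{s}" for s in STAT_NAMES_NON]
    return names


def extract_patient_features(
    set_pairs: Sequence[ProbabilitySetPair],
    n_cnns: int = N_CNNS,
    k: int = TOP_K,
    cutoff: float = PROBABILITY_CUTOFF,
) -> np.ndarray:
    """Concatenate the per-network 18-feature blocks of one patient.

    ``set_pairs`` must contain exactly one pair per ensemble member;
    blocks are ordered by ``cnn_index``. Length is ``18 * n_cnns`` (90 for
    the five-member ensemble).
    """
    by_cnn = {sp.cnn_index: sp for sp in set_pairs}
    if sorted(by_cnn) != list(range(n_cnns)):
        raise ValueError(
            f"need exactly one probability-set pair per member 0..{n_cnns - 1}, "
            f"got indices {sorted(by_cnn)}"
        )
    blocks = []
    for i in range(n_cnns):
        sp = by_cnn[i]
        blocks.append(first_order_features(filter_top_k(sp.P, k, cutoff),
                                           filter_top_k(sp.N, k, cutoff)))
    return np.concatenate(blocks)


@dataclass
class SelectedFeatures:
    """Indices retained by the decision-tree selector, with importances."""

    indices: np.ndarray
    importances: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.importances = np.asarray(self.importances, dtype=float)
        if self.indices.size == 0:
            raise ValueError("at least one feature must be retained")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("duplicate feature indices")


def fit_feature_selector(
    features: np.ndarray,
    labels: Sequence[int],
    n_folds: int = 10,
    seed: int = 0,
    n_keep: Optional[int] = None,
) -> SelectedFeatures:
    """Decision-tree feature selection with importances aggregated over CV.

    A depth-limited decision tree is fitted on each of ``n_folds``
    stratified training folds; Gini importances are averaged across
    folds. Features are retained above the mean nonzero importance (the
    usual "above average importance" rule), or — with ``n_keep`` — the
    top ``n_keep`` by aggregate importance. Falls back to the single
    best-ranked feature if nothing clears the threshold.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs both classes present")
    if n_folds > len(y):
        raise ValueError(f"n_folds={n_folds} exceeds the {len(y)} patients")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    agg = np.zeros(x.shape[1])
    for fold_idx, (tr, _) in enumerate(skf.split(x, y)):
        tree = DecisionTreeClassifier(max_depth=5, random_state=seed + fold_idx)
        tree.fit(x[tr], y[tr])
        agg += tree.feature_importances_
    agg /= n_folds
    if n_keep is not None:
        order = np.argsort(agg)[::-1][:n_keep]
    else:
        nonzero = agg[agg > 0]
        thr = nonzero.mean() if nonzero.size else np.inf
        order = np.flatnonzero(agg >= thr)
        order = order[np.argsort(agg[order])[::-1]]
        if order.size == 0:
            order = np.array([int(np.argmax(agg))])
    return SelectedFeatures(indices=order, importances=agg[order])


@dataclass
class PatientClassifier:
    """Fitted random forest over the selected feature subspace."""

    forest: RandomForestClassifier
    selected: SelectedFeatures
    cv_best_params: Dict


def fit_patient_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    selected: Optional[SelectedFeatures] = None,
    n_folds: int = 10,
    seed: int = 0,
) -> PatientClassifier:
    """Random forest on the selected features, tuned by stratified CV.

    The grid is deliberately small ({100, 300} trees x depth {3, 5,
    unlimited}) — with ~48 validation patients anything larger overfits
    the tuning itself.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("patient classifier needs both classes present")
    if selected is None:
        selected = SelectedFeatures(indices=np.arange(x.shape[1]),
                                    importances=np.ones(x.shape[1]))
    xs = x[:, selected.indices]
    n_folds_eff = min(n_folds, int(np.bincount(y).min()))
    grid = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        {"n_estimators": [100, 300], "max_depth": [3, 5, None]},
        cv=StratifiedKFold(n_splits=max(2, n_folds_eff), shuffle=True, random_state=seed),
        scoring="roc_auc",
    )
    grid.fit(xs, y)
    return PatientClassifier(forest=grid.best_estimator_, selected=selected,
                             cv_best_params=dict(grid.best_params_))


def predict_patient(classifier: PatientClassifier, features: np.ndarray) -> np.ndarray:
    """PCa probability for one feature vector or a matrix of them."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] == classifier.selected.indices.size:
        xs = x
    else:
        if x.shape[1] <= classifier.selected.indices.max():
            raise ValueError(
                f"feature vector of length {x.shape[1]} cannot be indexed by the "
                f"selected features (max index {classifier.selected.indices.max()})"
            )
        xs = x[:, classifier.selected.indices]
    probs = classifier.forest.predict_proba(xs)[:, 1]
    return probs if probs.size > 1 else float(probs[0])


def features_to_frame(
    patient_ids: Sequence[str], matrix: np.ndarray, n_cnns: int = N_CNNS
) -> pd.DataFrame:
    """Named feature table (columns cnn{i}_{class}_{stat})."""
    df = pd.DataFrame(np.atleast_2d(matrix), columns=feature_names(n_cnns))
    df.insert(0, "patient_id", list(patient_ids))
    return df
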