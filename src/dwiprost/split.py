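"""Patient-disjoint, label-stratified train/validation/test partitioning.

The split is two-stage: first the cohort is divided into a combined
training/validation pool (75%) and a held-out test set (25%); the pool is
then divided into training (85%) and validation (15%). Both stages operate
within each label stratum independently so the PCa / non-PCa mix of every
set stays close to the cohort's. Patients are the unit of assignment: all
slices of a patient travel together, so no slice-level leakage can occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

SETS = ("train", "validation", "test")

DEFAULT_RATIOS = (0.75, 0.85)  # outer pool fraction, inner train fraction


@dataclass
class SplitAssignment:
    """Mapping patient_id -> set name, plus the seed that produced it."""

    assignment: Dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        bad = {s for s in self.assignment.values()} - set(SETS)
        if bad:
            raise ValueError(f"unknown set names: {bad}")

    def patients_in(self, set_name: str) -> List[str]:
        return [p for p, s in self.assignment.items() if s == set_name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.assignment), "set": list(self.assignment.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = -1) -> "SplitAssignment":
        return cls(dict(zip(df["patient_id"].astype(str), df["set"])), seed)


def _split_stratum(ids: List[str], frac: float, rng: np.random.Generator) -> Tuple[List[str], List[str]]:
    """Shuffle then split one stratum; the first side gets round(frac*n)."""
    ids = list(ids)
    rng.shuffle(ids)
    k = int(round(frac * len(ids)))
    return ids[:k], ids[k:]


def stratified_patient_split(
    patients: Sequence[Tuple[str, int]],
    ratios: Tuple[float, float] = DEFAULT_RATIOS,
    seed: int = 0,
) -> SplitAssignment:
    """Two-stage stratified split of (patient_id, label) pairs.

    Within each label stratum the train/validation pool receives
    ``round(ratios[0] * n)`` patients and the test set the remainder; the
    pool is then split again per stratum with ``ratios[1]`` going to
    training. Raises if either label class is empty.
    """
    outer, inner = ratios
    if not (0 < outer < 1 and 0 < inner < 1):
        raise ValueError("ratios must lie strictly between 0 and 1")
    labels = {int(lab) for _, lab in patients}
    if labels != {0, 1}:
        raise ValueError("need at least one patient in each label class")
    pairs = [(str(p), int(lab)) for p, lab in patients]
    ids = [p for p, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, str] = {}
    for lab in (0, 1):
        stratum = sorted(p for p, l in pairs if l == lab)
        pool, test = _split_stratum(stratum, outer, rng)
        train, val = _split_stratum(pool, inner, rng)
        for p in train:
            assignment[p] = "train"
        for p in val:
            assignment[p] = "validation"
        for p in test:
            assignment[p] = "test"
    return SplitAssignment(assignment, seed)


def summarize_split(assignment: SplitAssignment, studies: Iterable) -> pd.DataFrame:
    """Per-set patient and slice counts by label.

    Returns a 3x4 table (rows train/validation/test) with columns
    ``pca_patients``, ``non_pca_patients``, ``tumor_slices``,
    ``non_tumor_slices``. Only slices inside the prostate range are counted.
    """
    studies = list(studies)
    known = set(assignment.assignment)
    for st in studies:
        if st.patient_id not in known:
            raise ValueError(f"patient {st.patient_id} not covered by the assignment")
    table = pd.DataFrame(
        0,
        index=list(SETS),
        columns=["pca_patients", "non_pca_patients", "tumor_slices", "non_tumor_slices"],
    )
    for st in studies:
        s = assignment.assignment[st.patient_id]
        table.loc[s, "pca_patients" if st.patient_label else "non_pca_patients"] += 1
        lo, hi = st.prostate_range
        labs = st.slice_labels[lo : hi + 1]
        table.loc[s, "tumor_slices"] += int(sum(labs))
        table.loc[s, "non_tumor_slices"] += int(len(labs) - sum(labs))
    return table
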