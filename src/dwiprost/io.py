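"""Disk formats: NIfTI volumes, cohort manifests, preprocessed stacks.

A cohort on disk is one NIfTI volume per b-value per patient (shape
H x W x n_slices) plus a manifest CSV with columns ``patient_id``,
``path_b0``, ``path_b100``, ``path_b400``, ``path_b1000``,
``patient_label``, ``slice_labels`` (semicolon-separated 0/1),
``prostate_first``, ``prostate_last``. Preprocessed slices are stored as
66x66x6 NIfTI files alongside a JSON sidecar holding the normalization
statistics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import ACQUIRED_B_VALUES, DWIStudy, NormalizationStats
from .split import SplitAssignment


def write_cohort(studies: Sequence[DWIStudy], out_dir, assignment: SplitAssignment | None = None) -> Path:
    """Write NIfTI volumes + manifest.csv (+ split.csv); returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "nifti").mkdir(parents=True, exist_ok=True)
    rows = []
    for st in studies:
        row = {"patient_id": st.patient_id}
        for b in ACQUIRED_B_VALUES:
            vol = np.stack([sl[b] for sl in st.slices], axis=-1).astype(np.float32)
            path = out_dir / "nifti" / f"{st.patient_id}_b{b}.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), path)
            row[f"path_b{b}"] = str(path.relative_to(out_dir))
        row["patient_label"] = st.patient_label
        row["slice_labels"] = ";".join(str(int(v)) for v in st.slice_labels)
        row["prostate_first"], row["prostate_last"] = st.prostate_range
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if assignment is not None:
        assignment.to_frame().to_csv(out_dir / "split.csv", index=False)
    return manifest


def read_cohort(manifest_path) -> List[DWIStudy]:
    """Load a cohort from its manifest CSV."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    studies = []
    for _, row in df.iterrows():
        vols = {b: np.asanyarray(nib.load(root / row[f"path_b{b}"]).dataobj)
                for b in ACQUIRED_B_VALUES}
        n_slices = next(iter(vols.values())).shape[-1]
        slices = [{b: np.asarray(vols[b][..., j], dtype=float) for b in vols}
                  for j in range(n_slices)]
        studies.append(DWIStudy(
            patient_id=str(row["patient_id"]),
            slices=slices,
            prostate_range=(int(row["prostate_first"]), int(row["prostate_last"])),
            patient_label=int(row["patient_label"]),
            slice_labels=[int(v) for v in str(row["slice_labels"]).split(";")],
        ))
    return studies


def write_preprocessed(records: Sequence[dict], stats: NormalizationStats,
                       sets: dict, out_dir) -> Path:
    """Persist normalized stacks as NIfTI + stats sidecar + slice index CSV."""
    out_dir = Path(out_dir)
    (out_dir / "stacks").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        name = f"{r['patient_id']}_s{r['slice_index']:03d}.nii.gz"
        nib.save(nib.Nifti1Image(r["stack"].astype(np.float32), affine=np.eye(4)),
                 out_dir / "stacks" / name)
        rows.append({"patient_id": r["patient_id"], "slice_index": r["slice_index"],
                     "label": r["label"], "set": sets[r["patient_id"]],
                     "path": f"stacks/{name}"})
    with open(out_dir / "norm_stats.json", "w") as fh:
        json.dump(stats.to_dict(), fh, indent=1)
    index = out_dir / "slices.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def read_preprocessed(index_path) -> Tuple[pd.DataFrame, NormalizationStats]:
    """Load the slice index and stats; stacks are loaded lazily by path."""
    index_path = Path(index_path)
    df = pd.read_csv(index_path)
    with open(index_path.parent / "norm_stats.json") as fh:
        stats = NormalizationStats.from_dict(json.load(fh))
    return df, stats


def load_stacks(index: pd.DataFrame, root) -> np.ndarray:
    root = Path(root)
    return np.stack([np.asanyarray(nib.load(root / p).dataobj).astype(float)
                     for p in index["path"]])
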