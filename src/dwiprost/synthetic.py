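"""Seed-deterministic synthetic phantom cohorts.

Two simulators back the pipeline at desk scale:

* :func:`generate_cohort` builds whole multi-b-value DWI cohorts of
  phantom patients. Per (set x label) patient and slice counts are
  specified exactly — the default composition is the 427-patient cohort
  (175 PCa / 252 non-PCa, 5,832 slices) with its published per-set
  breakdown — and reproduced by construction. Each slice follows a
  mono-exponential diffusion decay ``S(b) = S0 * exp(-b * ADC)`` with
  multiplicative Gaussian noise; tumor slices of PCa patients carry an
  elliptical lesion of reduced ADC (restricted diffusion: darker on the
  ADC map, brighter at high b relative to background).

* :func:`simulate_probability_sets` skips the imaging entirely and draws
  slice probabilities directly from per-class beta distributions with
  per-network jitter, standing in for trained network outputs when the
  aggregation stage is exercised in isolation.

The phantoms are deliberately simple: no prostate anatomy, no Rician
noise, no scanner artifacts. What they guarantee is exact bookkeeping
and a known ground truth (ADC fields, lesion masks, labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import ACQUIRED_B_VALUES, CROP_TO, RESIZE_TO, DWIStudy
from .split import SplitAssignment

#: Fraction of the image kept by the downstream center crop; lesions are
#: placed fully inside this window (the crop is defined to cover the
#: prostate, so a phantom lesion must not fall outside it).
_CROP_LO_FRAC = (RESIZE_TO - CROP_TO) / 2 / RESIZE_TO
_CROP_HI_FRAC = 1.0 - _CROP_LO_FRAC

#: Published per-set composition of the 427-patient cohort:
#: (PCa patients, non-PCa patients, tumor slices, non-tumor slices).
TABLE1_COMPOSITION: Dict[str, Tuple[int, int, int, int]] = {
    "train": (105, 166, 439, 3253),
    "validation": (18, 30, 66, 588),
    "test": (52, 56, 226, 1260),
}


@dataclass
class CohortSpec:
    """Counts, phantom physics and noise of a synthetic cohort.

    ``composition`` maps set name -> (pca_patients, non_pca_patients,
    tumor_slices, non_tumor_slices); defaults to the published cohort.
    ADC units are mm^2/s, b-values s/mm^2, intensities arbitrary units.
    """

    composition: Dict[str, Tuple[int, int, int, int]] = field(
        default_factory=lambda: {k: v for k, v in TABLE1_COMPOSITION.items()})
    tumor_slices_per_pca_patient: Tuple[int, int] = (1, 6)
    min_non_tumor_slices: int = 4
    image_size: int = 64
    s0_background: float = 1000.0
    s0_patient_sd: float = 50.0
    adc_background: float = 1.5e-3
    adc_patient_sd: float = 1.0e-4
    lesion_adc_factor: float = 0.5
    lesion_axes_px: Tuple[int, int] = (3, 8)
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tumor_slices_per_pca_patient
        if lo < 1 or hi < lo:
            raise ValueError("tumor-slice range must satisfy 1 <= lo <= hi")
        if not 0 < self.lesion_adc_factor < 1:
            raise ValueError("lesion_adc_factor must be in (0, 1)")
        for s, (pp, np_, ts, ns) in self.composition.items():
            if min(pp, np_, ts, ns) < 0:
                raise ValueError(f"negative count in set {s!r}")


def tiny_cohort_spec(seed: int = 0) -> CohortSpec:
    """A <=40-patient preset that runs the full pipeline in minutes on a CPU."""
    return CohortSpec(
        composition={
            "train": (8, 8, 20, 76),
            "validation": (6, 6, 14, 50),
            "test": (6, 6, 14, 50),
        },
        image_size=64,
        seed=seed,
    )


def _partition_counts(total: int, n: int, lo: int, hi: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into n integers, each in [lo, hi], summing exactly."""
    if not (n * lo <= total <= n * hi):
        raise ValueError(
            f"cannot split {total} slices over {n} patients with per-patient "
            f"range [{lo}, {hi}]"
        )
    counts = np.full(n, lo, dtype=int)
    remaining = total - n * lo
    while remaining > 0:
        room = hi - counts
        open_idx = np.flatnonzero(room > 0)
        add = rng.multinomial(remaining, np.full(open_idx.size, 1.0 / open_idx.size))
        add = np.minimum(add, room[open_idx])
        counts[open_idx] += add
        remaining -= int(add.sum())
    return counts


def _draw_lesion_geometry(spec: CohortSpec, rng: np.random.Generator):
    """Ellipse (cy, cx, a, b) contained in the crop window's preimage."""
    sz = spec.image_size
    a = int(rng.integers(spec.lesion_axes_px[0], spec.lesion_axes_px[1] + 1))
    b = int(rng.integers(spec.lesion_axes_px[0], spec.lesion_axes_px[1] + 1))
    lo_y = max(int(np.ceil(sz * _CROP_LO_FRAC)) + a, 0)
    hi_y = min(int(sz * _CROP_HI_FRAC) - a, sz - 1)
    lo_x = max(int(np.ceil(sz * _CROP_LO_FRAC)) + b, 0)
    hi_x = min(int(sz * _CROP_HI_FRAC) - b, sz - 1)
    cy = int(rng.integers(lo_y, max(hi_y, lo_y + 1)))
    cx = int(rng.integers(lo_x, max(hi_x, lo_x + 1)))
    return cy, cx, a, b


def generate_phantom_slice(
    has_tumor: bool,
    spec: CohortSpec,
    rng: np.random.Generator,
    s0: Optional[float] = None,
    adc_bg: Optional[float] = None,
    lesion: Optional[tuple] = None,
) -> Tuple[Dict[int, np.ndarray], np.ndarray]:
    """One phantom slice: per-b-value images plus the lesion ground-truth mask.

    Background follows ``S(b) = S0 * exp(-b * ADC_bg)``; a tumor slice
    replaces ADC inside an axis-aligned ellipse by
    ``lesion_adc_factor * ADC_bg``. Multiplicative Gaussian noise of
    relative width ``noise_sigma`` is applied independently per b-value.
    """
    sz = spec.image_size
    s0 = spec.s0_background if s0 is None else s0
    adc_bg = spec.adc_background if adc_bg is None else adc_bg
    adc_map = np.full((sz, sz), adc_bg)
    mask = np.zeros((sz, sz), dtype=bool)
    if has_tumor:
        if lesion is None:
            cy, cx, a, b = _draw_lesion_geometry(spec, rng)
        else:
            cy, cx, a, b = lesion
        yy, xx = np.ogrid[:sz, :sz]
        mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        adc_map[mask] = spec.lesion_adc_factor * adc_bg
    images = {}
    for b_val in ACQUIRED_B_VALUES:
        clean = s0 * np.exp(-b_val * adc_map)
        if spec.noise_sigma > 0:
            clean = clean * (1.0 + spec.noise_sigma * rng.standard_normal((sz, sz)))
        images[b_val] = np.maximum(clean, 1e-6).astype(np.float32)
    return images, mask


def generate_cohort(spec: CohortSpec) -> Tuple[List[DWIStudy], SplitAssignment]:
    """Generate a full cohort matching the spec's counts exactly.

    Every PCa patient receives a contiguous block of tumor slices (count
    within ``tumor_slices_per_pca_patient``); non-tumor slice totals are
    distributed over all patients of the set with at least
    ``min_non_tumor_slices`` each. All randomness flows from the single
    spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    studies: List[DWIStudy] = []
    assignment: Dict[str, str] = {}
    t_lo, t_hi = spec.tumor_slices_per_pca_patient
    for set_name, (n_pca, n_non, tumor_total, non_total) in spec.composition.items():
        n_pat = n_pca + n_non
        if n_pat == 0:
            continue
        tumor_counts = (_partition_counts(tumor_total, n_pca, t_lo, t_hi, rng)
                        if n_pca else np.zeros(0, dtype=int))
        non_counts = _partition_counts(
            non_total, n_pat, spec.min_non_tumor_slices, non_total, rng)
        for i in range(n_pat):
            is_pca = i < n_pca
            pid = f"{set_name}_{'pca' if is_pca else 'non'}_{i:04d}"
            n_tumor = int(tumor_counts[i]) if is_pca else 0
            n_slices = n_tumor + int(non_counts[i])
            labels = np.zeros(n_slices, dtype=int)
            if n_tumor:
                start = int(rng.integers(0, n_slices - n_tumor + 1))
                labels[start : start + n_tumor] = 1
            s0 = spec.s0_background + spec.s0_patient_sd * rng.standard_normal()
            adc = abs(spec.adc_background + spec.adc_patient_sd * rng.standard_normal())
            # one lesion geometry per patient, shared by its tumor slices
            cy, cx, a, b = _draw_lesion_geometry(spec, rng)
            slices = []
            for lab in labels:
                images, _ = generate_phantom_slice(
                    bool(lab), spec, rng, s0=s0, adc_bg=adc, lesion=(cy, cx, a, b))
                slices.append(images)
            studies.append(DWIStudy(
                patient_id=pid, slices=slices,
                prostate_range=(0, n_slices - 1),
                patient_label=int(is_pca),
                slice_labels=labels.tolist(),
            ))
            assignment[pid] = set_name
    return studies, SplitAssignment(assignment, spec.seed)


@dataclass
class ProbabilitySimSpec:
    """Beta-distribution stand-in for trained-network slice probabilities."""

    a_hi: float = 8.0   # tumor slices: Beta(8, 2), mean 0.8
    b_hi: float = 2.0
    a_lo: float = 2.0   # non-tumor slices: Beta(2, 8), mean 0.2
    b_lo: float = 8.0
    jitter: float = 0.05  # per-network Gaussian sd added to the base draw
    seed: int = 0

    def __post_init__(self):
        if min(self.a_hi, self.b_hi, self.a_lo, self.b_lo) <= 0:
            raise ValueError("beta parameters must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")


def simulate_probability_sets(
    cohort: Sequence[Tuple[str, Sequence[int]]],
    spec: ProbabilitySimSpec,
    n_cnns: int = 5,
) -> pd.DataFrame:
    """Draw per-network slice probabilities for labelled slices.

    ``cohort`` is a sequence of (patient_id, slice_labels). Each slice
    gets one base probability draw (high beta for tumor slices, low beta
    otherwise); each network sees that draw plus independent Gaussian
    jitter, clipped to (0, 1). Returns a frame with columns patient_id,
    slice_index, cnn_index, p, n.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    eps = 1e-6
    for pid, labels in cohort:
        labels = np.asarray(labels, dtype=int)
        base = np.where(
            labels == 1,
            rng.beta(spec.a_hi, spec.b_hi, size=labels.size),
            rng.beta(spec.a_lo, spec.b_lo, size=labels.size),
        )
        for k in range(n_cnns):
            p = base + (spec.jitter * rng.standard_normal(labels.size)
                        if spec.jitter > 0 else 0.0)
            p = np.clip(p, eps, 1 - eps)
            for j in range(labels.size):
                rows.append((str(pid), j, k, float(p[j]), float(1 - p[j])))
    return pd.DataFrame(rows, columns=["patient_id", "slice_index", "cnn_index", "p", "n"])
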