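"""Preprocessing of multi-b-value DWI slices into normalized model inputs.

A patient study holds one 2D image per b-value per slice. Preprocessing
turns each slice into a 66x66x6 channel stack:

1. fit a mono-exponential decay ``S(b) = S0 * exp(-b * ADC)`` per pixel by
   log-linear least squares over the acquired b-values, giving an ADC map
   (mm^2/s) and a fitted ``S0``;
2. extrapolate the computed high-b-value image ``b1600 = S0 * exp(-1600*ADC)``;
3. resize every channel to 144x144 (bilinear) and center-crop to 66x66;
4. stack channels in the fixed order (ADC, b0, b100, b400, b1000, b1600);
5. z-score each channel with statistics computed over the whole dataset.

Normalization is per channel: ADC values (~1e-3 mm^2/s) and raw signal
intensities (~1e3 a.u.) differ by six orders of magnitude, so a single
global mean/std would leave the ADC channel numerically invisible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _skimage_resize

#: Acquired diffusion weightings, s/mm^2.
ACQUIRED_B_VALUES: Tuple[int, ...] = (0, 100, 400, 1000)

#: Extrapolation target for the computed high-b-value image, s/mm^2.
B_TARGET: int = 1600

#: Fixed channel order of a model-input stack.
CHANNEL_ORDER: Tuple[str, ...] = ("ADC", "b0", "b100", "b400", "b1000", "b1600")

#: Spatial sizes: slices are resized to RESIZE_TO then cropped to CROP_TO.
RESIZE_TO: int = 144
CROP_TO: int = 66

#: Intensity floor applied before taking logarithms.
SIGNAL_FLOOR: float = 1e-6


@dataclass
class DWIStudy:
    """One patient's multi-b-value DWI stack with labels.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    slices : list of dict
        Ordered per-slice images; each maps b-value (s/mm^2) to a 2D array.
    prostate_range : (int, int)
        Inclusive first/last slice index containing prostate.
    patient_label : int
        1 for clinically significant PCa (Gleason >= 7, grade group >= 2),
        0 otherwise.
    slice_labels : list of int
        Per-slice tumor indicator; all zero for a non-PCa patient.
    """

    patient_id: str
    slices: List[Dict[int, np.ndarray]]
    prostate_range: Tuple[int, int]
    patient_label: int
    slice_labels: List[int]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("study must contain at least one slice")
        shapes = {img.shape for sl in self.slices for img in sl.values()}
        if len(shapes) != 1:
            raise ValueError(f"all slice images must share one shape, got {shapes}")
        missing = set(ACQUIRED_B_VALUES) - set(self.slices[0])
        if missing:
            raise ValueError(f"missing acquired b-values: {sorted(missing)}")
        lo, hi = self.prostate_range
        if not (0 <= lo <= hi < len(self.slices)):
            raise ValueError(f"prostate_range {self.prostate_range} outside slice range")
        if len(self.slice_labels) != len(self.slices):
            raise ValueError("slice_labels length must match slice count")
        if self.patient_label == 0 and any(self.slice_labels):
            raise ValueError("non-PCa patient cannot carry tumor slice labels")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class NormalizationStats:
    """Per-channel mean and standard deviation used for z-scoring."""

    mu: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mu.shape != self.std.shape:
            raise ValueError("mu and std must have identical shape")
        if np.any(self.std <= 0):
            raise ValueError("std must be strictly positive in every channel")

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "std": self.std.tolist(),
                "channels": list(CHANNEL_ORDER)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationStats":
        return cls(mu=np.asarray(d["mu"]), std=np.asarray(d["std"]))


def fit_adc(
    signals: Mapping[int, np.ndarray] | Mapping[float, np.ndarray],
    return_s0: bool = False,
):
    """Per-pixel mono-exponential ADC fit by log-linear least squares.

    Fits ``ln S = ln S0 - b * ADC`` through the ``(b, ln S)`` points of every
    pixel and returns the negative slope, floored at zero (free water cannot
    have negative diffusivity; negative slopes only arise from noise).

    Parameters
    ----------
    signals : mapping
        b-value (s/mm^2) -> 2D intensity image. At least two b-values.
    return_s0 : bool
        Also return the fitted intercept image ``S0 = exp(intercept)``.

    Returns
    -------
    adc : ndarray
        ADC map in mm^2/s, same shape as the inputs, >= 0.
    s0 : ndarray, optional
        Fitted S0 image (only if ``return_s0``).
    """
    if len(signals) < 2:
        raise ValueError("ADC fit requires at least two b-values")
    bvals = np.array(sorted(signals), dtype=float)
    stack = np.stack([np.asarray(signals[b], dtype=float) for b in sorted(signals)])
    logs = np.log(np.maximum(stack, SIGNAL_FLOOR))
    # closed-form simple linear regression, vectorized over pixels
    b_mean = bvals.mean()
    y_mean = logs.mean(axis=0)
    b_center = bvals - b_mean
    slope = np.tensordot(b_center, logs, axes=(0, 0)) / np.sum(b_center**2)
    adc = np.maximum(-slope, 0.0)
    if return_s0:
        s0 = np.exp(y_mean - slope * b_mean)  # intercept of the log-linear fit
        return adc, s0
    return adc


def extrapolate_high_b(
    s0: np.ndarray, adc: np.ndarray, b_target: float = B_TARGET
) -> np.ndarray:
    """Computed high-b-value image ``S = S0 * exp(-b_target * ADC)``."""
    if b_target < 0:
        raise ValueError("b_target must be nonnegative")
    s0 = np.asarray(s0, dtype=float)
    adc = np.asarray(adc, dtype=float)
    return s0 * np.exp(-b_target * adc)


def resize_slice(image: np.ndarray, target: int = RESIZE_TO) -> np.ndarray:
    """Bilinear resize of a 2D image to ``target x target`` pixels.

    Downsampling applies a Gaussian anti-aliasing prefilter so mean intensity
    is preserved; an already-correctly-sized image is returned unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2D image")
    if image.shape == (target, target):
        return image.copy()
    return _skimage_resize(
        image, (target, target), order=1, preserve_range=True,
        anti_aliasing=None, mode="edge",
    )


def center_crop(image: np.ndarray, size: int = CROP_TO) -> np.ndarray:
    """Center crop to ``size x size``; odd margins floor toward the origin."""
    image = np.asarray(image)
    h, w = image.shape
    if h < size or w < size:
        raise ValueError(f"image {image.shape} smaller than crop {size}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return image[r0 : r0 + size, c0 : c0 + size].copy()


def assemble_channels(study: DWIStudy, slice_index: int) -> np.ndarray:
    """Build the 66x66x6 channel stack for one slice of a study.

    Channels in order: ADC map, the four acquired b-value images, and the
    computed b1600 image (extrapolated from the fitted S0 and ADC). Every
    channel is resized to 144x144 then center-cropped to 66x66.
    """
    lo, hi = study.prostate_range
    if not (lo <= slice_index <= hi):
        raise ValueError(f"slice {slice_index} outside prostate range {study.prostate_range}")
    raw = study.slices[slice_index]
    missing = set(ACQUIRED_B_VALUES) - set(raw)
    if missing:
        raise ValueError(f"missing acquired b-values: {sorted(missing)}")
    adc, s0 = fit_adc({b: raw[b] for b in ACQUIRED_B_VALUES}, return_s0=True)
    b1600 = extrapolate_high_b(s0, adc, B_TARGET)
    planes = [adc] + [np.asarray(raw[b], dtype=float) for b in ACQUIRED_B_VALUES] + [b1600]
    out = np.empty((CROP_TO, CROP_TO, len(planes)), dtype=float)
    for k, plane in enumerate(planes):
        out[:, :, k] = center_crop(resize_slice(plane, RESIZE_TO), CROP_TO)
    return out


def compute_norm_stats(stacks: Sequence[np.ndarray]) -> NormalizationStats:
    """Per-channel mean/std over all pixels of all stacks (population std)."""
    if len(stacks) == 0:
        raise ValueError("need at least one channel stack")
    flat = np.concatenate([np.asarray(s, dtype=float).reshape(-1, s.shape[-1])
                           for s in stacks], axis=0)
    mu = flat.mean(axis=0)
    std = flat.std(axis=0)  # population convention (ddof=0)
    if np.any(std == 0):
        bad = [CHANNEL_ORDER[i] if i < len(CHANNEL_ORDER) else str(i)
               for i in np.flatnonzero(std == 0)]
        raise ValueError(f"degenerate (zero-variance) channel(s): {bad}")
    return NormalizationStats(mu=mu, std=std)


def normalize(stack: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Z-score a channel stack: ``(x - mu) / std`` per channel."""
    stack = np.asarray(stack, dtype=float)
    if stack.shape[-1] != stats.mu.shape[0]:
        raise ValueError(
            f"stack has {stack.shape[-1]} channels, stats have {stats.mu.shape[0]}"
        )
    return (stack - stats.mu) / stats.std


def denormalize(stack: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Inverse of :func:`normalize`."""
    return np.asarray(stack, dtype=float) * stats.std + stats.mu


def preprocess_cohort(
    studies: Sequence[DWIStudy],
    stats: NormalizationStats | None = None,
) -> Tuple[List[dict], NormalizationStats]:
    """Assemble and normalize every prostate slice of every study.

    By default the normalization statistics are computed across the entire
    dataset being preprocessed (training+validation+test pooled); pass
    ``stats`` fitted on the training set only for a leakage-free variant.

    Returns
    -------
    records : list of dict
        One per slice: patient_id, slice_index, label, stack (66x66x6,
        normalized).
    stats : NormalizationStats
        The statistics used.
    """
    records = []
    for study in studies:
        lo, hi = study.prostate_range
        for j in range(lo, hi + 1):
            records.append({
                "patient_id": study.patient_id,
                "slice_index": j,
                "label": int(study.slice_labels[j]),
                "stack": assemble_channels(study, j),
            })
    if stats is None:
        stats = compute_norm_stats([r["stack"] for r in records])
    for r in records:
        r["stack"] = normalize(r["stack"], stats)
    return records, stats
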