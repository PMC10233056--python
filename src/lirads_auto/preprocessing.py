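"""Intensity normalization, 2.5D windowing, augmentation, and fold splits.

The normalization is the piecewise map used for multi-phase liver MRI, where
raw signal below a floor of 80 is background and a per-volume 99th-percentile
threshold caps the bright tail:

    n_i = 0                      if o_i < floor
    n_i = (o_i - floor)/(P99 - floor)   if floor <= o_i <= P99
    n_i = 1                      if o_i > P99

followed by per-volume standardization to zero mean / unit variance.  The
segmentation network consumes 2.5D windows — three neighbouring axial slices
stacked as channels, labelled by the centre slice's mask — so an S-slice
volume yields S - 2 windows (a 300-slice volume yields 298).

Fold splitting is done at the patient level so neighbouring slices of one
patient can never straddle the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

PHASES = ("arterial", "portal_venous", "delayed")


@dataclass
class RawVolume:
    """A single-phase 3-D volume in scanner units."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    phase: str = "delayed"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("volume must be 3-D with all dimensions >= 1")
        if not np.isfinite(self.voxels).all():
            raise ValueError("volume contains non-finite intensities")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class NormalizedVolume:
    voxels: np.ndarray
    p99: float
    floor: float = 80.0

    def __post_init__(self) -> None:
        if self.p99 <= self.floor:
            raise ValueError("percentile threshold must exceed the floor")


@dataclass
class Window25D:
    """Three neighbouring axial slices as channels plus the centre-slice mask."""

    slices: np.ndarray  # (3, rows, cols)
    center_index: int
    label_slice: np.ndarray  # (rows, cols) binary

    def __post_init__(self) -> None:
        if self.slices.shape[0] != 3:
            raise ValueError("a 2.5D window has exactly 3 channels")


@dataclass
class FoldSplit:
    n_folds: int
    assignment: dict  # patient id -> fold index

    def fold_patients(self, k: int) -> list:
        return sorted(p for p, f in self.assignment.items() if f == k)

    def train_test(self, k: int) -> tuple[list, list]:
        test = self.fold_patients(k)
        train = sorted(p for p, f in self.assignment.items() if f != k)
        return train, test


def normalize_intensity(
    volume: RawVolume | np.ndarray, floor: float = 80.0, percentile: float = 0.99
) -> NormalizedVolume:
    """Apply the piecewise floor/percentile intensity normalization.

    Values below ``floor`` map to 0, values above the per-volume
    ``percentile`` threshold map to 1, and the range between is scaled
    linearly into [0, 1].  Raises if the percentile threshold does not exceed
    the floor (e.g. a constant volume), naming the offending volume.
    """
    vox = volume.voxels if isinstance(volume, RawVolume) else np.asarray(volume, dtype=float)
    if vox.size == 0:
        raise ValueError("empty volume")
    p99 = float(np.quantile(vox, percentile))
    if p99 <= floor:
        phase = volume.phase if isinstance(volume, RawVolume) else "volume"
        raise ValueError(
            f"degenerate {phase}: {percentile:.0%} percentile {p99:.3g} "
            f"does not exceed floor {floor:.3g}"
        )
    out = (vox - floor) / (p99 - floor)
    out = np.clip(out, 0.0, 1.0)
    out[vox < floor] = 0.0
    out[vox > p99] = 1.0
    return NormalizedVolume(voxels=out, p99=p99, floor=floor)


def standardize(volume: NormalizedVolume | np.ndarray) -> np.ndarray:
    """Per-volume standardization to zero mean and unit standard deviation."""
    vox = volume.voxels if isinstance(volume, NormalizedVolume) else np.asarray(volume, dtype=float)
    sd = vox.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant volume (zero variance)")
    return (vox - vox.mean()) / sd


def make_windows(volume: np.ndarray, mask: np.ndarray | None = None) -> list[Window25D]:
    """Cut a volume into 2.5D windows: one per interior slice.

    An S-slice volume produces S - 2 windows ordered by centre index; each
    window's label is the centre slice of ``mask`` (zeros if no mask given).
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("volume must be 3-D (slices, rows, cols)")
    s = vol.shape[0]
    if s < 3:
        raise ValueError(f"need at least 3 slices for 2.5D windows, got {s}")
    if mask is None:
        mask = np.zeros_like(vol, dtype=np.uint8)
    mask = np.asarray(mask)
    if mask.shape != vol.shape:
        raise ValueError("mask must share the volume grid")
    return [
        Window25D(slices=vol[c - 1 : c + 2], center_index=c, label_slice=mask[c])
        for c in range(1, s - 1)
    ]


def augment(
    image: np.ndarray,
    label: np.ndarray,
    seed: int | np.random.Generator,
    max_rotation_deg: float = 15.0,
    max_shift_frac: float = 0.10,
    flip_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Random rotation, shift, and horizontal/vertical flips, zero-padded.

    The identical spatial transform is applied to the image and its label
    (nearest-neighbour for the label so it stays binary); outputs keep the
    input shape, with content leaving the field of view replaced by zeros.
    """
    img = np.asarray(image, dtype=float)
    lab = np.asarray(label)
    if img.shape[-2:] != lab.shape[-2:]:
        raise ValueError("image and label must share a grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    shifts = rng.uniform(-max_shift_frac, max_shift_frac, size=2) * np.array(img.shape[-2:])
    flips = rng.random(2) < flip_prob

    def _transform(a: np.ndarray, order: int) -> np.ndarray:
        out = a.astype(float)
        multi = out.ndim == 3
        if flips[0]:
            out = out[..., ::-1, :]
        if flips[1]:
            out = out[..., :, ::-1]
        rot_axes = (-2, -1)
        out = ndi.rotate(out, angle, axes=rot_axes, reshape=False, order=order,
                         mode="constant", cval=0.0)
        shift = ([0.0] if multi else []) + list(shifts)
        out = ndi.shift(out, shift, order=order, mode="constant", cval=0.0)
        return out

    img_out = _transform(img, order=1)
    lab_out = _transform(lab.astype(float), order=0)
    return img_out, lab_out.astype(lab.dtype)


def split_folds(
    patients, n_folds: int = 9, seed: int | np.random.Generator = 0,
    stratify_by: dict | None = None,
) -> FoldSplit:
    """Randomly partition patients into ``n_folds`` near-equal folds.

    Splitting is at the patient level.  ``stratify_by`` optionally maps each
    patient to a stratum label; patients are then dealt round-robin within
    strata, which keeps strata balanced while fold sizes still differ by at
    most one.
    """
    patients = list(patients)
    if len(patients) < n_folds:
        raise ValueError(f"{len(patients)} patients cannot fill {n_folds} folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if stratify_by is None:
        order = [patients[i] for i in rng.permutation(len(patients))]
    else:
        strata: dict = {}
        for p in patients:
            strata.setdefault(stratify_by[p], []).append(p)
        order = []
        for key in sorted(strata, key=str):
            group = strata[key]
            order.extend(group[i] for i in rng.permutation(len(group)))
    start = int(rng.integers(n_folds))
    assignment = {p: (start + i) % n_folds for i, p in enumerate(order)}
    return FoldSplit(n_folds=n_folds, assignment=assignment)
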