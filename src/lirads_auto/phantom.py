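"""Synthetic multi-phase liver phantoms with known lesion feature dynamics.

Each patient is three co-registered phase volumes (arterial, portal-venous,
delayed) holding an ellipsoidal "liver" of uniform parenchyma on a dark
background, with 0–3 spherical lesions.  A lesion's appearance is driven
entirely by its three ground-truth feature flags:

* APHE (B1): the whole lesion is brighter than parenchyma in the arterial
  phase;
* washout (B2): the lesion core is darker than parenchyma in the
  portal-venous and delayed phases;
* capsule (B3): a 1–2 voxel bright shell just inside the lesion boundary in
  the portal-venous and delayed phases.

Without its feature offsets a lesion is isointense to parenchyma, so feature
contrast — not anatomy — is the only signal, which is exactly what the
downstream characterizer must learn.  Gaussian noise of configurable sigma is
added last.  Every lesion's LI-RADS label is produced by the scoring module's
rule engine from (B1, B2, B3, diameter), so phantom labels are
rule-consistent by construction.

Determinism: all randomness flows from ``(spec.seed, patient_seed,
lesion_index)`` seed sequences, so identical specs reproduce identical
datasets bit for bit and patients are independent of one another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scoring import AmbiguityPolicy, ScoredCategory, infer_lirads

PHASES = ("arterial", "portal_venous", "delayed")

#: Signal offsets (scanner units) applied per feature in the phases where the
#: feature expresses: APHE in arterial, washout and capsule in PV/delayed.
DEFAULT_CONTRAST = {"aphe": 60.0, "washout": -45.0, "capsule": 50.0}


class LesionPlacementError(RuntimeError):
    """Raised when non-overlapping lesion placement fails after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a phantom dataset.

    Defaults emulate the composition of the clinical cohort the pipeline is
    modelled on: 512x512 slices, 0-3 lesions per patient with diameters
    4-164 mm of which ~45% are below 20 mm, and HCC-typical feature
    prevalences (APHE common, washout frequent, capsule roughly every other
    lesion).
    """

    n_patients: int = 111
    lesions_per_patient: tuple[int, int] = (0, 3)
    diameter_mm: tuple[float, float] = (4.0, 164.0)
    small_lesion_fraction: float = 0.448
    feature_prevalence: tuple[float, float, float] = (0.80, 0.70, 0.50)
    contrast: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    noise_sigma: float = 8.0
    volume_shape: tuple[int, int, int] = (300, 512, 512)
    spacing_mm: tuple[float, float, float] = (1.0, 0.7, 0.7)
    seed: int = 0
    background_intensity: float = 40.0
    liver_intensity: float = 150.0
    capsule_thickness_voxels: float = 1.6

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        lo, hi = self.lesions_per_patient
        if not (0 <= lo <= hi):
            raise ValueError("lesions_per_patient must satisfy 0 <= low <= high")
        dlo, dhi = self.diameter_mm
        if not (0 < dlo <= dhi):
            raise ValueError("diameter range must be positive with low <= high")
        for p in (*self.feature_prevalence, self.small_lesion_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.volume_shape[1] != self.volume_shape[2]:
            raise ValueError("slices must be square (rows == cols)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def easy(cls, n_patients: int = 40, seed: int = 0) -> "PhantomSpec":
        """Desk-scale 'easy' conditions: small 64x64 volumes, high feature
        contrast, low noise, and high feature prevalence, so lesions are
        well separated from parenchyma in every informative phase."""
        return cls(
            n_patients=n_patients,
            lesions_per_patient=(0, 2),
            diameter_mm=(8.0, 22.0),
            small_lesion_fraction=0.45,
            feature_prevalence=(0.95, 0.95, 0.5),
            contrast={"aphe": 90.0, "washout": -70.0, "capsule": 80.0},
            noise_sigma=2.0,
            volume_shape=(24, 64, 64),
            spacing_mm=(2.0, 1.25, 1.25),
            seed=seed,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruthLesion:
    lesion_id: str
    center_voxel: tuple[int, int, int]
    diameter_mm: float
    B1: bool
    B2: bool
    B3: bool
    label: ScoredCategory


@dataclass
class MultiPhaseStudy:
    """Per-patient co-registered phase volumes plus the ground-truth mask."""

    patient_id: str
    phases: dict  # phase name -> (slices, rows, cols) float array
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray  # uint8, 1 inside any lesion


def _lesion_rng(spec: PhantomSpec, patient_seed: int, lesion_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, patient_seed, lesion_index])
    )


def _sample_diameter(rng: np.random.Generator, spec: PhantomSpec) -> float:
    lo, hi = spec.diameter_mm
    if lo < 20.0 < hi:
        if rng.random() < spec.small_lesion_fraction:
            return float(rng.uniform(lo, 20.0))
        return float(rng.uniform(20.0, hi))
    return float(rng.uniform(lo, hi))


def generate_study(
    spec: PhantomSpec, patient_seed: int, max_retries: int = 400
) -> tuple[MultiPhaseStudy, list[GroundTruthLesion]]:
    """Generate one patient: three phase volumes, mask, and lesion truth.

    Lesions are spheres placed inside the liver ellipsoid without overlap;
    placement failure after ``max_retries`` attempts raises
    :class:`LesionPlacementError` naming the patient.
    """
    shape = spec.volume_shape
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, patient_seed])
    )
    pid = f"P{patient_seed:04d}"

    # physical coordinate grid (mm), one axis at a time to save memory
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    semi = 0.42 * np.asarray(shape) * spacing  # liver ellipsoid semi-axes, mm
    coords = [
        (np.arange(shape[a]) * spacing[a] - center[a]) for a in range(3)
    ]
    zz = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    xx = coords[2][None, None, :]
    liver = (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2 <= 1.0

    base = np.full(shape, spec.background_intensity, dtype=np.float32)
    base[liver] = spec.liver_intensity
    phases = {ph: base.copy() for ph in PHASES}
    mask = np.zeros(shape, dtype=np.uint8)

    n_lesions = int(rng.integers(spec.lesions_per_patient[0], spec.lesions_per_patient[1] + 1))
    lesions: list[GroundTruthLesion] = []
    placed: list[tuple[np.ndarray, float]] = []  # (center mm, radius mm)
    p_aphe, p_washout, p_capsule = spec.feature_prevalence

    for li in range(n_lesions):
        lrng = _lesion_rng(spec, patient_seed, li)
        diameter = _sample_diameter(lrng, spec)
        r = diameter / 2.0
        b1 = bool(lrng.random() < p_aphe)
        b2 = bool(lrng.random() < p_washout)
        b3 = bool(lrng.random() < p_capsule)

        pos = None
        for _ in range(max_retries):
            # uniform in the shrunken ellipsoid so the sphere stays inside
            u = lrng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = lrng.random() ** (1.0 / 3.0)
            cand = u * rad * np.maximum(semi - r - spacing.max(), 0.0)
            if np.any(semi - r - spacing.max() <= 0):
                continue
            if all(np.linalg.norm(cand - c0) > r + r0 + 2.0 for c0, r0 in placed):
                pos = cand
                break
        if pos is None:
            raise LesionPlacementError(
                f"patient {pid}: could not place lesion {li} "
                f"(diameter {diameter:.1f} mm) without overlap after {max_retries} tries"
            )
        placed.append((pos, r))

        # rasterize within the lesion's bounding box only
        lo_ix = [max(int(np.floor((pos[a] + center[a] - r) / spacing[a])) - 1, 0) for a in range(3)]
        hi_ix = [min(int(np.ceil((pos[a] + center[a] + r) / spacing[a])) + 2, shape[a]) for a in range(3)]
        box = tuple(slice(lo_ix[a], hi_ix[a]) for a in range(3))
        d2 = (
            (zz[box[0], :, :] - pos[0]) ** 2
            + (yy[:, box[1], :] - pos[1]) ** 2
            + (xx[:, :, box[2]] - pos[2]) ** 2
        )
        sphere = d2 <= r**2
        thickness = spec.capsule_thickness_voxels * float(spacing[2])
        core = d2 <= max(r - thickness, 0.0) ** 2 if b3 else sphere
        rim = sphere & ~core

        if b1:
            phases["arterial"][box][sphere] += spec.contrast["aphe"]
        for ph in ("portal_venous", "delayed"):
            if b2:
                phases[ph][box][core] += spec.contrast["washout"]
            if b3:
                phases[ph][box][rim] += spec.contrast["capsule"]
        mask[box][sphere] = 1

        center_vox = tuple(
            int(round(v)) for v in (pos + center) / spacing
        )
        label = infer_lirads(b1, b2, b3, diameter, AmbiguityPolicy.PREFER_WASHOUT_RULE)
        lesions.append(
            GroundTruthLesion(
                lesion_id=f"{pid}_L{li}",
                center_voxel=center_vox,
                diameter_mm=diameter,
                B1=b1, B2=b2, B3=b3,
                label=label,
            )
        )

    if spec.noise_sigma > 0:
        for ph in PHASES:
            phases[ph] += rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)

    study = MultiPhaseStudy(
        patient_id=pid,
        phases=phases,
        spacing_mm=tuple(float(s) for s in spacing),
        mask=mask,
    )
    return study, lesions


def generate_dataset(spec: PhantomSpec, out_dir) -> "pandas.DataFrame":
    """Generate and write a whole phantom dataset.

    Writes, per patient, one NIfTI volume per phase plus the binary lesion
    mask, and at the top level a CSV manifest (one row per lesion) and a JSON
    copy of the spec.  Returns the manifest as a DataFrame.
    """
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(spec.n_patients):
        study, lesions = generate_study(spec, i)
        affine = np.diag([*study.spacing_mm[::-1], 1.0])
        pdir = out / study.patient_id
        pdir.mkdir(exist_ok=True)
        try:
            for ph, vol in study.phases.items():
                nib.save(nib.Nifti1Image(vol.T.astype(np.float32), affine),
                         pdir / f"{ph}.nii.gz")
            nib.save(nib.Nifti1Image(study.mask.T.astype(np.uint8), affine),
                     pdir / "mask.nii.gz")
        except OSError as exc:
            raise OSError(f"failed writing phantom volumes under {pdir}: {exc}") from exc
        for les in lesions:
            rows.append(
                {
                    "patient_id": study.patient_id,
                    "lesion_id": les.lesion_id,
                    "diameter_mm": les.diameter_mm,
                    "B1": int(les.B1),
                    "B2": int(les.B2),
                    "B3": int(les.B3),
                    "label": les.label.resolved_value.value,
                }
            )
    manifest = pd.DataFrame(
        rows, columns=["patient_id", "lesion_id", "diameter_mm", "B1", "B2", "B3", "label"]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "phantom_spec.json").write_text(spec.to_json())
    return manifest


def load_study(dataset_dir, patient_id: str) -> MultiPhaseStudy:
    """Read one patient's phase volumes and mask back from a dataset directory."""
    import nibabel as nib

    pdir = Path(dataset_dir) / patient_id
    if not pdir.is_dir():
        raise FileNotFoundError(f"no such patient directory: {pdir}")
    phases = {}
    for ph in PHASES:
        img = nib.load(pdir / f"{ph}.nii.gz")
        phases[ph] = np.asarray(img.dataobj, dtype=np.float32).T
    img = nib.load(pdir / "mask.nii.gz")
    mask = np.asarray(img.dataobj, dtype=np.uint8).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return MultiPhaseStudy(patient_id=patient_id, phases=phases,
                           spacing_mm=spacing, mask=mask)
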