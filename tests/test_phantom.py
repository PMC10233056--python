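"""Phantom generator: determinism, feature-contrast semantics, label
consistency with the rule engine, and dataset output files."""

import hashlib

import numpy as np
import pytest

from lirads_auto.phantom import (
    PhantomSpec,
    generate_dataset,
    generate_study,
    load_study,
)
from lirads_auto.scoring import AmbiguityPolicy, infer_lirads, measure_lesion_size


def _small_spec(**kw):
    base = dict(
        n_patients=4,
        lesions_per_patient=(1, 1),
        diameter_mm=(6.0, 24.0),
        small_lesion_fraction=0.5,
        feature_prevalence=(0.5, 0.5, 0.5),
        noise_sigma=0.0,
        volume_shape=(20, 48, 48),
        spacing_mm=(2.0, 1.25, 1.25),
        seed=7,
    )
    base.update(kw)
    return PhantomSpec(**base)


def test_no_lesion_case():
    spec = _small_spec(lesions_per_patient=(0, 0))
    study, lesions = generate_study(spec, 0)
    assert lesions == []
    assert not study.mask.any()
    assert set(study.phases) == {"arterial", "portal_venous", "delayed"}


def test_determinism_bit_identical():
    spec = _small_spec(noise_sigma=4.0)
    s1, l1 = generate_study(spec, 2)
    s2, l2 = generate_study(spec, 2)
    for ph in s1.phases:
        np.testing.assert_array_equal(s1.phases[ph], s2.phases[ph])
    np.testing.assert_array_equal(s1.mask, s2.mask)
    assert [v.lesion_id for v in l1] == [v.lesion_id for v in l2]
    # different patients differ
    s3, _ = generate_study(spec, 3)
    assert any((s1.phases[ph] != s3.phases[ph]).any() for ph in s1.phases)


def test_labels_match_rule_engine_over_many_lesions():
    """Exhaustive cross-module consistency on a 500-lesion sample."""
    spec = _small_spec(n_patients=500, seed=11)
    n = 0
    for i in range(spec.n_patients):
        _, lesions = generate_study(spec, i)
        for les in lesions:
            expected = infer_lirads(les.B1, les.B2, les.B3, les.diameter_mm,
                                    AmbiguityPolicy.PREFER_WASHOUT_RULE)
            assert les.label.value == expected.value
            assert les.label.resolved_value == expected.resolved_value
            n += 1
    assert n >= 500


def test_feature_contrast_semantics_at_zero_noise():
    """Arterial lesion signal elevated iff APHE; PV/delayed core depressed iff
    washout; a bright PV rim appears iff capsule.  Checked against the liver
    parenchyma level on noise-free phantoms."""
    spec = _small_spec(n_patients=40, seed=3)
    liver_level = spec.liver_intensity
    checked = {"b1": 0, "b2": 0, "b3": 0}
    for i in range(spec.n_patients):
        study, lesions = generate_study(spec, i)
        for les in lesions:
            inside = study.mask.astype(bool)
            art = study.phases["arterial"][inside].mean() - liver_level
            assert (art > 1.0) == les.B1
            checked["b1"] += 1
            pv = study.phases["portal_venous"]
            if not les.B3:  # whole lesion is core
                assert ((pv[inside].mean() - liver_level) < -1.0) == les.B2
                checked["b2"] += 1
            else:  # capsule present: the rim is brighter than parenchyma
                assert pv[inside].max() > liver_level + 1.0
                checked["b3"] += 1
    assert min(checked.values()) >= 3  # each branch exercised


def test_empirical_diameter_close_to_requested():
    spec = _small_spec(n_patients=12, seed=5)
    voxel_diag = float(np.linalg.norm(spec.spacing_mm))
    for i in range(spec.n_patients):
        study, lesions = generate_study(spec, i)
        assert len(lesions) == 1
        measured = measure_lesion_size(study.mask.astype(bool), spec.spacing_mm)
        assert abs(measured - lesions[0].diameter_mm) <= voxel_diag


def test_dataset_hash_reproducible():
    spec = _small_spec(n_patients=3, noise_sigma=2.0)

    def digest():
        h = hashlib.sha256()
        for i in range(spec.n_patients):
            study, _ = generate_study(spec, i)
            for ph in sorted(study.phases):
                h.update(np.ascontiguousarray(study.phases[ph]).tobytes())
            h.update(np.ascontiguousarray(study.mask).tobytes())
        return h.hexdigest()

    assert digest() == digest()


def test_generate_dataset_manifest_and_roundtrip(tmp_path):
    spec = _small_spec(n_patients=5)
    manifest = generate_dataset(spec, tmp_path)
    assert len(manifest) == 5  # one lesion per patient
    assert list(manifest.columns) == [
        "patient_id", "lesion_id", "diameter_mm", "B1", "B2", "B3", "label"
    ]
    assert (tmp_path / "manifest.csv").exists()
    assert (tmp_path / "phantom_spec.json").exists()
    study = load_study(tmp_path, manifest.patient_id.iloc[0])
    fresh, _ = generate_study(spec, 0)
    np.testing.assert_allclose(study.phases["delayed"], fresh.phases["delayed"], atol=1e-4)
    np.testing.assert_array_equal(study.mask, fresh.mask)
    assert study.spacing_mm == pytest.approx(spec.spacing_mm)


def test_extreme_prevalence_labels(tmp_path):
    all_on = _small_spec(
        n_patients=4, feature_prevalence=(1.0, 1.0, 1.0), diameter_mm=(20.0, 24.0),
        small_lesion_fraction=0.0,
    )
    manifest = generate_dataset(all_on, tmp_path / "on")
    assert set(manifest.label) == {"LR-5"}
    all_off = _small_spec(
        n_patients=4, feature_prevalence=(0.0, 0.0, 0.0), diameter_mm=(6.0, 18.0),
    )
    manifest = generate_dataset(all_off, tmp_path / "off")
    assert set(manifest.label) == {"LR-3"}


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(volume_shape=(10, 32, 48))  # non-square slices
    with pytest.raises(ValueError):
        PhantomSpec(diameter_mm=(0.0, 10.0))
    with pytest.raises(ValueError):
        PhantomSpec(feature_prevalence=(1.2, 0.5, 0.5))


def test_placement_failure_names_patient():
    from lirads_auto.phantom import LesionPlacementError

    spec = _small_spec(
        lesions_per_patient=(3, 3), diameter_mm=(22.0, 24.0), small_lesion_fraction=0.0,
        volume_shape=(16, 32, 32), spacing_mm=(2.0, 1.25, 1.25),
    )
    with pytest.raises(LesionPlacementError, match="P00"):
        for i in range(5):
            generate_study(spec, i, max_retries=20)
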