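"""Rule-based LI-RADS category inference and lesion-size measurement.

The LI-RADS major-feature rule table maps the three boolean feature calls —
B1 (non-rim arterial phase hyperenhancement), B2 (non-peripheral washout),
B3 (enhancing capsule) — together with the lesion diameter in millimetres to
an ordinal category LR-3 / LR-4 / LR-5.  One cell of the table (B1 present,
diameter 10–19 mm, exactly one of washout/capsule) is ambiguous ("LR-4/5");
an explicit :class:`AmbiguityPolicy` resolves it.

Size bins are half-open: "<10" is [0, 10) mm, "10–19" is [10, 20) mm and
"≥20" is [20, ∞) mm, so the mapping is total.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class LiradsCategory(str, Enum):
    LR3 = "LR-3"
    LR4 = "LR-4"
    LR4_OR_5 = "LR-4/5"
    LR5 = "LR-5"


class AmbiguityPolicy(str, Enum):
    """How the ambiguous LR-4/5 cell is resolved.

    ``prefer_washout_rule`` resolves to LR-5 when washout (B2) is the feature
    present and to LR-4 when only capsule is, mirroring the distinction ACR
    LI-RADS v2018 draws between the two features.  ``report_both`` keeps the
    ambiguous value.
    """

    REPORT_BOTH = "report_both"
    PREFER_WASHOUT_RULE = "prefer_washout_rule"
    FORCE_LR4 = "force_lr4"
    FORCE_LR5 = "force_lr5"


@dataclass(frozen=True)
class ScoredCategory:
    value: LiradsCategory
    resolved_value: LiradsCategory

    def __post_init__(self) -> None:
        if self.value is not LiradsCategory.LR4_OR_5:
            if self.resolved_value is not self.value:
                raise ValueError("resolved_value must equal value unless ambiguous")


# Rule table indexed by [B1][size bin][B2 + B3].
# For B1 = 0 there are two size bins (<20, >=20); for B1 = 1 there are three
# (<10, 10-19, >=20).
_TABLE_B1_FALSE = {
    "lt20": (LiradsCategory.LR3, LiradsCategory.LR3, LiradsCategory.LR4),
    "ge20": (LiradsCategory.LR3, LiradsCategory.LR4, LiradsCategory.LR4),
}
_TABLE_B1_TRUE = {
    "lt10": (LiradsCategory.LR3, LiradsCategory.LR4, LiradsCategory.LR4),
    "10to19": (LiradsCategory.LR3, LiradsCategory.LR4_OR_5, LiradsCategory.LR5),
    "ge20": (LiradsCategory.LR4, LiradsCategory.LR5, LiradsCategory.LR5),
}


def _resolve(value: LiradsCategory, b2: bool, policy: AmbiguityPolicy) -> LiradsCategory:
    if value is not LiradsCategory.LR4_OR_5:
        return value
    if policy is AmbiguityPolicy.REPORT_BOTH:
        return LiradsCategory.LR4_OR_5
    if policy is AmbiguityPolicy.FORCE_LR4:
        return LiradsCategory.LR4
    if policy is AmbiguityPolicy.FORCE_LR5:
        return LiradsCategory.LR5
    # prefer_washout_rule: washout upgrades, capsule alone does not
    return LiradsCategory.LR5 if b2 else LiradsCategory.LR4


def infer_lirads(
    b1: bool,
    b2: bool,
    b3: bool,
    size_mm: float,
    policy: AmbiguityPolicy = AmbiguityPolicy.PREFER_WASHOUT_RULE,
) -> ScoredCategory:
    """Look up the LI-RADS category for one lesion.

    Parameters
    ----------
    b1, b2, b3
        Feature calls: arterial phase hyperenhancement, washout, capsule.
    size_mm
        Lesion diameter in millimetres (must be positive).
    policy
        Resolution policy for the ambiguous LR-4/5 cell.
    """
    if size_mm <= 0:
        raise ValueError(f"size_mm must be positive, got {size_mm}")
    n_minor = int(bool(b2)) + int(bool(b3))
    if b1:
        if size_mm < 10:
            row = _TABLE_B1_TRUE["lt10"]
        elif size_mm < 20:
            row = _TABLE_B1_TRUE["10to19"]
        else:
            row = _TABLE_B1_TRUE["ge20"]
    else:
        row = _TABLE_B1_FALSE["lt20" if size_mm < 20 else "ge20"]
    value = row[n_minor]
    resolved = _resolve(value, bool(b2), policy)
    if value is LiradsCategory.LR4_OR_5 and policy is AmbiguityPolicy.REPORT_BOTH:
        return ScoredCategory(value=value, resolved_value=value)
    if value is LiradsCategory.LR4_OR_5:
        return ScoredCategory(value=value, resolved_value=resolved)
    return ScoredCategory(value=value, resolved_value=value)


def measure_lesion_size(component_mask: np.ndarray, spacing_mm) -> float:
    """Maximum in-plane Feret diameter of a lesion component, in mm.

    The diameter is the largest centre-to-centre distance between two
    foreground pixels within any single axial slice, scaled by the in-plane
    spacing, plus one in-plane spacing unit so that a single-voxel lesion
    measures one pixel width rather than zero (documented +1-voxel
    convention; a straight run of k voxels at 1 mm spacing measures k mm).

    Parameters
    ----------
    component_mask
        Boolean array, either (slices, rows, cols) or a single (rows, cols)
        slice, containing exactly one lesion component.
    spacing_mm
        Voxel spacing; the trailing two entries are the in-plane (row, col)
        spacings.  In-plane pixels are assumed square.
    """
    mask = np.asarray(component_mask, dtype=bool)
    if mask.ndim == 2:
        mask = mask[None]
    if mask.ndim != 3:
        raise ValueError("component mask must be 2-D or 3-D")
    if not mask.any():
        raise ValueError("empty lesion component")
    spacing = np.asarray(spacing_mm, dtype=float).ravel()
    sy, sx = float(spacing[-2]), float(spacing[-1])
    best = 0.0
    for z in range(mask.shape[0]):
        pts = np.argwhere(mask[z])
        if pts.size == 0:
            continue
        best = max(best, _max_pairwise(pts * np.array([sy, sx])))
    return best + sx


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance among 2-D points (convex hull when possible)."""
    if len(points) == 1:
        return 0.0
    if len(points) > 16:
        try:
            from scipy.spatial import ConvexHull

            points = points[ConvexHull(points).vertices]
        except Exception:  # collinear input degenerates; fall through
            pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def score_study(profiles, policy: AmbiguityPolicy = AmbiguityPolicy.PREFER_WASHOUT_RULE):
    """Score every detected lesion of one study.

    Parameters
    ----------
    profiles
        Iterable of objects carrying ``lesion_id``, ``B1``, ``B2``, ``B3``,
        ``p_aphe``, ``p_washout``, ``p_capsule`` and ``size_mm`` (the
        characterization module's ``FeatureProfile``).

    Returns
    -------
    pandas.DataFrame
        One row per lesion with feature calls, size, and both the raw and
        policy-resolved LI-RADS category.  Empty input gives an empty table.
    """
    import pandas as pd

    rows = []
    for prof in profiles:
        cat = infer_lirads(prof.B1, prof.B2, prof.B3, prof.size_mm, policy)
        rows.append(
            {
                "lesion_id": prof.lesion_id,
                "B1": int(prof.B1),
                "B2": int(prof.B2),
                "B3": int(prof.B3),
                "p_aphe": prof.p_aphe,
                "p_washout": prof.p_washout,
                "p_capsule": prof.p_capsule,
                "size_mm": prof.size_mm,
                "category": cat.value.value,
                "resolved": cat.resolved_value.value,
            }
        )
    columns = [
        "lesion_id", "B1", "B2", "B3", "p_aphe", "p_washout", "p_capsule",
        "size_mm", "category", "resolved",
    ]
    return pd.DataFrame(rows, columns=columns)
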