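"""Lesion feature characterization: APHE / washout / capsule probabilities.

One convolutional backbone is shared by three independent sigmoid heads, one
per feature.  Because the arterial phase carries only the APHE signal while
washout and capsule express in the portal-venous and delayed phases, each
training sample carries a phase indicator x (0 = arterial, 1 = PV/delayed)
and the adaptive multi-task loss routes gradients accordingly: an arterial
sample updates the backbone and the APHE head only; a PV/delayed sample
updates the backbone and the washout + capsule heads only.  This lets every
crop, from every phase, train the one shared model.

Inference takes one representative slice per phase — the slice with the
largest segmented lesion area — cropped square around the lesion with a
margin, resized, and standardized.  Washout and capsule evidence from the
portal-venous and delayed phases is fused by taking the maximum of the two
head probabilities ("present in either phase").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .losses import adaptive_multitask_loss, bce_and_grad

FEATURES = ("aphe", "washout", "capsule")
ARTERIAL_PHASES = ("arterial",)
LATE_PHASES = ("portal_venous", "delayed")


@dataclass
class LesionCrop:
    """A standardized square crop around one lesion in one phase."""

    image: np.ndarray
    phase_indicator: int  # 0 = arterial, 1 = portal-venous / delayed
    lesion_id: str
    source_phase: str

    def __post_init__(self) -> None:
        expect = 0 if self.source_phase in ARTERIAL_PHASES else 1
        if self.phase_indicator != expect:
            raise ValueError(
                f"phase indicator {self.phase_indicator} inconsistent with "
                f"source phase {self.source_phase!r}"
            )


@dataclass
class FeatureProfile:
    lesion_id: str
    p_aphe: float
    p_washout: float
    p_capsule: float
    B1: bool
    B2: bool
    B3: bool
    size_mm: float


def select_representative_slice(stack: np.ndarray) -> int:
    """Index of the slice with the largest segmented-lesion area.

    ``stack`` is a (slices, rows, cols) binary mask (or probability map
    thresholded upstream).  Ties resolve to the lowest index; a stack with no
    foreground anywhere raises (no lesion detected).
    """
    areas = np.asarray(stack).reshape(len(stack), -1).sum(axis=1)
    if areas.max() == 0:
        raise ValueError("no lesion detected: every slice is empty")
    return int(areas.argmax())


def crop_resize(
    slice_image: np.ndarray,
    component_mask: np.ndarray,
    margin: float = 0.25,
    out_size: int = 224,
) -> np.ndarray:
    """Square crop of the lesion bounding box plus margin, resized and
    standardized.

    The bounding box is squared (so aspect is preserved), grown by ``margin``
    of its side, clamped to the image bounds, resized to ``out_size`` squared
    with bilinear interpolation, and standardized to zero mean / unit
    variance.  The crop keeps the raw surrounding context (it is not
    mask-multiplied), so capsule rims survive.
    """
    img = np.asarray(slice_image, dtype=float)
    comp = np.asarray(component_mask, dtype=bool)
    if not comp.any():
        raise ValueError("empty lesion component")
    rows, cols = np.nonzero(comp)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    side = max(r1 - r0, c1 - c0, 2)
    side = int(np.ceil(side * (1.0 + margin)))
    rc, cc = (r0 + r1) / 2.0, (c0 + c1) / 2.0
    half = side / 2.0
    r0n = max(int(np.floor(rc - half)), 0)
    c0n = max(int(np.floor(cc - half)), 0)
    r1n = min(r0n + side, img.shape[0])
    c1n = min(c0n + side, img.shape[1])
    r0n = max(r1n - side, 0)
    c0n = max(c1n - side, 0)
    crop = img[r0n:r1n, c0n:c1n]
    out = resize(crop, (out_size, out_size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    sd = out.std()
    return (out - out.mean()) / sd if sd > 0 else out - out.mean()


@dataclass
class CharConfig:
    """Characterizer architecture; the default is a reduced VGG-style
    backbone sized for desk-scale crops."""

    input_size: int = 32
    widths: tuple[int, ...] = (8, 16)
    hidden: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % (2 ** len(self.widths)):
            raise ValueError("input_size must be divisible by 2^len(widths)")


class Characterizer(nn.Module):
    """Shared conv backbone with three parameter-disjoint sigmoid heads."""

    def __init__(self, config: CharConfig) -> None:
        rng = np.random.default_rng(config.seed)
        self.config = config
        stages = []
        c = 1
        for w in config.widths:
            stages.append(nn.ConvRelu(c, w, rng=rng))
            stages.append(nn.MaxPool2())
            c = w
        self.backbone = nn.Sequential(*stages)
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(c, config.hidden, rng=rng)
        self.fc_act = nn.ReLU()
        self.heads = [nn.Linear(config.hidden, 1, rng=rng) for _ in FEATURES]

    def head_params(self, feature: str):
        return self.heads[FEATURES.index(feature)].params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, S, S) crops -> (N, 3) feature probabilities."""
        feats = self.fc_act.forward(self.fc.forward(self.gap.forward(self.backbone.forward(x))))
        logits = np.concatenate([h.forward(feats) for h in self.heads], axis=1)
        self._p = 1.0 / (1.0 + np.exp(-logits))
        return self._p

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dfeat = sum(h.backward(dlogits[:, i : i + 1]) for i, h in enumerate(self.heads))
        return self.backbone.backward(self.gap.backward(self.fc.backward(self.fc_act.backward(dfeat))))


def build_characterizer(config: CharConfig | None = None) -> Characterizer:
    return Characterizer(config if config is not None else CharConfig())


@dataclass
class CharTrainParams:
    steps: int = 400
    batch_size: int = 16
    lr: float = 2e-3
    seed: int = 0


@dataclass
class CharSample:
    """One training crop: image, phase indicator, and per-feature labels.

    ``labels`` maps feature name -> 0/1.  An arterial sample (x = 0) must
    carry only the "aphe" label; a PV/delayed sample (x = 1) only "washout"
    and "capsule" — labels that contradict the sample's phase routing are
    rejected (unless the trainer runs in non-adaptive mode, where any head
    may consume any sample).
    """

    image: np.ndarray
    x: int
    labels: dict


def _validate_routing(samples: list[CharSample]) -> None:
    for s in samples:
        allowed = {"aphe"} if s.x == 0 else {"washout", "capsule"}
        extra = set(s.labels) - allowed
        if extra:
            raise ValueError(
                f"labels {sorted(extra)} attached to a sample with phase "
                f"indicator x={s.x}; allowed: {sorted(allowed)}"
            )


def train_multitask(
    model: Characterizer,
    samples: list[CharSample],
    params: CharTrainParams,
    adaptive: bool = True,
) -> list[float]:
    """Train the shared backbone with phase-routed (adaptive) per-head BCE.

    With ``adaptive=True`` the per-sample loss is the adaptive multi-task
    loss: the phase indicator picks which heads contribute, and only those
    heads (plus the backbone) receive gradient.  With ``adaptive=False``
    every head consumes every sample (requires all three labels per sample) —
    the comparison arm of the ablation, in which arterial crops force
    washout/capsule supervision onto images that do not carry the signal.
    Returns the per-step mean batch loss log.
    """
    if not samples:
        raise ValueError("no training samples")
    if adaptive:
        _validate_routing(samples)
    else:
        for s in samples:
            if set(s.labels) != set(FEATURES):
                raise ValueError("non-adaptive training needs all three labels per sample")
    rng = np.random.default_rng(params.seed)
    opt = nn.Adam(model.params(), lr=params.lr)
    log: list[float] = []
    for _ in range(params.steps):
        idx = rng.integers(0, len(samples), size=params.batch_size)
        batch = [samples[i] for i in idx]
        xb = np.stack([s.image for s in batch])[:, None]
        probs = model.forward(xb)
        dlogits = np.zeros_like(probs)
        total = 0.0
        for bi, s in enumerate(batch):
            head_losses = {f: 0.0 for f in FEATURES}
            for fi, f in enumerate(FEATURES):
                if f not in s.labels:
                    continue
                if adaptive:
                    active = (s.x == 0 and f == "aphe") or (s.x == 1 and f != "aphe")
                    if not active:
                        continue
                loss_f, _ = bce_and_grad(s.labels[f], probs[bi, fi])
                head_losses[f] = loss_f
                # d(BCE)/dlogit = p - y through the sigmoid
                dlogits[bi, fi] = probs[bi, fi] - s.labels[f]
            if adaptive:
                total += adaptive_multitask_loss(
                    head_losses["aphe"], head_losses["washout"], head_losses["capsule"], s.x
                )
            else:
                total += sum(head_losses.values())
        total /= len(batch)
        dlogits /= len(batch)
        opt.zero_grad()
        model.backward(dlogits)
        opt.step()
        log.append(float(total))
    return log


def predict_features(
    model: Characterizer,
    crops: list[LesionCrop],
    size_mm: float,
    call_threshold: float = 0.5,
) -> FeatureProfile:
    """Fuse per-phase crops of one lesion into a feature profile.

    p_aphe is the maximum APHE-head probability over the arterial crop(s);
    p_washout and p_capsule are the maxima of their heads over the
    portal-venous and delayed crops.  Feature calls use >= call_threshold.
    Raises if a phase group is missing.
    """
    art = [c for c in crops if c.phase_indicator == 0]
    late = [c for c in crops if c.phase_indicator == 1]
    missing = [name for name, group in (("arterial", art), ("portal_venous/delayed", late)) if not group]
    if missing:
        raise ValueError(f"missing phase crops for lesion: {', '.join(missing)}")
    lesion_id = crops[0].lesion_id
    p_art = model.forward(np.stack([c.image for c in art])[:, None])
    p_late = model.forward(np.stack([c.image for c in late])[:, None])
    p_aphe = float(p_art[:, 0].max())
    p_washout = float(p_late[:, 1].max())
    p_capsule = float(p_late[:, 2].max())
    return FeatureProfile(
        lesion_id=lesion_id,
        p_aphe=p_aphe, p_washout=p_washout, p_capsule=p_capsule,
        B1=p_aphe >= call_threshold,
        B2=p_washout >= call_threshold,
        B3=p_capsule >= call_threshold,
        size_mm=size_mm,
    )
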