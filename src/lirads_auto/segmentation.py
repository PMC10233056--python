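"""Lesion segmentation: nested encoder–decoder network and training loop.

The network is a UNet++-style nested encoder–decoder.  The encoder is a
stack of residual blocks (optionally gated by CBAM channel+spatial attention)
separated by 2x2 max-pooling; the decoder is the nested grid of nodes
X[i][j], each fusing all same-level predecessors with the upsampled node one
level below, and the prediction is the final top-level node passed through a
1x1 convolution and a sigmoid.  Inputs are 2.5D windows (three neighbouring
axial slices as channels); the output is the centre slice's foreground
probability map.

Training minimizes the scheduled hybrid loss — soft dice + focal, with the
Lovasz–Softmax term latched in once the running training loss falls below the
configured trigger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from . import nn
from .losses import LossConfig, LovaszSchedule, segmentation_loss_and_grad
from .preprocessing import make_windows


@dataclass
class SegModelConfig:
    """Architecture hyper-parameters.

    n_down / n_up: encoder and decoder stages (must be equal; 4 at full
        scale, 2–3 for desk-scale runs).
    base_width: channels at the first stage, doubled per stage.
    attention: apply CBAM to every encoder residual block.
    input_size: (rows, cols) of each slice; must be divisible by 2**n_down.
    """

    n_down: int = 4
    n_up: int = 4
    base_width: int = 16
    attention: bool = True
    input_size: tuple[int, int] = (512, 512)
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_down != self.n_up:
            raise ValueError("n_down must equal n_up")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        div = 2**self.n_down
        if self.input_size[0] % div or self.input_size[1] % div:
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2^{self.n_down} = {div}"
            )


@dataclass
class BinaryMask:
    values: np.ndarray
    threshold_used: float


class NestedUNet(nn.Module):
    """Nested encoder–decoder over 2.5D windows; returns per-pixel logits."""

    def __init__(self, config: SegModelConfig) -> None:
        rng = np.random.default_rng(config.seed)
        self.config = config
        d = config.n_down
        widths = [config.base_width * 2**i for i in range(d + 1)]
        self.widths = widths
        self.encoders = [
            nn.ResidualBlock(
                config.in_channels if i == 0 else widths[i - 1],
                widths[i],
                rng=rng,
                attention=config.attention,
            )
            for i in range(d + 1)
        ]
        self.pools = [nn.MaxPool2() for _ in range(d)]
        # decoder node (i, j), j >= 1: fuses j same-level maps + one upsample
        self.decoders = {}
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                c_in = j * widths[i] + widths[i + 1]
                self.decoders[(i, j)] = nn.ConvRelu(c_in, widths[i], rng=rng)
        self.up = nn.UpNearest2()
        self.head = nn.Conv2d(widths[0], 1, k=1, rng=rng)

    def params(self):
        out = []
        for m in self.encoders:
            out.extend(m.params())
        for m in self.decoders.values():
            out.extend(m.params())
        out.extend(self.head.params())
        return out

    def _order(self):
        d = self.config.n_down
        seq = [(i, 0) for i in range(d + 1)]
        for j in range(1, d + 1):
            seq.extend((i, j) for i in range(d + 1 - j))
        return seq

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.config.n_down
        nodes: dict = {}
        h = x
        for i in range(d + 1):
            h = self.encoders[i].forward(h if i == 0 else self.pools[i - 1].forward(nodes[(i - 1, 0)]))
            nodes[(i, 0)] = h
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                below = self.up.forward(nodes[(i + 1, j - 1)])
                cat = np.concatenate([nodes[(i, t)] for t in range(j)] + [below], axis=1)
                nodes[(i, j)] = self.decoders[(i, j)].forward(cat)
        self._nodes_shapes = {k: v.shape for k, v in nodes.items()}
        out = self.head.forward(nodes[(0, d)])
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d = self.config.n_down
        grads: dict = {k: None for k in self._nodes_shapes}

        def _add(key, g):
            if grads[key] is None:
                grads[key] = g.copy()
            else:
                grads[key] += g

        _add((0, d), self.head.backward(grad))
        for i, j in reversed(self._order()):
            g = grads[(i, j)]
            if g is None:
                g = np.zeros(self._nodes_shapes[(i, j)])
            if j == 0:
                gx = self.encoders[i].backward(g)
                if i > 0:
                    _add((i - 1, 0), self.pools[i - 1].backward(gx))
                else:
                    self._dx = gx
            else:
                w_i = self.widths[i]
                dcat = self.decoders[(i, j)].backward(g)
                for t in range(j):
                    _add((i, t), dcat[:, t * w_i : (t + 1) * w_i])
                _add((i + 1, j - 1), self.up.backward(dcat[:, j * w_i :]))
        return self._dx

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability maps, (N, rows, cols)."""
        return 1.0 / (1.0 + np.exp(-self.forward(x)))[:, 0]


def build_model(config: SegModelConfig) -> NestedUNet:
    """Construct the segmentation network for the given configuration."""
    return NestedUNet(config)


@dataclass
class TrainParams:
    steps: int = 300
    batch_size: int = 8
    lr: float = 1e-3
    seed: int = 0
    augment: bool = False


def train_steps(
    model: NestedUNet,
    windows: np.ndarray,
    labels: np.ndarray,
    loss_config: LossConfig,
    params: TrainParams,
) -> list[float]:
    """Run the optimization loop on an array of windows.

    windows: (N, 3, rows, cols) standardized inputs; labels: (N, rows, cols)
    binary centre-slice masks.  Returns the per-step scheduled-loss log.
    Batches with a visible lesion are oversampled (a window stack is mostly
    lesion-free) by sampling half of each batch from lesion-bearing windows
    when any exist.
    """
    if len(windows) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(params.seed)
    opt = nn.Adam(model.params(), lr=params.lr)
    schedule = LovaszSchedule()
    pos_idx = np.flatnonzero(labels.reshape(len(labels), -1).any(axis=1))
    log: list[float] = []
    running = np.inf
    for _ in range(params.steps):
        idx = rng.integers(0, len(windows), size=params.batch_size)
        if len(pos_idx) > 0:
            half = params.batch_size // 2
            idx[:half] = pos_idx[rng.integers(0, len(pos_idx), size=half)]
        xb = windows[idx]
        yb = labels[idx].astype(float)
        logits = model.forward(xb)
        p = 1.0 / (1.0 + np.exp(-logits[:, 0]))
        loss, dldp = segmentation_loss_and_grad(yb, p, loss_config, schedule, running)
        if not np.isfinite(loss):
            raise FloatingPointError("training loss became non-finite")
        dz = (dldp * p * (1.0 - p))[:, None]
        opt.zero_grad()
        model.backward(dz)
        opt.step()
        log.append(loss)
        running = loss if not log else float(np.mean(log[-10:]))
    return log


def train_segmentation(
    windows_by_patient: dict,
    labels_by_patient: dict,
    fold_split,
    seg_config: SegModelConfig,
    loss_config: LossConfig,
    params: TrainParams,
    folds: list[int] | None = None,
):
    """Cross-validated training: one model per fold iteration.

    For each fold k, trains on the complement and predicts the held-out
    patients.  Returns {fold: (model, loss log, {patient: prob maps})}.
    """
    results = {}
    for k in folds if folds is not None else range(fold_split.n_folds):
        train_pats, test_pats = fold_split.train_test(k)
        if not train_pats:
            raise ValueError(f"fold {k}: empty training fold")
        xs = np.concatenate([windows_by_patient[p] for p in train_pats])
        ys = np.concatenate([labels_by_patient[p] for p in train_pats])
        model = build_model(seg_config)
        log = train_steps(model, xs, ys, loss_config, params)
        preds = {
            p: _predict_windows(model, windows_by_patient[p]) for p in test_pats
        }
        results[k] = (model, log, preds)
    return results


def _predict_windows(model: NestedUNet, windows: np.ndarray, batch: int = 16) -> np.ndarray:
    maps = [model.predict_proba(windows[i : i + batch]) for i in range(0, len(windows), batch)]
    return np.concatenate(maps) if maps else np.zeros((0,) + windows.shape[-2:])


def predict_volume(model: NestedUNet, study, phase: str = "delayed") -> np.ndarray:
    """Per-slice foreground probability maps for one phase of a study.

    The volume is normalized and standardized, cut into 2.5D windows, and
    each interior slice receives its window's prediction; the two boundary
    slices copy the nearest interior prediction, so an S-slice volume yields
    S probability maps.
    """
    from .preprocessing import normalize_intensity, standardize

    if phase not in study.phases:
        raise KeyError(f"phase {phase!r} missing from study {study.patient_id}")
    vol = standardize(normalize_intensity(study.phases[phase]).voxels)
    wins = make_windows(vol)
    stack = np.stack([w.slices for w in wins])
    interior = _predict_windows(model, stack)
    return np.concatenate([interior[:1], interior, interior[-1:]])


def binarize(prob_map: np.ndarray, threshold: float) -> BinaryMask:
    """Threshold a probability map: pixel = 1 iff probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return BinaryMask(values=(np.asarray(prob_map) >= threshold).astype(np.uint8),
                      threshold_used=float(threshold))


def extract_components(mask: BinaryMask | np.ndarray, min_voxels: int = 5):
    """Label connected lesion components under face connectivity.

    Components smaller than ``min_voxels`` are dropped (speckle suppression;
    set 1 to keep everything).  Returns (labelled array, list of component
    labels kept).
    """
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    structure = ndi.generate_binary_structure(values.ndim, 1)  # faces only
    labelled, n = ndi.label(values > 0, structure=structure)
    kept = []
    for lab in range(1, n + 1):
        size = int((labelled == lab).sum())
        if size >= min_voxels:
            kept.append(lab)
        else:
            labelled[labelled == lab] = 0
    return labelled, kept
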