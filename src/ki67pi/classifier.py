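"""Binary fragment classifiers and majority-vote ensembling.

Two classifiers share the :class:`PredictionMap` contract:

* ``tiny_cnn`` — a compact three-block convolutional network (conv-relu-pool
  x2, conv-relu, global average pooling, single-logit head) trained with
  Adam on binary cross-entropy, implemented directly on numpy so training is
  exactly reproducible from a seed on any machine.  It is sized for CPU
  training on fragment sets of a few hundred to a few thousand examples.
* a deterministic stained-fraction heuristic — labels a fragment positive
  when enough of its pixels carry appreciable stain density in either
  channel.  It involves no training, which makes the downstream ROI and
  segmentation stages testable in isolation.

Three same-window models combine by per-fragment majority vote (a fragment
is positive when at least 2 of the 3 component models say so).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ki67pi.fragments import FragmentGrid, extract_all_fragments
from ki67pi.io_annotations import SlideImage
from ki67pi.segmentation import rgb_to_hed

ARCHITECTURES = ("tiny_cnn",)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of one fragment-classifier training run."""

    architecture: str = "tiny_cnn"
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 50
    bn_momentum: float = 0.1  # echoed for provenance; tiny_cnn has no batch norm
    valid_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; available: {ARCHITECTURES}"
            )
        if not 0.0 < self.valid_fraction < 1.0:
            raise ValueError("valid_fraction must be in (0, 1)")
        for name in ("learning_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ModelArtifact:
    """Trained weights plus config echo and per-epoch training log."""

    params: dict[str, np.ndarray]
    config: TrainingConfig
    input_size: int
    log: list[dict] = field(default_factory=list)
    best_val_loss: float = np.inf

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "config": self.config.__dict__,
            "input_size": self.input_size,
            "log": self.log,
            "best_val_loss": self.best_val_loss,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "ModelArtifact":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            params=params,
            config=TrainingConfig(**meta["config"]),
            input_size=int(meta["input_size"]),
            log=meta["log"],
            best_val_loss=float(meta["best_val_loss"]),
        )


@dataclass
class PredictionMap:
    """Per-fragment scores in [0, 1] with 0.5-thresholded binary labels."""

    grid: FragmentGrid
    scores: np.ndarray
    labels: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64).ravel()
        if self.scores.shape[0] != len(self.grid):
            raise ValueError(
                f"{self.scores.shape[0]} scores for {len(self.grid)} grid origins"
            )
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("scores must lie in [0, 1]")
        if self.labels is None:
            self.labels = (self.scores >= 0.5).astype(np.int8)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
            if self.labels.shape != self.scores.shape:
                raise ValueError("labels and scores lengths differ")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["origin_row", "origin_col", "score", "label"])
            for (row, col), s, lab in zip(self.grid.origins, self.scores, self.labels):
                writer.writerow([row, col, f"{s:.6f}", int(lab)])


# ---------------------------------------------------------------------------
# tiny CNN on numpy


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


def _init_params(rng: np.random.Generator) -> dict[str, np.ndarray]:
    p = {}
    for name, (cin, cout) in {"conv1": (3, 8), "conv2": (8, 16), "conv3": (16, 32)}.items():
        p[f"{name}_w"] = _he_init(rng, (3, 3, cin, cout), 9 * cin)
        p[f"{name}_b"] = np.zeros(cout)
    p["fc_w"] = _he_init(rng, (32, 1), 32)
    p["fc_b"] = np.zeros(1)
    return p


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patches of (N,H,W,C) as (N,H,W,3,3,C)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # (N, H, W, C, 3, 3) -> (N, H, W, 3, 3, C)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    N, H, W_, C = x.shape
    cols = _im2col(x).reshape(N * H * W_, 9 * C)
    y = cols @ w.reshape(9 * C, -1) + b
    return y.reshape(N, H, W_, -1), cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray):
    N, H, W_, C = x_shape
    F = w.shape[-1]
    dy_flat = dy.reshape(N * H * W_, F)
    dw = (cols.T @ dy_flat).reshape(w.shape)
    db = dy_flat.sum(axis=0)
    dcols = (dy_flat @ w.reshape(9 * C, F).T).reshape(N, H, W_, 3, 3, C)
    dxp = np.zeros((N, H + 2, W_ + 2, C))
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + H, j : j + W_, :] += dcols[:, :, :, i, j, :]
    return dxp[:, 1 : 1 + H, 1 : 1 + W_, :], dw, db


def _pool_forward(x: np.ndarray):
    N, H, W_, C = x.shape
    H2, W2 = H // 2, W_ // 2
    xc = x[:, : 2 * H2, : 2 * W2, :]
    r = xc.reshape(N, H2, 2, W2, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(N, H2, W2, C, 4)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def _pool_backward(dy: np.ndarray, cache):
    idx, x_shape = cache
    N, H, W_, C = x_shape
    H2, W2 = H // 2, W_ // 2
    dr = np.zeros((N, H2, W2, C, 4))
    np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
    dxc = dr.reshape(N, H2, W2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(N, 2 * H2, 2 * W2, C)
    dx = np.zeros(x_shape)
    dx[:, : 2 * H2, : 2 * W2, :] = dxc
    return dx


def _forward(params: dict, x: np.ndarray, want_cache: bool = False):
    c1, cols1 = _conv_forward(x, params["conv1_w"], params["conv1_b"])
    a1 = np.maximum(c1, 0)
    p1, pc1 = _pool_forward(a1)
    c2, cols2 = _conv_forward(p1, params["conv2_w"], params["conv2_b"])
    a2 = np.maximum(c2, 0)
    p2, pc2 = _pool_forward(a2)
    c3, cols3 = _conv_forward(p2, params["conv3_w"], params["conv3_b"])
    a3 = np.maximum(c3, 0)
    g = a3.mean(axis=(1, 2))  # global average pool -> (N, 32)
    z = g @ params["fc_w"] + params["fc_b"]  # (N, 1)
    if not want_cache:
        return z[:, 0]
    cache = (x, c1, cols1, a1, p1, pc1, c2, cols2, a2, p2, pc2, c3, cols3, a3, g)
    return z[:, 0], cache


def _backward(params: dict, cache, dz: np.ndarray) -> dict[str, np.ndarray]:
    (x, c1, cols1, a1, p1, pc1, c2, cols2, a2, p2, pc2, c3, cols3, a3, g) = cache
    grads: dict[str, np.ndarray] = {}
    dz = dz[:, None]  # (N, 1)
    grads["fc_w"] = g.T @ dz
    grads["fc_b"] = dz.sum(axis=0)
    dg = dz @ params["fc_w"].T  # (N, 32)
    n_spatial = a3.shape[1] * a3.shape[2]
    da3 = np.broadcast_to(dg[:, None, None, :], a3.shape) / n_spatial
    dc3 = da3 * (c3 > 0)
    dp2, grads["conv3_w"], grads["conv3_b"] = _conv_backward(dc3, cols3, p2.shape, params["conv3_w"])
    da2 = _pool_backward(dp2, pc2)
    dc2 = da2 * (c2 > 0)
    dp1, grads["conv2_w"], grads["conv2_b"] = _conv_backward(dc2, cols2, p1.shape, params["conv2_w"])
    da1 = _pool_backward(dp1, pc1)
    dc1 = da1 * (c1 > 0)
    _, grads["conv1_w"], grads["conv1_b"] = _conv_backward(dc1, cols1, x.shape, params["conv1_w"])
    return grads


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(z: np.ndarray, y: np.ndarray) -> float:
    # numerically stable binary cross-entropy on logits
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def _scores_batched(params: dict, x: np.ndarray, batch: int = 64) -> np.ndarray:
    out = np.empty(x.shape[0])
    for start in range(0, x.shape[0], batch):
        out[start : start + batch] = _sigmoid(_forward(params, x[start : start + batch]))
    return out


def train_model(
    fragments: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    config: TrainingConfig | None = None,
) -> ModelArtifact:
    """Train the compact CNN on labeled fragments.

    ``fragments`` is (N, w, w, 3) uint8 (or float in [0, 1]); per-channel
    scaling to [0, 1] is the only input normalization.  The pool is split
    into training and validation subsets at ratio (1 - valid_fraction) :
    valid_fraction, stratified by label so neither subset is single-class.
    After each epoch the model is evaluated on the validation subset and a
    checkpoint of the weights is kept only when the validation loss improved;
    the returned artifact carries the best checkpoint.  Fully deterministic
    given ``config.seed``.
    """
    config = config or TrainingConfig()
    x = np.asarray(fragments)
    if x.ndim != 4 or x.shape[3] != 3 or x.shape[1] != x.shape[2]:
        raise ValueError(f"expected (N, w, w, 3) fragments, got shape {x.shape}")
    y = np.asarray(labels, dtype=np.float64).ravel()
    if y.shape[0] != x.shape[0]:
        raise ValueError("fragments and labels lengths differ")
    if x.shape[0] == 0:
        raise ValueError("empty training pool")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(
            "training pool must contain both classes; "
            f"got labels {sorted(classes.tolist())}"
        )
    x = x.astype(np.float64) / 255.0 if x.dtype == np.uint8 else x.astype(np.float64)

    rng = np.random.default_rng(config.seed)
    # stratified validation split
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(config.valid_fraction * idx.size)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    train_idx = np.concatenate(train_idx)
    val_idx = np.concatenate(val_idx)
    if train_idx.size == 0:
        raise ValueError("training split empty; pool too small for valid_fraction")
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_va, y_va = x[val_idx], y[val_idx]

    params = _init_params(rng)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_params = {k: v.copy() for k, v in params.items()}
    best_val = np.inf
    log: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(x_tr.shape[0])
        epoch_losses = []
        for start in range(0, order.size, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            z, cache = _forward(params, xb, want_cache=True)
            epoch_losses.append(_bce(z, yb))
            dz = (_sigmoid(z) - yb) / yb.size
            grads = _backward(params, cache, dz)
            step += 1
            for k in params:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                m_hat = adam_m[k] / (1 - beta1**step)
                v_hat = adam_v[k] / (1 - beta2**step)
                params[k] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        z_va = np.concatenate(
            [_forward(params, x_va[s : s + 64]) for s in range(0, x_va.shape[0], 64)]
        )
        val_loss = _bce(z_va, y_va)
        val_acc = float(np.mean((_sigmoid(z_va) >= 0.5) == (y_va == 1)))
        improved = val_loss < best_val
        if improved:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
                "checkpointed": improved,
            }
        )

    return ModelArtifact(
        params=best_params,
        config=config,
        input_size=int(x.shape[1]),
        log=log,
        best_val_loss=float(best_val),
    )


def predict(model: ModelArtifact, image: SlideImage, grid: FragmentGrid) -> PredictionMap:
    """Score every grid fragment with a trained model."""
    if grid.window != model.input_size:
        raise ValueError(
            f"grid window {grid.window} does not match model input size {model.input_size}"
        )
    frags = extract_all_fragments(image, grid).astype(np.float64) / 255.0
    scores = np.clip(_scores_batched(model.params, frags), 0.0, 1.0)
    return PredictionMap(grid=grid, scores=scores)


def validation_accuracy(model: ModelArtifact) -> float:
    """Best checkpoint's validation accuracy from the training log."""
    checkpointed = [e for e in model.log if e["checkpointed"]]
    if not checkpointed:
        raise ValueError("model has no checkpoint events")
    return checkpointed[-1]["val_acc"]


# ---------------------------------------------------------------------------
# deterministic heuristic classifier


def heuristic_classify(
    image: SlideImage,
    grid: FragmentGrid,
    min_stained_fraction: float = 0.18,
    stain_cut: float = 0.02,
) -> PredictionMap:
    """Label a fragment positive when enough of it carries stain.

    A pixel counts as stained when its DAB or hematoxylin optical density
    exceeds ``stain_cut``; a fragment is positive when its stained-pixel
    fraction reaches ``min_stained_fraction``.  Dense tumor clusters clear
    that bar easily while isolated lymphocytes and compact artifact blobs —
    small relative to the window — do not, which is the discrimination the
    trained classifier learns from texture.  Scores are the stained fraction
    scaled so the label threshold sits at 0.5.

    ``min_stained_fraction`` picks the operating point: the default 0.18
    rejects artifact blobs (emulating the trained model) at the price of
    trimming cluster-edge windows, while a low cut around the area of a
    single nucleus (~0.01 for a 96 px window) approximates the
    "at least one relevant cell" labeling rule itself.
    """
    if not 0.0 < min_stained_fraction <= 1.0:
        raise ValueError("min_stained_fraction must be in (0, 1]")
    dab, hema = rgb_to_hed(image)
    stained = ((dab > stain_cut) | (hema > stain_cut)).astype(np.float64)
    # summed-area table for O(1) window sums
    sat = np.zeros((stained.shape[0] + 1, stained.shape[1] + 1))
    sat[1:, 1:] = stained.cumsum(axis=0).cumsum(axis=1)
    w = grid.window
    origins = grid.origins
    r, c = origins[:, 0], origins[:, 1]
    sums = sat[r + w, c + w] - sat[r, c + w] - sat[r + w, c] + sat[r, c]
    fraction = sums / (w * w)
    scores = np.clip(fraction / (2.0 * min_stained_fraction), 0.0, 1.0)
    return PredictionMap(grid=grid, scores=scores)


def ensemble_vote(maps: Sequence[PredictionMap]) -> PredictionMap:
    """Per-fragment majority vote of exactly 3 same-grid prediction maps.

    A fragment's ensemble label is 1 when at least 2 component models label
    it 1.  Reported scores are the mean of the component scores, but labels
    come from the vote, not from thresholding that mean.
    """
    if len(maps) != 3:
        raise ValueError(f"ensemble requires exactly 3 prediction maps, got {len(maps)}")
    grid = maps[0].grid
    if any(m.grid != grid for m in maps[1:]):
        raise ValueError("prediction maps were made on different grids")
    votes = np.stack([m.labels for m in maps])
    labels = (votes.sum(axis=0) >= 2).astype(np.int8)
    scores = np.clip(np.stack([m.scores for m in maps]).mean(axis=0), 0.0, 1.0)
    return PredictionMap(grid=grid, scores=scores, labels=labels)
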