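"""3-D convolutional regression network predicting CytAct from tumor cubes.

A small sequential CNN — repeated [conv 3x3x3 -> ReLU -> max-pool 2] blocks,
global average pooling and a single linear output — trained with Adam on a
mean-squared-error loss.  Convolutions are evaluated as im2col matrix
products so training runs at desk scale on one CPU; all randomness flows
from integer seeds, making runs reproducible.

Training follows k-fold cross-validation: the cohort is partitioned by a
seeded shuffle, each fold's model is trained on rotation-augmented copies of
the other folds only (no augmented copy of a validation sample ever enters
training), and predictions are pooled out-of-fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cubes import AugmentationPolicy, TumorCube, random_rotate


class CNNError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# layers  (activations are channels-last: (B, D, H, W, C))
# ---------------------------------------------------------------------------

_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


def _shifted(xp: np.ndarray, off: tuple[int, int, int], d: int, h: int, w: int) -> np.ndarray:
    i, j, k = off
    return xp[:, i:i + d, j:j + h, k:k + w, :]


class Conv3D:
    """3x3x3 same-padding convolution, evaluated as 27 offset GEMMs.

    ``first_layer`` marks the network input layer, where the gradient with
    respect to the input is never needed and is skipped.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 first_layer: bool = False):
        scale = np.sqrt(2.0 / (c_in * 27))  # He initialization
        self.w = (rng.standard_normal((27, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.first_layer = first_layer
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, d, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        out = np.empty((b, d, h, w, self.w.shape[2]), dtype=np.float32)
        out[...] = self.b
        for o, off in enumerate(_OFFSETS):
            xs = _shifted(xp, off, d, h, w).reshape(-1, c)
            out += (xs @ self.w[o]).reshape(b, d, h, w, -1)
        if train:
            self._cache = (xp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        xp, xshape = self._cache
        b, d, h, w, c = xshape
        f = self.w.shape[2]
        dflat = dout.reshape(-1, f)
        self.db = dflat.sum(axis=0)
        self.dw = np.empty_like(self.w)
        dxp = None if self.first_layer else np.zeros_like(xp)
        for o, off in enumerate(_OFFSETS):
            xs = _shifted(xp, off, d, h, w).reshape(-1, c)
            self.dw[o] = xs.T @ dflat
            if dxp is not None:
                _shifted(dxp, off, d, h, w)[...] += (dflat @ self.w[o].T).reshape(b, d, h, w, c)
        self._cache = None
        if dxp is None:
            return None
        return dxp[:, 1:-1, 1:-1, 1:-1, :]

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


class ReLU:
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class MaxPool2:
    """2x2x2 max pooling, stride 2; gradients split evenly among ties."""

    def forward(self, x, train=True):
        b, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise CNNError(f"max-pool needs even spatial dims, got {(d, h, w)}")
        x6 = x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
        out = x6.max(axis=(2, 4, 6))
        if train:
            self._cache = (x6, out)
        return out

    def backward(self, dout):
        x6, out = self._cache
        big = out[:, :, None, :, None, :, None, :]
        mask = x6 == big
        counts = mask.sum(axis=(2, 4, 6), keepdims=True)
        dx6 = mask * (dout[:, :, None, :, None, :, None, :] / counts)
        b, c = x6.shape[0], x6.shape[7]
        d, h, w = x6.shape[1] * 2, x6.shape[3] * 2, x6.shape[5] * 2
        self._cache = None
        return dx6.reshape(b, d, h, w, c).astype(np.float32)

    def params(self):
        return []

    def grads(self):
        return []


class GlobalAvgPool:
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout):
        b, d, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, None, :] / (d * h * w), self._shape
        ).astype(np.float32).copy()

    def params(self):
        return []

    def grads(self):
        return []


class Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    The defaults are deliberately small: three conv blocks (4, 8, 16
    channels), 16-voxel cubes, 3 epochs of Adam at 1e-3 over the
    15-fold-augmented training set (so roughly 48 passes over each original
    cube).  Every field is serialized with checkpoints so a run is
    reproducible from its config.
    """

    cube_vox: int = 16
    channels: tuple[int, ...] = (4, 8, 16)
    lr: float = 1e-3
    epochs: int = 3
    batch_size: int = 64
    rng_seed: int = 0
    regenerate_per_epoch: bool = False
    include_original: bool = True

    def __post_init__(self) -> None:
        self.channels = tuple(int(c) for c in self.channels)
        side = self.cube_vox
        for _ in self.channels:
            if side % 2:
                raise CNNError(f"cube_vox {self.cube_vox} not divisible by 2^{len(self.channels)}")
            side //= 2

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


class CytActNet:
    """Sequential 3-D CNN regressor; one real-valued output per cube."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng or np.random.default_rng(cfg.rng_seed)
        self.layers: list = []
        c_prev = 1
        for i, c in enumerate(cfg.channels):
            self.layers += [Conv3D(c_prev, c, rng, first_layer=(i == 0)), ReLU(), MaxPool2()]
            c_prev = c
        self.layers += [GlobalAvgPool(), Dense(c_prev, 1, rng)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dout = dpred[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(p for _, p in layer.params())
        return out

    def gradients(self):
        out = []
        for layer in self.layers:
            out.extend(layer.grads())
        return out

    def predict(self, cubes: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic inference on an (N, S, S, S) array of cubes."""
        x = np.asarray(cubes, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] != self.cfg.cube_vox:
            raise CNNError(
                f"cube shape {x.shape[-3:]} does not match config cube_vox={self.cfg.cube_vox}"
            )
        preds = []
        for i in range(0, len(x), batch_size):
            preds.append(self.forward(x[i:i + batch_size, ..., None], train=False))
        return np.concatenate(preds).astype(np.float64)

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                state[f"layer{i}.{name}"] = p
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                p[...] = state[f"layer{i}.{name}"]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.state_dict())
        path.with_suffix(".json").write_text(self.cfg.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CytActNet":
        path = Path(path)
        cfg = ModelConfig.from_json(path.with_suffix(".json").read_text())
        model = cls(cfg)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
            model.load_state_dict(dict(f))
        return model


class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _fit(model: CytActNet, x: np.ndarray, y: np.ndarray,
         cfg: ModelConfig, rng: np.random.Generator) -> list[float]:
    """Adam / MSE training loop; returns per-epoch mean training losses."""
    opt = Adam(model.parameters(), lr=cfg.lr)
    n = len(x)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            xb = x[sel][..., None]
            yb = y[sel]
            pred = model.forward(xb, train=True)
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise CNNError("training diverged: non-finite loss")
            model.backward(2.0 * resid / len(sel))
            opt.step(model.gradients())
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def _sample_seed(base_seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), *map(int, keys)]).generate_state(1)[0] % (2**31))


def _augment(cube: TumorCube, policy: AugmentationPolicy, seed: int) -> np.ndarray:
    pol = AugmentationPolicy(
        n_copies=policy.n_copies, angle_range_deg=policy.angle_range_deg, rng_seed=seed
    )
    return np.stack([c.data for c in random_rotate(cube, pol)])


@dataclass
class CVResult:
    """Pooled out-of-fold predictions from k-fold cross-validation."""

    oof_pred: np.ndarray
    fold_id: np.ndarray
    fold_train_loss: list[list[float]]
    fold_val_loss: list[float]
    pooled_spearman: float
    pooled_spearman_p: float


def assign_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded near-equal partition; fold sizes differ by at most 1."""
    if folds < 2:
        raise CNNError("folds must be >= 2")
    if n < folds:
        raise CNNError(f"need at least {folds} samples for {folds}-fold CV, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    fold_id = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, folds)):
        fold_id[chunk] = k
    return fold_id


def train_cv(
    cubes: Sequence[TumorCube],
    targets: Sequence[float],
    cfg: ModelConfig | None = None,
    folds: int = 10,
    policy: AugmentationPolicy | None = None,
    verbose: bool = False,
) -> tuple[CVResult, list[CytActNet]]:
    """k-fold cross-validated training with rotation augmentation.

    Each fold's network trains on the augmented copies (plus originals, by
    default) of the other folds' samples only; validation samples are
    predicted unaugmented, giving one out-of-fold prediction per sample.
    """
    cfg = cfg or ModelConfig()
    policy = policy or AugmentationPolicy(rng_seed=cfg.rng_seed)
    y = np.asarray(targets, dtype=np.float32)
    if len(cubes) != len(y):
        raise CNNError("one target per cube required")
    n = len(cubes)
    fold_id = assign_folds(n, folds, cfg.rng_seed)

    raw = np.stack([c.data for c in cubes]).astype(np.float32)
    if raw.shape[-1] != cfg.cube_vox:
        raise CNNError(f"cube side {raw.shape[-1]} != config cube_vox {cfg.cube_vox}")

    aug: np.ndarray | None = None
    if not cfg.regenerate_per_epoch:
        aug = np.stack([
            _augment(c, policy, _sample_seed(policy.rng_seed, i)) for i, c in enumerate(cubes)
        ])  # (N, n_copies, S, S, S)

    oof = np.full(n, np.nan)
    models: list[CytActNet] = []
    fold_train_loss: list[list[float]] = []
    fold_val_loss: list[float] = []

    for k in range(folds):
        val = fold_id == k
        tr = ~val
        tr_idx = np.flatnonzero(tr)
        model = CytActNet(cfg, rng=np.random.default_rng(_sample_seed(cfg.rng_seed, 1000 + k)))
        rng = np.random.default_rng(_sample_seed(cfg.rng_seed, 2000 + k))

        if cfg.regenerate_per_epoch:
            history = []
            for epoch in range(cfg.epochs):
                parts = [
                    _augment(cubes[i], policy, _sample_seed(policy.rng_seed, i, epoch))
                    for i in tr_idx
                ]
                xs = np.concatenate(
                    ([raw[tr]] if cfg.include_original else []) + [np.concatenate(parts)]
                )
                ys = np.concatenate(
                    ([y[tr]] if cfg.include_original else [])
                    + [np.repeat(y[tr_idx], policy.n_copies)]
                )
                one = ModelConfig(**{**asdict(cfg), "epochs": 1})
                history += _fit(model, xs, ys, one, rng)
        else:
            xs_parts = [aug[tr].reshape(-1, *raw.shape[1:])]
            ys_parts = [np.repeat(y[tr], policy.n_copies)]
            if cfg.include_original:
                xs_parts.insert(0, raw[tr])
                ys_parts.insert(0, y[tr])
            history = _fit(model, np.concatenate(xs_parts), np.concatenate(ys_parts), cfg, rng)

        pred = model.predict(raw[val])
        oof[val] = pred
        fold_train_loss.append(history)
        fold_val_loss.append(float(np.mean((pred - y[val]) ** 2)))
        models.append(model)
        if verbose:
            print(f"fold {k}: train_loss={history[-1]:.4f} val_mse={fold_val_loss[-1]:.4f}")

    if np.ptp(oof) > 0 and np.ptp(y) > 0:
        rho, p = sps.spearmanr(oof, y)
    else:  # constant targets or predictions: correlation undefined
        rho, p = np.nan, np.nan
    return (
        CVResult(
            oof_pred=oof,
            fold_id=fold_id,
            fold_train_loss=fold_train_loss,
            fold_val_loss=fold_val_loss,
            pooled_spearman=float(rho),
            pooled_spearman_p=float(p),
        ),
        models,
    )


def predict_cytact(models: Sequence[CytActNet], cube: TumorCube | np.ndarray) -> float | np.ndarray:
    """Ensemble-mean prediction over the fold models (deterministic)."""
    if not models:
        raise CNNError("no models given")
    data = cube.data if isinstance(cube, TumorCube) else np.asarray(cube)
    preds = np.stack([m.predict(data) for m in models])
    out = preds.mean(axis=0)
    return float(out[0]) if out.size == 1 else out


def save_ensemble(models: Sequence[CytActNet], run_dir: str | Path) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for k, m in enumerate(models):
        m.save(run_dir / f"fold{k:02d}.npz")


def load_ensemble(run_dir: str | Path) -> list[CytActNet]:
    run_dir = Path(run_dir)
    paths = sorted(run_dir.glob("fold*.npz"))
    if not paths:
        raise CNNError(f"no checkpoints found in {run_dir}")
    return [CytActNet.load(p) for p in paths]
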