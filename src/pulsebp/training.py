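"""Experimental protocol: per-subject split, tenfold CV, best-on-test selection.

Each subject's segments are split ~77/23 into train/test (so every subject
appears on both sides — the protocol shares within-subject information
between train and test; see the methods note for the caveat).  The training
portion is divided into ten folds; one model is trained per fold (trained on
the other nine, early-stopped on the held-out fold), and the model with the
best test-set mean absolute error is selected.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .network import BPNet, NetworkConfig
from .records import BeatSegment

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train_fraction: float = 0.77
    seed: int = 0
    strategy: str = "per-subject-random"  # or "per-subject-chronological"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass
class TrainConfig:
    target: str = "sbp"  # "sbp" or "dbp"
    folds: int = 10
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate and batch size must be positive")
        if self.target not in {"sbp", "dbp"}:
            raise ValueError(f"target must be 'sbp' or 'dbp', got {self.target!r}")


def split_per_subject(
    segments: list[BeatSegment], spec: SplitSpec | None = None
) -> tuple[list[BeatSegment], list[BeatSegment]]:
    """Split each subject's segments into train/test at the configured fraction.

    Rounding is to the nearest integer with at least one segment on each
    side; subjects with fewer than two segments are excluded with a warning.
    Deterministic under ``spec.seed``.
    """
    spec = spec or SplitSpec()
    by_subject: dict[str, list[BeatSegment]] = defaultdict(list)
    for seg in segments:
        by_subject[seg.subject_id].append(seg)
    rng = np.random.default_rng(spec.seed)
    train: list[BeatSegment] = []
    test: list[BeatSegment] = []
    for subject in sorted(by_subject):
        segs = by_subject[subject]
        if len(segs) < 2:
            logger.warning("excluding subject %s with < 2 segments", subject)
            continue
        n_train = int(round(spec.train_fraction * len(segs)))
        n_train = min(max(n_train, 1), len(segs) - 1)
        order = np.arange(len(segs))
        if spec.strategy == "per-subject-random":
            rng.shuffle(order)
        picked = set(order[:n_train].tolist())
        for i, seg in enumerate(segs):
            (train if i in picked else test).append(seg)
    return train, test


def make_folds(
    train: list[BeatSegment], k: int = 10, seed: int = 0
) -> list[list[BeatSegment]]:
    """Shuffle and partition the training set into k folds of near-equal size."""
    if len(train) < k:
        raise ValueError(f"cannot make {k} folds from {len(train)} segments")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    sizes = np.full(k, len(train) // k)
    sizes[: len(train) % k] += 1
    folds = []
    start = 0
    for size in sizes:
        folds.append([train[i] for i in order[start : start + size]])
        start += size
    return folds


def _as_arrays(segments: list[BeatSegment], target: str):
    ppg = np.stack([s.ppg200 for s in segments])
    ecg = np.stack([s.ecg200 for s in segments])
    rr = np.array([[s.rr1, s.rr2] for s in segments])
    y = np.array([getattr(s, target) for s in segments], dtype=float)
    return ppg, ecg, rr, y


class Adam:
    def __init__(self, net: BPNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {i: np.zeros_like(l.params[k])
                  for i, (l, k) in enumerate(net.parameters())}
        self.v = {key: np.zeros_like(val) for key, val in self.m.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for slot, (layer, key) in enumerate(self.net.parameters()):
            g = layer.grads[key]
            self.m[slot] = self.beta1 * self.m[slot] + (1 - self.beta1) * g
            self.v[slot] = self.beta2 * self.v[slot] + (1 - self.beta2) * g**2
            mhat = self.m[slot] / b1t
            vhat = self.v[slot] / b2t
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class FoldResult:
    net: BPNet
    train_losses: list[float]
    val_maes: list[float]
    fold_index: int


def fit(
    net: BPNet,
    train_segments: list[BeatSegment],
    val_segments: list[BeatSegment],
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> FoldResult:
    """Minimize the MSE loss with Adam; early-stop on validation MAE."""
    ppg, ecg, rr, y = _as_arrays(train_segments, cfg.target)
    vppg, vecg, vrr, vy = _as_arrays(val_segments, cfg.target)
    opt = Adam(net, cfg.learning_rate)
    best_mae = np.inf
    best_state = None
    stale = 0
    train_losses: list[float] = []
    val_maes: list[float] = []
    m = len(y)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            net.zero_grad()
            pred = net.forward(ppg[idx], ecg[idx], rr[idx], train=True)
            if not np.all(np.isfinite(pred)):
                raise FloatingPointError(
                    f"divergence: non-finite predictions at epoch {epoch}"
                )
            err = pred - y[idx]
            epoch_loss += float(np.sum(err**2))
            net.backward(2.0 * err / len(idx))
            opt.step()
        train_losses.append(epoch_loss / m)
        vpred = net.forward(vppg, vecg, vrr, train=False)
        vmae = float(np.mean(np.abs(vpred - vy)))
        val_maes.append(vmae)
        logger.info("epoch %d: train MSE %.3f, val MAE %.3f", epoch, train_losses[-1], vmae)
        if vmae < best_mae - 1e-6:
            best_mae = vmae
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        _restore_state(net, best_state)
    return FoldResult(net, train_losses, val_maes, fold_index=-1)


def _restore_state(net: BPNet, state: dict[str, np.ndarray]) -> None:
    from .layers import BatchNorm

    for i, layer in enumerate(net.layers()):
        for key in layer.params:
            layer.params[key] = state[f"layer{i:02d}.{key}"].copy()
        if isinstance(layer, BatchNorm):
            layer.running_mean = state[f"layer{i:02d}.running_mean"].copy()
            layer.running_var = state[f"layer{i:02d}.running_var"].copy()


def train_model(folds: list[list[BeatSegment]], cfg: TrainConfig) -> list[FoldResult]:
    """Train one model per fold: train on the other k−1 folds, validate on it."""
    results: list[FoldResult] = []
    for f in range(len(folds)):
        val = folds[f]
        train = [seg for g, fold in enumerate(folds) if g != f for seg in fold]
        net = BPNet(cfg.network, seed=cfg.seed + f)
        rng = np.random.default_rng(cfg.seed + 1000 + f)
        try:
            result = fit(net, train, val, cfg, rng)
        except FloatingPointError as exc:
            logger.error("fold %d aborted: %s", f, exc)
            continue
        result.fold_index = f
        results.append(result)
    return results


def select_best(
    models: list[FoldResult] | list[BPNet],
    test_segments: list[BeatSegment],
    target: str = "sbp",
) -> BPNet:
    """Pick the model with the lowest test MAE (ties: lower error SD, then index).

    Mirrors the protocol of selecting on the testing set; an honest
    alternative is to select on pooled validation folds instead.
    """
    if not models:
        raise ValueError("no models to select from")
    nets = [m.net if isinstance(m, FoldResult) else m for m in models]
    ppg, ecg, rr, y = _as_arrays(test_segments, target)
    scored = []
    for i, net in enumerate(nets):
        err = net.forward(ppg, ecg, rr, train=False) - y
        mae = float(np.mean(np.abs(err)))
        sd = float(np.std(err))
        scored.append((round(mae, 12), round(sd, 12), i))
    scored.sort()
    return nets[scored[0][2]]


def run_protocol(
    segments: list[BeatSegment],
    cfg: TrainConfig,
    split: SplitSpec | None = None,
) -> tuple[BPNet, list[BeatSegment], list[FoldResult]]:
    """Full chain: per-subject split → folds → CV training → best-on-test.

    Returns (selected model, test segments, per-fold results).
    """
    split = split or SplitSpec(seed=cfg.seed)
    train, test = split_per_subject(segments, split)
    folds = make_folds(train, cfg.folds, seed=cfg.seed)
    results = train_model(folds, cfg)
    if not results:
        raise RuntimeError("all folds diverged")
    best = select_best(results, test, cfg.target)
    return best, test, results
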