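"""Training loop with progress-based early stopping.

No validation set is used: training halts when the *training progress*

    P_k(t) = 1000 * ( sum_{t'=t-k+1..t} E_tr(t') / (k * min_{t'} E_tr(t')) - 1 )

falls below a threshold alpha, i.e. when the trailing strip of k epochs has
become (nearly) flat.  Defaults: k = 10 epochs, alpha = 0.001, at most 500
epochs.  E_tr is the epoch-mean training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn_layers as L
from .containers import LABELS, SubTrial
from .network import BranchConfig, FusionNetwork, FusionSpec, assemble, predict_proba_batch


@dataclass
class EarlyStopState:
    """Strip length, threshold and the training-error history."""

    k: int = 10
    alpha: float = 0.001
    history: list[float] = field(default_factory=list)
    overlapping: bool = True  # evaluate every epoch over the trailing strip

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("strip length k must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def t(self) -> int:
        return len(self.history)

    def record(self, error: float) -> None:
        self.history.append(float(error))


def progress_criterion(history: list[float], k: int) -> float | None:
    """P_k(t) over the trailing k epochs; ``None`` when fewer than k exist.

    A strip whose minimum error is zero means training has solved the
    problem; the progress is then defined as 0 (stop).
    """
    if k < 1:
        raise ValueError("strip length k must be >= 1")
    if len(history) < k:
        return None
    strip = np.asarray(history[-k:], dtype=float)
    if np.any(strip < 0):
        raise ValueError("training errors must be non-negative")
    m = strip.min()
    if m == 0.0:
        return 0.0
    # the ratio is >= 1 analytically; clamp float round-off on flat strips
    return max(0.0, 1000.0 * (strip.sum() / (k * m) - 1.0))


def should_stop(state: EarlyStopState) -> bool:
    """True iff P_k(t) < alpha; never true before k epochs exist."""
    if state.overlapping or state.t % state.k == 0:
        p = progress_criterion(state.history, state.k)
        return p is not None and p < state.alpha
    return False


@dataclass
class TrainConfig:
    max_epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 16
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def subtrials_to_arrays(
    subtrials: list[SubTrial], dtype=np.float32
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack sub-trials into (eeg, fnirs, labels) arrays; labels are
    0 = left, 1 = right."""
    eeg = np.stack([s.eeg.data for s in subtrials]).astype(dtype)
    fnirs = np.stack([s.fnirs.data for s in subtrials]).astype(dtype)
    y = np.array([LABELS.index(s.label) for s in subtrials])
    return eeg, fnirs, y


def fit(
    net: FusionNetwork,
    train_subtrials: list[SubTrial] | tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
    stop: EarlyStopState | None = None,
) -> tuple[FusionNetwork, list[float]]:
    """Minimize cross-entropy with Adam; halt at the early-stopping epoch
    or ``max_epochs``, whichever comes first.

    Returns the trained network and the per-epoch loss log.  Fully seeded:
    identical config, data and initial weights give an identical log.
    """
    cfg = cfg or TrainConfig()
    stop = stop or EarlyStopState()
    if isinstance(train_subtrials, tuple):
        eeg, fnirs, y = train_subtrials
    else:
        if not train_subtrials:
            raise ValueError("empty training set")
        eeg, fnirs, y = subtrials_to_arrays(train_subtrials)
    if len(eeg) == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = L.Adam(net.params(), lr=cfg.learning_rate)

    n = len(eeg)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            opt.zero_grad()
            logits = net.forward(eeg[idx], fnirs[idx], train=True, rng=rng)
            loss, grad = L.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            net.backward(grad)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        epoch_loss = float(np.average(losses, weights=weights))
        stop.record(epoch_loss)
        if should_stop(stop):
            break
    return net, list(stop.history)


class FusionModel:
    """fit/predict_proba adapter bundling a fusion network with its
    training configuration, for use as a cross-validation model factory."""

    def __init__(
        self,
        spec: FusionSpec,
        branch_cfg: BranchConfig | None = None,
        train_cfg: TrainConfig | None = None,
        k: int = 10,
        alpha: float = 0.001,
        seed: int = 0,
    ):
        self.spec = spec
        self.branch_cfg = branch_cfg or BranchConfig()
        self.train_cfg = train_cfg or TrainConfig(seed=seed)
        self.k, self.alpha = k, alpha
        self.seed = seed
        self.net: FusionNetwork | None = None
        self.loss_log: list[float] = []

    def fit(self, subtrials: list[SubTrial]) -> "FusionModel":
        self.net = assemble(self.spec, self.branch_cfg, seed=self.seed)
        stop = EarlyStopState(k=self.k, alpha=self.alpha)
        _, self.loss_log = fit(self.net, subtrials, self.train_cfg, stop)
        return self

    def predict_proba(self, subtrials: list[SubTrial]) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("model is not fitted")
        eeg, fnirs, _ = subtrials_to_arrays(subtrials)
        return predict_proba_batch(self.net, eeg, fnirs)
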