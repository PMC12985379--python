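"""Staged training of the dose and alpha/beta models.

The schedule follows a two-stage recipe: the first half of training uses
plain MSE, the second half the composite loss; the learning rate is reset
(and cosine-decayed) within each block to escape local minima. At full
scale the blocks are 4 x 28 epochs; the test preset shrinks the counts
while preserving the proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .losses import LossThresholds, LossWeights, mse
from .model import ABModel, DoseModel
from .nn import Adam

log = logging.getLogger(__name__)


@dataclass
class TrainSchedule:
    """Phase plan: a list of (n_epochs, loss_name) blocks.

    ``loss_name`` is "mse" or "custom"; the learning rate is reset at the
    start of every block and cosine-decayed within it.
    """

    phases: list[tuple[int, str]] = field(
        default_factory=lambda: [(28, "mse"), (28, "mse"),
                                 (28, "custom"), (28, "custom")])
    base_lr: float = 1e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for n, name in self.phases:
            if n <= 0 or name not in ("mse", "custom"):
                raise ValueError(f"bad phase ({n}, {name!r})")

    @property
    def total_epochs(self) -> int:
        return sum(n for n, _ in self.phases)


def test_schedule(epochs_per_block: int = 8, **overrides) -> TrainSchedule:
    """Scaled-down schedule: 2 blocks of MSE + 2 blocks of custom loss."""
    phases = [(epochs_per_block, "mse"), (epochs_per_block, "mse"),
              (epochs_per_block, "custom"), (epochs_per_block, "custom")]
    return TrainSchedule(phases=phases, **overrides)


@dataclass
class TrainingArrays:
    """In-memory dataset: stacked samples on the model grid."""

    ct: np.ndarray            # (N, gx, gy, gz) normalized CT
    energy: np.ndarray        # (N,) normalized energy
    label: np.ndarray         # (N, gx, gy, gz) scaled, masked labels
    dose_input: np.ndarray | None = None  # (N, gx, gy, gz) for alpha/beta

    def __post_init__(self) -> None:
        n = len(self.ct)
        if not (len(self.energy) == len(self.label) == n):
            raise ValueError("dataset arrays must have equal length")
        if self.dose_input is not None and len(self.dose_input) != n:
            raise ValueError("dose_input length mismatch")

    def __len__(self) -> int:
        return len(self.ct)

    def subset(self, idx) -> "TrainingArrays":
        return TrainingArrays(
            ct=self.ct[idx], energy=self.energy[idx], label=self.label[idx],
            dose_input=None if self.dose_input is None else self.dose_input[idx],
        )


def _forward(model, batch: TrainingArrays, rate: float,
             rng: np.random.Generator | None) -> Tensor:
    ct = Tensor(batch.ct)
    en = Tensor(batch.energy)
    if isinstance(model, ABModel):
        if batch.dose_input is None:
            raise ValueError("alpha/beta training requires dose_input")
        return model(ct, en, Tensor(batch.dose_input), rate=rate, rng=rng)
    return model(ct, en, rate=rate, rng=rng)


def batch_custom_loss(y: np.ndarray, y_hat: Tensor, weights: LossWeights,
                      thresholds: LossThresholds) -> Tensor:
    """Composite loss over a batch, with per-sample selection masks.

    The masked and region components use per-sample thresholds (the "sample
    maximum" is each beamlet's own maximum); per-sample means are averaged
    over the batch. Selection masks are constants of the iterate.
    """
    B = y.shape[0]
    d = y_hat - Tensor(y)
    total = (d * d).mean()
    if weights.w_mask:
        err2 = (y_hat.data - y) ** 2
        sel = err2 > thresholds.eps_sq
        n = sel.reshape(B, -1).sum(axis=1)
        w = np.where(sel, 1.0, 0.0)
        w *= (1.0 / (B * np.maximum(n, 1))).reshape((B,) + (1,) * (y.ndim - 1))
        total = total + weights.w_mask * ((d * d) * Tensor(w)).sum()
    if weights.w_depth:
        gy = y[..., 1:] - y[..., :-1]
        gyh = y_hat[..., 1:] - y_hat[..., :-1]
        dd = gyh - Tensor(gy)
        total = total + weights.w_depth * (dd * dd).mean()
    if weights.w_region:
        ymax = y.reshape(B, -1).max(axis=1).reshape((B,) + (1,) * (y.ndim - 1))
        sel = y > thresholds.theta_frac * ymax
        l = sel.reshape(B, -1).sum(axis=1)
        w = np.where(sel, 1.0, 0.0)
        w *= (1.0 / (B * np.maximum(l, 1))).reshape((B,) + (1,) * (y.ndim - 1))
        total = total + weights.w_region * ((d * d) * Tensor(w)).sum()
    return total


def _epoch_loss(model, data: TrainingArrays, loss_name: str,
                weights: LossWeights, thresholds: LossThresholds,
                batch_size: int) -> float:
    """Validation-style loss (no dropout, no updates)."""
    from .autodiff import no_grad

    losses, counts = [], []
    for lo in range(0, len(data), batch_size):
        batch = data.subset(slice(lo, lo + batch_size))
        with no_grad():
            pred = _forward(model, batch, 0.0, None)
            if loss_name == "custom":
                val = float(batch_custom_loss(batch.label.astype(float), pred,
                                              weights, thresholds).data)
            else:
                val = float(mse(Tensor(batch.label.astype(float)), pred).data)
        losses.append(val)
        counts.append(len(batch))
    return float(np.average(losses, weights=counts))


def train(
    model: DoseModel | ABModel,
    data: TrainingArrays,
    schedule: TrainSchedule,
    weights: LossWeights = LossWeights(),
    thresholds: LossThresholds = LossThresholds(),
    val_data: TrainingArrays | None = None,
    dropout_rate: float | None = None,
    verbose: bool = False,
) -> dict:
    """Run the phase plan; returns a history dict with phase checkpoints.

    History keys: ``train_loss`` and ``val_loss`` (one entry per epoch),
    ``phase`` (loss name per epoch), ``checkpoints`` (model state at each
    phase boundary). Fully seeded; aborts on a non-finite loss.
    """
    if len(data) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(schedule.seed)
    rate = model.cfg.dropout_rate if dropout_rate is None else dropout_rate
    params = model.parameters()
    opt = Adam(params, lr=schedule.base_lr)
    history = {"train_loss": [], "val_loss": [], "phase": [], "checkpoints": []}
    labels = data.label.astype(float)

    for n_epochs, loss_name in schedule.phases:
        opt = Adam(params, lr=schedule.base_lr)  # learning-rate reset
        for ep in range(n_epochs):
            # cosine decay within the block
            opt.lr = schedule.base_lr * (0.55 + 0.45 * np.cos(
                np.pi * ep / max(n_epochs - 1, 1)))
            order = rng.permutation(len(data))
            ep_loss, n_seen = 0.0, 0
            for lo in range(0, len(order), schedule.batch_size):
                idx = order[lo:lo + schedule.batch_size]
                batch = data.subset(idx)
                pred = _forward(model, batch, rate, rng)
                y = labels[idx]
                if loss_name == "custom":
                    loss = batch_custom_loss(y, pred, weights, thresholds)
                else:
                    dd = pred - Tensor(y)
                    loss = (dd * dd).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {len(history['train_loss'])}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += float(loss.data) * len(idx)
                n_seen += len(idx)
            history["train_loss"].append(ep_loss / n_seen)
            history["phase"].append(loss_name)
            if val_data is not None:
                history["val_loss"].append(_epoch_loss(
                    model, val_data, loss_name, weights, thresholds,
                    schedule.batch_size))
            else:
                history["val_loss"].append(float("nan"))
            if verbose:
                log.info("epoch %d (%s): train %.5f val %.5f",
                         len(history["train_loss"]), loss_name,
                         history["train_loss"][-1], history["val_loss"][-1])
        history["checkpoints"].append(model.state_dict())
    return history


def grid_search_weights(candidates, train_fn, val_metric) -> LossWeights:
    """Train one (scaled-down) model per candidate weight vector.

    Returns the candidate maximizing ``val_metric`` (e.g. validation gamma
    pass rate); ties are broken by smaller L1 norm of the weights, then
    lexicographically. A candidate whose training fails is skipped with a
    logged warning.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    results = []
    for w in candidates:
        try:
            m = train_fn(w)
            score = float(val_metric(m))
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            log.warning("candidate %s failed: %s", w, exc)
            continue
        results.append((score, w))
    if not results:
        raise RuntimeError("all grid-search candidates failed")
    best_score = max(s for s, _ in results)
    tied = [w for s, w in results if s == best_score]
    tied.sort(key=lambda w: (sum(w.as_tuple()), w.as_tuple()))
    return tied[0]
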