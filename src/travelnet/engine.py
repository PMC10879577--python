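"""Training engines: the traveling model and its centralized baseline.

In the traveling (cyclical-weight-transfer) paradigm a single network visits
every training center once per cycle, in an order given by a seeded travel
schedule, and trains for a fixed number of local epochs on each center's
data before moving on.  The model's weights *and* its Adam moments travel
together; nothing is aggregated and nothing is reset at center boundaries
unless explicitly requested.  The centralized baseline trains on the pooled,
globally shuffled training set with early stopping on the pooled test loss.

Both loops share one seed-derivation rule for per-epoch batch shuffling and
dropout, so that with a single training center and matched seeds they
execute the identical sequence of updates (an exact equivalence the test
suite relies on).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .cohort import ParticipantRecord, SplitCohort
from .metrics import EvalResult, auroc, best_cycle
from .network import SFCN3D, predict_scores
from .nn import Adam

__all__ = [
    "SchedulePolicy",
    "TrainConfig",
    "History",
    "HistoryEntry",
    "EarlyStopping",
    "make_travel_schedule",
    "make_batches",
    "local_update",
    "run_traveling",
    "run_centralized",
    "evaluate_pooled",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SchedulePolicy:
    """Travel-order policy.

    ``fixed`` draws one permutation with ``base_seed`` and reuses it every
    cycle; ``random`` redraws each cycle with seed ``base_seed + (cycle - 1)``
    (cycle 1 uses the base seed itself).
    """

    mode: str = "random"  # "fixed" | "random"
    base_seed: int = 42

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "random"):
            raise ValueError(f"schedule mode must be 'fixed' or 'random', got {self.mode!r}")

    def seed_for_cycle(self, cycle_index: int) -> int:
        if cycle_index < 1:
            raise ValueError("cycle_index is 1-based")
        if self.mode == "fixed":
            return self.base_seed
        return self.base_seed + (cycle_index - 1)


@dataclass(frozen=True)
class TrainConfig:
    """All training hyperparameters for either paradigm.

    Defaults follow the published protocol: Adam, batch cap 5, dropout
    handled by the network, 30 cycles/epochs; initial learning rate 0.001
    for centralized training and 0.0001 for the traveling model (small
    centers need small steps); exponential learning-rate decay once per
    epoch, where one traveling cycle counts as one epoch.
    """

    paradigm: str = "traveling"  # "traveling" | "centralized"
    initial_lr: float = 1e-4
    lr_decay_factor: float = 0.97
    batch_size_cap: int = 5
    local_epochs: int = 1
    max_cycles: int = 30
    early_stopping_patience: int | None = 10  # centralized only
    schedule: SchedulePolicy = field(default_factory=SchedulePolicy)
    data_seed: int = 0
    reset_optimizer_per_center: bool = False
    pooled_center_key: str = "pooled"  # shuffle-stream label for pooled training

    def __post_init__(self) -> None:
        if self.paradigm not in ("traveling", "centralized"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.batch_size_cap < 1:
            raise ValueError("batch_size_cap must be >= 1")

    @staticmethod
    def centralized_default(**overrides) -> "TrainConfig":
        base = dict(paradigm="centralized", initial_lr=1e-3)
        base.update(overrides)
        return TrainConfig(**base)

    @staticmethod
    def traveling_default(**overrides) -> "TrainConfig":
        base = dict(paradigm="traveling", initial_lr=1e-4, early_stopping_patience=None)
        base.update(overrides)
        return TrainConfig(**base)

    def lr_at(self, cycle_index: int) -> float:
        return self.initial_lr * self.lr_decay_factor ** (cycle_index - 1)


# ---------------------------------------------------------------------------
# history
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistoryEntry:
    cycle: int
    schedule: tuple[str, ...]
    mean_train_loss: float
    test_loss: float
    test_auroc: float
    lr: float


@dataclass
class History:
    """Per-cycle training record plus exposure accounting."""

    paradigm: str
    entries: list[HistoryEntry] = field(default_factory=list)
    exposure_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def aurocs(self) -> list[float]:
        return [e.test_auroc for e in self.entries]

    @property
    def test_losses(self) -> list[float]:
        return [e.test_loss for e in self.entries]

    @property
    def final_auroc(self) -> float:
        return self.entries[-1].test_auroc

    def best_cycle(self) -> int:
        return best_cycle(self.test_losses)

    @property
    def best_auroc(self) -> float:
        return self.entries[self.best_cycle() - 1].test_auroc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": [e.cycle for e in self.entries],
                "auroc": [e.test_auroc for e in self.entries],
                "test_loss": [e.test_loss for e in self.entries],
                "train_loss": [e.mean_train_loss for e in self.entries],
                "lr": [e.lr for e in self.entries],
                "schedule": [";".join(e.schedule) for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path, paradigm: str = "unknown") -> "History":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - message shaping
            raise ValueError(f"malformed history CSV {path}: {exc}") from exc
        required = {"cycle", "auroc", "test_loss", "lr", "schedule"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"history CSV {path} lacks columns {sorted(missing)}")
        hist = History(paradigm=paradigm)
        for row in df.itertuples(index=False):
            hist.entries.append(
                HistoryEntry(
                    cycle=int(row.cycle),
                    schedule=tuple(str(row.schedule).split(";")),
                    mean_train_loss=float(getattr(row, "train_loss", float("nan"))),
                    test_loss=float(row.test_loss),
                    test_auroc=float(row.auroc),
                    lr=float(row.lr),
                )
            )
        return hist


# ---------------------------------------------------------------------------
# schedules and batches
# ---------------------------------------------------------------------------


def make_travel_schedule(
    center_ids: Sequence[str], policy: SchedulePolicy, cycle_index: int
) -> list[str]:
    """Seeded permutation of the centers for one cycle.

    Centers are sorted lexicographically, then shuffled by an explicit
    Fisher-Yates driven by a PCG64 generator seeded per the policy — a
    fully documented procedure so schedules replay identically anywhere.
    """
    if not center_ids:
        raise ValueError("center list is empty")
    ids = sorted(center_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate center ids")
    rng = np.random.Generator(np.random.PCG64(policy.seed_for_cycle(cycle_index)))
    for i in range(len(ids) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        ids[i], ids[j] = ids[j], ids[i]
    return ids


def make_batches(
    center_records: Sequence[ParticipantRecord],
    batch_size_cap: int,
    shuffle_rng: np.random.Generator,
) -> list[list[ParticipantRecord]]:
    """Shuffle a center's records and chunk them into batches.

    The effective batch size is ``min(batch_size_cap, n_center)`` — a center
    with fewer samples than the cap contributes one small batch.  The final
    partial batch is kept, so every record appears exactly once per epoch.
    """
    if not center_records:
        raise ValueError("center has no records")
    n = len(center_records)
    size = min(batch_size_cap, n)
    order = shuffle_rng.permutation(n)
    shuffled = [center_records[i] for i in order]
    return [shuffled[i : i + size] for i in range(0, n, size)]


# ---------------------------------------------------------------------------
# local update
# ---------------------------------------------------------------------------


def local_update(
    model: SFCN3D,
    optimizer: Adam,
    records: Sequence[ParticipantRecord],
    volumes,
    local_epochs: int,
    lr: float,
    batch_size_cap: int,
    epoch_seeds: Sequence[int],
    exposure_counts: dict[str, int] | None = None,
) -> float:
    """Train in place on one center's data for ``local_epochs`` passes.

    Each epoch gets its own seed (one entry of ``epoch_seeds``) driving both
    the batch shuffle and the dropout masks, which makes a run with
    ``local_epochs=2`` identical to two chained runs with ``local_epochs=1``
    and the same seed pair.  Returns the mean per-batch training loss.
    Raises ``FloatingPointError`` with center diagnostics if the loss
    diverges.
    """
    if len(epoch_seeds) != local_epochs:
        raise ValueError("need one shuffle seed per local epoch")
    losses = []
    for epoch in range(local_epochs):
        rng = np.random.Generator(np.random.PCG64(int(epoch_seeds[epoch])))
        batches = make_batches(records, batch_size_cap, rng)
        for batch in batches:
            ids = [r.participant_id for r in batch]
            x = volumes.get_batch(ids)
            y = np.array([r.label for r in batch], dtype=np.int64)
            try:
                loss, grads = model.loss_and_grads(x, y, rng)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"diverged at center {records[0].center_id!r}, epoch {epoch + 1}: {exc}"
                ) from exc
            optimizer.step(model.named_params(), grads, lr)
            losses.append(loss)
            if exposure_counts is not None:
                for pid in ids:
                    exposure_counts[pid] = exposure_counts.get(pid, 0) + 1
    return float(np.mean(losses))


def _epoch_seeds(data_seed: int, cycle: int, center_key: str, local_epochs: int) -> list[int]:
    return [
        derive_seed(data_seed, "shuffle", cycle, center_key, epoch)
        for epoch in range(1, local_epochs + 1)
    ]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_pooled(
    model: SFCN3D, records: Sequence[ParticipantRecord], volumes
) -> EvalResult:
    """Pooled test-set AUROC and mean cross-entropy loss (evaluation mode)."""
    from .nn import cross_entropy_with_grad, softmax

    ids = [r.participant_id for r in records]
    labels = np.array([r.label for r in records], dtype=np.int64)
    x = volumes.get_batch(ids)
    # single forward pass yields both the scores and the loss
    logits = []
    for start in range(0, x.shape[0], 32):
        logits.append(model.forward(x[start : start + 32], train=False))
    logits = np.concatenate(logits)
    scores = softmax(logits.astype(np.float64))[:, 1]
    loss, _ = cross_entropy_with_grad(logits, labels)
    return EvalResult(
        auroc=auroc(scores, labels),
        mean_loss=loss,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------


class EarlyStopping:
    """Stop when the monitored loss has not improved for `patience` epochs."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = float("inf")
        self.best_epoch: int | None = None
        self._since_improve = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record one epoch's loss; return True if training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self._since_improve = 0
        else:
            self._since_improve += 1
        return self._since_improve >= self.patience


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def run_traveling(
    initial_model: SFCN3D,
    split_cohort: SplitCohort,
    volumes,
    config: TrainConfig,
    optimizer: Adam | None = None,
    callback: Callable[[int, SFCN3D, Adam], None] | None = None,
) -> History:
    """Traveling-model training for ``config.max_cycles`` cycles.

    Per cycle: draw the travel schedule, visit each center in order calling
    :func:`local_update` (weights and Adam state carried along), then
    evaluate the pooled test set.  The learning rate decays once per full
    cycle.  There is no early stopping; the history records every cycle and
    the caller may select the best one afterwards.
    """
    model = initial_model
    centers = split_cohort.train.centers
    if not centers:
        raise ValueError("no training centers")
    for cid, recs in centers.items():
        if not recs:
            raise ValueError(f"training center {cid!r} is empty")
    if optimizer is None:
        optimizer = model.make_optimizer()
    history = History(paradigm="traveling")
    test_records = split_cohort.test.records

    for cycle in range(1, config.max_cycles + 1):
        lr = config.lr_at(cycle)
        schedule = make_travel_schedule(list(centers.keys()), config.schedule, cycle)
        center_losses = []
        for center_id in schedule:
            if config.reset_optimizer_per_center:
                optimizer.reset()
            seeds = _epoch_seeds(config.data_seed, cycle, center_id, config.local_epochs)
            loss = local_update(
                model,
                optimizer,
                centers[center_id],
                volumes,
                config.local_epochs,
                lr,
                config.batch_size_cap,
                seeds,
                history.exposure_counts,
            )
            center_losses.append(loss)
        result = evaluate_pooled(model, test_records, volumes)
        history.entries.append(
            HistoryEntry(
                cycle=cycle,
                schedule=tuple(schedule),
                mean_train_loss=float(np.mean(center_losses)),
                test_loss=result.mean_loss,
                test_auroc=result.auroc,
                lr=lr,
            )
        )
        if callback is not None:
            callback(cycle, model, optimizer)
    return history


def run_centralized(
    initial_model: SFCN3D,
    split_cohort: SplitCohort,
    volumes,
    config: TrainConfig,
    optimizer: Adam | None = None,
    callback: Callable[[int, SFCN3D, Adam], None] | None = None,
) -> History:
    """Centralized baseline: pooled shuffled training with early stopping.

    Each epoch shuffles the whole training pool (seeded by the pooled
    shuffle stream), trains with the capped batch size, evaluates the test
    set, and stops once the test loss has not improved for
    ``early_stopping_patience`` epochs (or after ``max_cycles``).
    """
    model = initial_model
    pool = list(split_cohort.train.records)
    if not pool:
        raise ValueError("training pool is empty")
    if optimizer is None:
        optimizer = model.make_optimizer()
    stopper = (
        EarlyStopping(config.early_stopping_patience)
        if config.early_stopping_patience is not None
        else None
    )
    history = History(paradigm="centralized")
    test_records = split_cohort.test.records

    for epoch in range(1, config.max_cycles + 1):
        lr = config.lr_at(epoch)
        seeds = _epoch_seeds(config.data_seed, epoch, config.pooled_center_key, 1)
        loss = local_update(
            model,
            optimizer,
            pool,
            volumes,
            1,
            lr,
            config.batch_size_cap,
            seeds,
            history.exposure_counts,
        )
        result = evaluate_pooled(model, test_records, volumes)
        history.entries.append(
            HistoryEntry(
                cycle=epoch,
                schedule=(config.pooled_center_key,),
                mean_train_loss=loss,
                test_loss=result.mean_loss,
                test_auroc=result.auroc,
                lr=lr,
            )
        )
        if callback is not None:
            callback(epoch, model, optimizer)
        if stopper is not None and stopper.update(epoch, result.mean_loss):
            break
    return history
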