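"""Model-object front end: build from data, ``fit()``, get a results object.

``TravelingModel`` and ``CentralizedModel`` wrap the training engines in the
familiar modelling-package shape: construct the model from a split cohort,
a volume provider and a configuration; ``fit()`` runs the training loop and
returns a :class:`TrainingResults` carrying the trained network, the full
per-cycle history, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, SplitCohort, split_cohort
from .engine import History, TrainConfig, run_centralized, run_traveling
from .metrics import instability_index
from .network import ModelConfig, SFCN3D, build_model

__all__ = ["TravelingModel", "CentralizedModel", "TrainingResults"]


@dataclass
class TrainingResults:
    """Outcome of one training run.

    Attributes
    ----------
    history
        Per-cycle metrics (AUROC, losses, learning rate, visit order).
    network
        The trained classifier (final-cycle weights).
    config
        The training configuration that produced the run.
    """

    history: History
    network: SFCN3D
    config: TrainConfig

    @property
    def final_auroc(self) -> float:
        return self.history.final_auroc

    @property
    def best_auroc(self) -> float:
        return self.history.best_auroc

    @property
    def best_cycle(self) -> int:
        return self.history.best_cycle()

    def instability(self, window: int | None = None) -> float:
        return instability_index(self.history.aurocs, window)

    def history_frame(self) -> pd.DataFrame:
        return self.history.to_frame()

    def summary(self) -> str:
        h = self.history
        lines = [
            f"{'=' * 58}",
            f"{self.config.paradigm.capitalize()} training results",
            f"{'-' * 58}",
            f"cycles run           : {len(h)}",
            f"final-cycle AUROC    : {h.final_auroc:.4f}",
            f"best cycle (loss)    : {h.best_cycle()}",
            f"best-cycle AUROC     : {h.best_auroc:.4f}",
            f"final test loss      : {h.test_losses[-1]:.4f}",
            f"instability index    : {self.instability():.4f}" if len(h) >= 2 else "",
            f"initial lr / decay   : {self.config.initial_lr:g} / {self.config.lr_decay_factor:g}",
            f"local epochs         : {self.config.local_epochs}",
            f"schedule             : {self.config.schedule.mode} (base seed {self.config.schedule.base_seed})"
            if self.config.paradigm == "traveling"
            else f"early-stop patience  : {self.config.early_stopping_patience}",
            f"{'=' * 58}",
        ]
        return "\n".join(line for line in lines if line)


class _BaseTrainer:
    paradigm = "traveling"

    def __init__(
        self,
        data: SplitCohort | Cohort,
        volumes,
        config: TrainConfig | None = None,
        model_config: ModelConfig | None = None,
    ):
        if isinstance(data, Cohort):
            data = split_cohort(data)
        self.split = data
        self.volumes = volumes
        default = (
            TrainConfig.traveling_default()
            if self.paradigm == "traveling"
            else TrainConfig.centralized_default()
        )
        self.config = config if config is not None else default
        if self.config.paradigm != self.paradigm:
            raise ValueError(
                f"config paradigm {self.config.paradigm!r} does not match {self.paradigm!r}"
            )
        grid = getattr(volumes, "grid_size", None)
        if model_config is None:
            model_config = ModelConfig(grid_size=grid) if grid else ModelConfig()
        self.model_config = model_config

    def fit(self, start_network: SFCN3D | None = None) -> TrainingResults:
        network = start_network if start_network is not None else build_model(self.model_config)
        runner = run_traveling if self.paradigm == "traveling" else run_centralized
        history = runner(network, self.split, self.volumes, self.config)
        return TrainingResults(history=history, network=network, config=self.config)


class TravelingModel(_BaseTrainer):
    """Traveling-model (cyclical weight transfer) trainer.

    Examples
    --------
    >>> split = split_cohort(build_cohort(spec))          # doctest: +SKIP
    >>> volumes = PhantomVolumes(split.full, phantom_spec)  # doctest: +SKIP
    >>> res = TravelingModel(split, volumes).fit()          # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    paradigm = "traveling"


class CentralizedModel(_BaseTrainer):
    """Centralized baseline trainer on the pooled training set."""

    paradigm = "centralized"
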