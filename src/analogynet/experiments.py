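"""End-to-end simulations: the developmental relational shift and the
frontotemporal-lesion pattern.

Simulation 1 trains five independently seeded networks, each on its own
independently generated environment, for 350 epochs, probing all analogy
questions with the twin/echo procedure every 10 epochs (plus epoch 0).
Early in training the co-occurrence-frequency imbalance dominates: positive-
SFI questions are answered best and negative-SFI questions fall below chance.
With further training the acquired relational knowledge overrides the
association imbalance and all three question types approach ceiling — the
relational shift.

Simulation 2 takes the five trained networks and evaluates three conditions:
control (no lesion), frontal (H1 bias lowered to -6.5) and temporal
(connections removed with probability .42; five independent draws per
network, giving 25 lesioned networks). The frontal lesion selectively
re-opens the SFI effect (negative-SFI accuracy collapses toward associative
responding) while the temporal lesion depresses accuracy across the board.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from typing import Optional

import numpy as np
import pandas as pd

from .environment import Environment, EnvironmentConfig, build_environment
from .errors import InvalidConfigError
from .lesion import LesionSpec, frontal_lesion, temporal_lesion
from .network import NetworkConfig, NetworkWeights, init_network, train
from .probe import ProbeConfig, build_twin, evaluate

__all__ = [
    "ExperimentConfig",
    "Sim1Result",
    "network_config_for",
    "lesion_summary",
    "simulation1",
    "simulation2",
    "sustained_crossing_epoch",
    "plot_relational_shift",
    "plot_lesion_summary",
]

_ACC_COLS = ["accuracy_positive", "accuracy_zero", "accuracy_negative", "accuracy_overall"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol parameters shared by the two simulations."""

    n_networks: int = 5
    epochs: int = 350
    eval_every: int = 10
    seed: int = 1
    n_lesion_draws: int = 5
    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    frontal: LesionSpec = field(default_factory=lambda: LesionSpec(kind="frontal"))
    temporal: LesionSpec = field(default_factory=lambda: LesionSpec(kind="temporal"))
    net_overrides: dict = field(default_factory=dict)


@dataclass
class Sim1Result:
    records: pd.DataFrame
    weights: list[NetworkWeights]
    environments: list[Environment]
    configs: list[NetworkConfig]


def network_config_for(env_cfg: EnvironmentConfig, **overrides) -> NetworkConfig:
    """A NetworkConfig with pool sizes matching an environment config."""
    n_items = 5 * env_cfg.n_groups
    return NetworkConfig(
        n_first_role=n_items,
        n_second_role=n_items,
        n_relation=env_cfg.relation.n_units,
        **overrides,
    )


def _derive_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % 2**31)


def simulation1(cfg: ExperimentConfig, progress: bool = False) -> Sim1Result:
    """Train the five networks and record per-SFI accuracy every 10 epochs.

    Records are tidy: one row per (network, sampled epoch) with condition
    ``control`` and the four accuracy columns; epoch 0 is included to anchor
    the chance baseline.
    """
    rows: list[dict] = []
    weights_out: list[NetworkWeights] = []
    envs: list[Environment] = []
    net_cfgs: list[NetworkConfig] = []
    for i in range(cfg.n_networks):
        env_seed = _derive_seed(cfg.seed, 0, i)
        net_seed = _derive_seed(cfg.seed, 1, i)
        env = build_environment(dataclasses.replace(cfg.env, seed=env_seed))
        net_cfg = network_config_for(cfg.env, seed=net_seed, **cfg.net_overrides)
        w = init_network(net_cfg)
        questions = env.questions()

        def hook(epoch: int, weights: NetworkWeights, _q=questions) -> dict:
            return evaluate(build_twin(weights), _q, cfg.probe)

        rows.append(
            {"network_id": i, "epoch": 0, "condition": "control", "lesion_draw": None,
             "mean_loss": np.nan, **hook(0, w)}
        )
        w, history = train(
            w, env, net_cfg, cfg.epochs, eval_hook=hook, eval_every=cfg.eval_every
        )
        for rec in history:
            if "accuracy_overall" in rec:
                rows.append(
                    {"network_id": i, "epoch": rec["epoch"], "condition": "control",
                     "lesion_draw": None, "mean_loss": rec["mean_loss"],
                     **{k: rec[k] for k in _ACC_COLS}}
                )
        if progress:
            final = rows[-1]["accuracy_overall"]
            print(f"network {i}: final overall accuracy {final:.3f}")
        weights_out.append(w)
        envs.append(env)
        net_cfgs.append(net_cfg)
    return Sim1Result(
        records=pd.DataFrame(rows), weights=weights_out, environments=envs, configs=net_cfgs
    )


def simulation2(cfg: ExperimentConfig, sim1: Sim1Result) -> pd.DataFrame:
    """Evaluate control, frontal and temporal conditions on the trained nets.

    Returns tidy records: one row per (network, condition, lesion draw) with
    per-SFI accuracies. The temporal condition contributes
    ``n_networks * n_lesion_draws`` rows (default 25).
    """
    if len(sim1.weights) != cfg.n_networks:
        raise InvalidConfigError(
            f"need {cfg.n_networks} trained networks, got {len(sim1.weights)}"
        )
    rows: list[dict] = []
    for i, (w, env) in enumerate(zip(sim1.weights, sim1.environments)):
        questions = env.questions()
        control_twin = build_twin(w)
        rows.append(
            {"network_id": i, "condition": "control", "lesion_draw": None,
             **evaluate(control_twin, questions, cfg.probe)}
        )
        rows.append(
            {"network_id": i, "condition": "frontal", "lesion_draw": None,
             **evaluate(frontal_lesion(control_twin, cfg.frontal), questions, cfg.probe)}
        )
        for draw in range(cfg.n_lesion_draws):
            spec = dataclasses.replace(
                cfg.temporal, seed=_derive_seed(cfg.seed, 2, i, draw)
            )
            lesioned, mask = temporal_lesion(w, spec)
            twin = dataclasses.replace(build_twin(lesioned), lesion_mask=mask)
            rows.append(
                {"network_id": i, "condition": "temporal", "lesion_draw": draw,
                 **evaluate(twin, questions, cfg.probe)}
            )
    return pd.DataFrame(rows)


def lesion_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean per-SFI accuracy by condition, plus the SFI effect
    (positive minus negative accuracy)."""
    summary = records.groupby("condition")[_ACC_COLS].mean()
    summary["sfi_effect"] = summary["accuracy_positive"] - summary["accuracy_negative"]
    return summary.reset_index()


def sustained_crossing_epoch(
    records: pd.DataFrame, column: str = "accuracy_negative", threshold: float = 0.5
) -> Optional[int]:
    """Earliest sampled epoch at which the mean of ``column`` over networks
    exceeds ``threshold`` and stays above it at every later sample."""
    curve = records.groupby("epoch")[column].mean().sort_index()
    above = curve.values > threshold
    for k in range(len(above)):
        if above[k:].all():
            return int(curve.index[k])
    return None


def plot_relational_shift(records: pd.DataFrame, path) -> None:
    """Developmental curves: mean accuracy by SFI type over epochs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    mean = records.groupby("epoch")[_ACC_COLS].mean()
    for col, label in (
        ("accuracy_positive", "SFI > 0"),
        ("accuracy_zero", "SFI = 0"),
        ("accuracy_negative", "SFI < 0"),
    ):
        ax.plot(mean.index, mean[col], marker=".", label=label)
    ax.axhline(0.5, color="grey", linestyle="--", linewidth=1, label="chance")
    ax.set_xlabel("training epoch")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lesion_summary(records: pd.DataFrame, path) -> None:
    """Grouped bars: per-SFI accuracy by lesion condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = lesion_summary(records).set_index("condition")
    order = [c for c in ("control", "frontal", "temporal") if c in summary.index]
    labels = ["SFI > 0", "SFI = 0", "SFI < 0"]
    cols = ["accuracy_positive", "accuracy_zero", "accuracy_negative"]
    x = np.arange(len(order))
    width = 0.25
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for k, (col, label) in enumerate(zip(cols, labels)):
        ax.bar(x + (k - 1) * width, summary.loc[order, col], width, label=label)
    ax.axhline(0.5, color="grey", linestyle="--", linewidth=1)
    ax.set_xticks(x, order)
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
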