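"""Experiment drivers: meta-prior grids, the two-dimensional phase sweep,
the oscillating-meta-prior run, aggregation and heat-map plots.

The full protocol (50x50 meta-prior pairs x 5 network repeats x 1000
steps) is far beyond a single desk CPU; ``run_phase_sweep`` takes an
arbitrary subset of grid indices so coarse sweeps run in minutes while the
full grid remains expressible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .analysis import per_label_chance
from .classifier import PrimitiveClassifier
from .dyad import AgentHandle, run_interaction
from .inference import InferenceConfig, MetaPriorSchedule

__all__ = ["MetaPriorGrid", "SweepConfig", "build_meta_prior_grid",
           "run_phase_sweep", "summarize_regions", "plot_phase_grid"]


@dataclass(frozen=True)
class MetaPriorGrid:
    """n log-spaced layer-1 interaction meta-priors from w_min to w_max."""

    values: np.ndarray

    def __getitem__(self, idx: int) -> float:
        """1-based indexing, matching the w_idx naming of the sweep."""
        if not 1 <= idx <= len(self.values):
            raise IndexError(f"index {idx} outside 1..{len(self.values)}")
        return float(self.values[idx - 1])

    def __len__(self) -> int:
        return len(self.values)


def build_meta_prior_grid(w_min: float = 0.001, w_max: float = 5.0,
                          n: int = 50) -> MetaPriorGrid:
    """values[i] = w_min (w_max/w_min)^((i-1)/(n-1)), i = 1..n."""
    if not (0 < w_min < w_max):
        raise ValueError("need 0 < w_min < w_max")
    if n < 2:
        raise ValueError("n must be >= 2")
    return MetaPriorGrid(values=np.geomspace(w_min, w_max, n))


@dataclass
class SweepConfig:
    """Phase-sweep settings.

    ``indices``: 1-based grid indices to sweep for both agents (defaults to
    the whole grid).  ``repeats`` pairs network i of agent 1 with network i
    of agent 2.  ``min_run`` is the minimum synchronized run length for the
    turn detector (one primitive duration).
    """

    grid: MetaPriorGrid = field(default_factory=build_meta_prior_grid)
    indices: list[int] | None = None
    T: int = 1000
    repeats: int = 5
    base_seed: int = 0
    min_run: int = 20
    marginals1: tuple[float, float, float] = (0.5, 0.1, 0.4)
    marginals2: tuple[float, float, float] = (0.5, 0.4, 0.1)

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.indices is None:
            self.indices = list(range(1, len(self.grid) + 1))


def _cell_seed(base_seed: int, idx1: int, idx2: int, repeat: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    ss = np.random.SeedSequence([base_seed, idx1, idx2, repeat])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_phase_sweep(
    cfg: SweepConfig,
    models1: list,
    models2: list,
    classifier: PrimitiveClassifier,
    inference_cfg: InferenceConfig | None = None,
) -> pd.DataFrame:
    """Run the dyadic interaction for every meta-prior index pair.

    ``models1`` / ``models2`` are the per-repeat trained networks of each
    agent (cycled if shorter than ``repeats``).  Every cell stores, averaged
    over repeats: per-agent label frequencies, overall and per-label sync,
    turn-taking count, directed transfer entropies and the cell seed of the
    first repeat.
    """
    icfg = inference_cfg or InferenceConfig()
    rows = []
    for idx1 in cfg.indices:
        for idx2 in cfg.indices:
            acc: dict[str, list[float]] = {}
            for rep in range(cfg.repeats):
                seed = _cell_seed(cfg.base_seed, idx1, idx2, rep)
                m1 = models1[rep % len(models1)]
                m2 = models2[rep % len(models2)]
                a1 = AgentHandle(m1.params, icfg,
                                 MetaPriorSchedule(value=cfg.grid[idx1]))
                a2 = AgentHandle(m2.params, icfg,
                                 MetaPriorSchedule(value=cfg.grid[idx2]))
                trace = run_interaction(a1, a2, T=cfg.T, seed=seed)
                lab1 = classifier.label_sequence(trace.proprio[0])
                lab2 = classifier.label_sequence(trace.proprio[1])
                f1 = analysis.movement_frequency(lab1)
                f2 = analysis.movement_frequency(lab2)
                sync = analysis.synchronization_rate(lab1, lab2)
                turns = analysis.count_turn_taking(lab1, lab2,
                                                  min_run=cfg.min_run)
                te12 = analysis.transfer_entropy(lab1, lab2)
                te21 = analysis.transfer_entropy(lab2, lab1)
                vals = {
                    "freqA_1": f1[0], "freqB_1": f1[1], "freqC_1": f1[2],
                    "freqA_2": f2[0], "freqB_2": f2[1], "freqC_2": f2[2],
                    "sync_all": sync.overall,
                    "sync_A": sync.per_label[0],
                    "sync_B": sync.per_label[1],
                    "sync_C": sync.per_label[2],
                    "turns": turns, "te12": te12, "te21": te21,
                }
                for k, v in vals.items():
                    acc.setdefault(k, []).append(float(v))
            row = {"idx1": idx1, "idx2": idx2,
                   "w1": cfg.grid[idx1], "w2": cfg.grid[idx2],
                   "seed": _cell_seed(cfg.base_seed, idx1, idx2, 0)}
            row.update({k: float(np.mean(v)) for k, v in acc.items()})
            rows.append(row)
    df = pd.DataFrame(rows)
    chance = per_label_chance(np.array(cfg.marginals1), np.array(cfg.marginals2))
    df["region"] = analysis.classify_phase_regions(
        df["sync_B"].to_numpy(), df["sync_C"].to_numpy(),
        chance_b=float(chance[1]), chance_c=float(chance[2]))
    return df


def summarize_regions(cells: pd.DataFrame) -> dict:
    """Counts and index bounding boxes of the coordination regions."""
    report: dict = {"n_cells": int(len(cells)), "regions": {}}
    for region, sub in cells.groupby("region"):
        report["regions"][str(region)] = {
            "count": int(len(sub)),
            "idx1_range": [int(sub["idx1"].min()), int(sub["idx1"].max())],
            "idx2_range": [int(sub["idx2"].min()), int(sub["idx2"].max())],
            "mean_turns": float(sub["turns"].mean()),
            "mean_sync_all": float(sub["sync_all"].mean()),
        }
    return report


def save_region_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def plot_phase_grid(cells: pd.DataFrame, column: str, path: str | None = None):
    """Heat map of one per-cell statistic over the (idx1, idx2) grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = cells.pivot(index="idx2", columns="idx1", values=column)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.to_numpy(),
                       shading="nearest")
    fig.colorbar(im, ax=ax, label=column)
    ax.set_xlabel("meta-prior index, agent 1")
    ax.set_ylabel("meta-prior index, agent 2")
    ax.set_title(column)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
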