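"""Batch training of the PV-RNN by backpropagation through time.

Network weights and the per-sequence, per-step adaptive posterior
variables A are optimized jointly with Adam, minimizing the normalized
free energy summed over the training sequences.  The error term covers
all 10 channels; the complexity term uses the layered training meta-prior
(3.5, x10 per layer at full scale), overridden to 1.0 in every layer at
the first time step so the network keeps its sensitivity to the initial
latent state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .movement import Trajectory
from . import network as net
from .network import LayerSpec, NetworkParams

__all__ = ["Adam", "TrainingConfig", "TrainedModel", "train_network",
           "evaluate_preference", "select_best_networks"]


class Adam:
    """Adam over a dict of numpy arrays (used for both weights and A)."""

    def __init__(self, shapes: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, values: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            values[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps)


def clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


@dataclass
class TrainingConfig:
    """Training hyperparameters.

    Full-scale values: 70,000 epochs, lr 0.001, layer-1 training meta-prior
    3.5 (x10 per layer), weight 1.0 in all layers at t=1.  Desk-scale runs
    use far fewer epochs; pass ``epochs`` explicitly.
    """

    epochs: int = 70_000
    lr: float = 1e-3
    w_at_t1: float = 1.0
    grad_clip: float = 1.0
    seed: int = 0
    log_every: int = 100

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("epochs must be >= 1 and lr > 0")


@dataclass
class TrainedModel:
    """Trained weights plus the per-sequence training posteriors."""

    params: NetworkParams
    a_mu: list[np.ndarray]
    a_sig: list[np.ndarray]
    config: TrainingConfig
    loss_history: list[dict] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]["F"] if self.loss_history else float("nan")

    def save(self, path: str) -> None:
        self.params.save(path)
        with open(str(path) + ".log.json", "w") as fh:
            json.dump(self.loss_history, fh)


def train_network(
    dataset: list[Trajectory],
    specs: list[LayerSpec],
    cfg: TrainingConfig,
    shared_heads: bool = True,
) -> TrainedModel:
    """Train a PV-RNN on a set of equal-length trajectories (full batch).

    Raises RuntimeError with a diagnostic if the loss diverges to NaN.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    T = len(dataset[0])
    if any(len(tr) != T for tr in dataset):
        raise ValueError("all training trajectories must have equal length")
    B = len(dataset)
    targets = np.stack([tr.observations for tr in dataset])  # (B, T, 10)

    rng = np.random.default_rng(cfg.seed)
    params = net.init_params(specs, seed=cfg.seed, shared_heads=shared_heads)
    a_mu = [np.zeros((B, T, s.z_dim)) for s in specs]
    a_sig = [np.zeros((B, T, s.z_dim)) for s in specs]
    w_layers = np.array([s.w_train for s in specs])
    mask = np.ones(net.N_OUT)

    opt_p = Adam(params.data, lr=cfg.lr)
    a_values = {}
    for l in range(len(specs)):
        a_values[f"amu{l}"] = a_mu[l]
        a_values[f"asig{l}"] = a_sig[l]
    opt_a = Adam(a_values, lr=cfg.lr)

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        cache = net.forward_sequence(params, a_mu, a_sig, rng=rng)
        terms, gp, ga_mu, ga_sig = net.free_energy_and_grads(
            params, a_mu, a_sig, cache, targets, w_layers, mask,
            w_at_t1=cfg.w_at_t1)
        if not np.isfinite(terms["F"]):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: F={terms['F']}; "
                f"last finite loss: {history[-1] if history else None}")
        clip_grads(gp, cfg.grad_clip)
        ga = {f"amu{l}": ga_mu[l] for l in range(len(specs))}
        ga.update({f"asig{l}": ga_sig[l] for l in range(len(specs))})
        clip_grads(ga, cfg.grad_clip)
        opt_p.step(params.data, gp)
        opt_a.step(a_values, ga)
        if epoch % cfg.log_every == 0 or epoch == cfg.epochs - 1:
            history.append({"epoch": epoch, **{k: float(v) for k, v in terms.items()}})
    return TrainedModel(params=params, a_mu=a_mu, a_sig=a_sig, config=cfg,
                        loss_history=history)


def evaluate_preference(
    model,
    classifier,
    n_rollouts: int = 10,
    T: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Mean primitive percentages (A, B, C) of prior-generated rollouts.

    ``model`` needs a ``.params`` usable by :func:`network.prior_generate`,
    or may itself provide a ``prior_generate(T, seed)`` method (stubs).
    Rollouts are classified from their proprioceptive channels.
    """
    rng = np.random.default_rng(seed)
    fracs = np.zeros(3)
    for _ in range(n_rollouts):
        if hasattr(model, "prior_generate"):
            traj = model.prior_generate(T, rng)
        else:
            traj = net.prior_generate(model.params, T, rng)
        labels = classifier.label_sequence(traj.proprio)
        counts = np.bincount(labels, minlength=3)
        fracs += counts / counts.sum()
    return 100.0 * fracs / n_rollouts


def select_best_networks(
    candidates: list,
    evaluated: list[np.ndarray],
    target_freqs: np.ndarray,
    k: int = 5,
) -> list[int]:
    """Rank candidate networks by closeness to the target label frequencies.

    ``evaluated[i]`` are the percentages from :func:`evaluate_preference`.
    Primary key: L1 distance to ``target_freqs`` (in %); ties broken by
    lower final training free energy.  Returns indices of the best k.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if k > len(candidates):
        import warnings
        warnings.warn("k exceeds the number of candidates; returning all")
        k = len(candidates)
    target = np.asarray(target_freqs, dtype=float)
    keys = []
    for i, (cand, ev) in enumerate(zip(candidates, evaluated)):
        dist = float(np.abs(np.asarray(ev) - target).sum())
        fe = getattr(cand, "final_loss", 0.0)
        keys.append((dist, fe, i))
    keys.sort()
    return [i for _, _, i in keys[:k]]
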