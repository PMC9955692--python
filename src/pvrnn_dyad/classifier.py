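"""Echo State Network classifier for movement primitives.

A fixed sparse leaky-integrator reservoir (N=25, 25% connectivity, 60%
leakage) is driven by the 6 proprioceptive channels; a ridge-regression
readout maps the reservoir state at the end of each 12-step sliding window
(restarted from rest per window, concatenated with the window-mean input)
to a one-hot primitive label, decided by argmax.  Per the label-count
convention adopted throughout, a T-step trajectory yields T - 12 labels
(label i covers the window starting at step i; the final window is
discarded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .movement import Trajectory

__all__ = ["ESNConfig", "Reservoir", "PrimitiveClassifier",
           "build_reservoir", "fit_readout", "train_default_classifier"]


@dataclass(frozen=True)
class ESNConfig:
    reservoir_size: int = 25
    connectivity: float = 0.25
    leakage: float = 0.60
    window: int = 12
    spectral_radius: float = 0.9
    input_scale: float = 1.0
    ridge_lambda: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.connectivity <= 1:
            raise ValueError("connectivity must be in (0, 1]")
        if not 0 < self.leakage <= 1:
            raise ValueError("leakage must be in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")


class Reservoir:
    """Fixed random recurrent map with leaky-integrator state update."""

    def __init__(self, cfg: ESNConfig, n_inputs: int = 6):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        N = cfg.reservoir_size
        W = rng.uniform(-1, 1, size=(N, N))
        mask = rng.random((N, N)) < cfg.connectivity
        W = W * mask
        eig = np.max(np.abs(np.linalg.eigvals(W)))
        if eig > 0:
            W *= cfg.spectral_radius / eig
        self.W = W
        self.W_in = rng.uniform(-1, 1, size=(N, n_inputs)) * cfg.input_scale
        self.b = rng.uniform(-0.2, 0.2, size=N)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.W))

    def run(self, inputs: np.ndarray) -> np.ndarray:
        """Drive the reservoir with (T, 6) inputs; returns (T, N) states."""
        a = self.cfg.leakage
        x = np.zeros(self.cfg.reservoir_size)
        states = np.empty((inputs.shape[0], x.size))
        for t in range(inputs.shape[0]):
            drive = np.tanh(self.W @ x + self.W_in @ inputs[t] + self.b)
            x = (1 - a) * x + a * drive
            states[t] = x
        return states

    def window_states(self, proprio: np.ndarray, starts: np.ndarray,
                      window: int) -> np.ndarray:
        """Final reservoir state of each window, restarted from rest.

        Restarting per window makes the label a function of the window
        content alone.  Vectorized across windows; returns
        (len(starts), N + n_inputs) feature rows.
        """
        a = self.cfg.leakage
        n = len(starts)
        x = np.zeros((n, self.cfg.reservoir_size))
        mean_u = np.zeros((n, proprio.shape[1]))
        for k in range(window):
            u = proprio[starts + k]
            drive = np.tanh(x @ self.W.T + u @ self.W_in.T + self.b)
            x = (1 - a) * x + a * drive
            mean_u += u
        # readout features: window-end state plus the window-mean input
        return np.concatenate([x, mean_u / window], axis=1)


def build_reservoir(cfg: ESNConfig, n_inputs: int = 6) -> Reservoir:
    return Reservoir(cfg, n_inputs)


class PrimitiveClassifier:
    """Reservoir + fitted ridge readout, labeling sliding windows."""

    def __init__(self, reservoir: Reservoir, readout: Ridge):
        self.reservoir = reservoir
        self.readout = readout

    @property
    def window(self) -> int:
        return self.reservoir.cfg.window

    def label_sequence(self, proprio: np.ndarray) -> np.ndarray:
        """Per-window primitive labels of a (T, 6) trajectory.

        Returns an int array of length max(T - window, 0); label i covers
        the window starting at step i (decided from the reservoir state at
        the window's last step).
        """
        proprio = np.asarray(proprio, dtype=float)
        T = proprio.shape[0]
        w = self.window
        if T <= w:
            warnings.warn(f"trajectory of length {T} yields no labels "
                          f"(window {w})")
            return np.empty(0, dtype=int)
        starts = np.arange(T - w)  # T - w windows, final one discarded
        states = self.reservoir.window_states(proprio, starts, w)
        scores = self.readout.predict(states)
        return np.argmax(scores, axis=1).astype(int)


def _window_states_and_labels(
    reservoir: Reservoir, trajectories: list[Trajectory]
) -> tuple[np.ndarray, np.ndarray]:
    w = reservoir.cfg.window
    X, y = [], []
    for traj in trajectories:
        if traj.labels is None:
            raise ValueError("training trajectories must carry labels")
        starts = np.arange(len(traj) - w)
        X.append(reservoir.window_states(traj.proprio, starts, w))
        # majority label of each window
        y.append(np.array([
            np.argmax(np.bincount(traj.labels[s:s + w], minlength=3))
            for s in starts
        ]))
    return np.concatenate(X), np.concatenate(y)


def fit_readout(reservoir: Reservoir,
                trajectories: list[Trajectory]) -> PrimitiveClassifier:
    """Fit the one-hot ridge readout on labeled trajectories."""
    X, y = _window_states_and_labels(reservoir, trajectories)
    present = np.unique(y)
    if len(present) < 3:
        raise ValueError(f"all three primitives must appear in the training "
                         f"data; found labels {present}")
    onehot = np.eye(3)[y]
    readout = Ridge(alpha=reservoir.cfg.ridge_lambda)
    readout.fit(X, onehot)
    return PrimitiveClassifier(reservoir, readout)


def train_default_classifier(seed: int = 0, n_sequences: int = 12,
                             T: int = 400) -> PrimitiveClassifier:
    """Convenience constructor: fit the standard classifier on fresh
    synthetic trajectories from both preference machines."""
    from .movement import Primitive, generate_training_set, render_trajectory, \
        robot_fsm

    trajs = (generate_training_set(robot_fsm(1), n_sequences // 2, T, seed=seed)
             + generate_training_set(robot_fsm(2), n_sequences // 2, T,
                                     seed=seed + 1))
    # constant-primitive contexts (absent from the alternating FSM data);
    # replicated so the ridge fit does not sacrifice them to the bulk
    trajs += [render_trajectory([p] * 10) for p in Primitive] * 10
    reservoir = build_reservoir(ESNConfig(seed=seed))
    return fit_readout(reservoir, trajs)
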