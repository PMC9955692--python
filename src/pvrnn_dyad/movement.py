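"""Synthetic movement-primitive trajectories for two imitating agents.

Each agent's repertoire consists of three stereotyped movement primitives
A, B and C.  A probabilistic finite state machine alternates the
deterministic primitive A with a probabilistically chosen B or C: agent 1
prefers C after A (80/20), agent 2 prefers B (the mirror bias).  Primitives
are rendered as 6-channel joint-angle waveforms (a planar 3-joint arm per
side, values normalized to [-1, 1]); the 4-channel exteroception is the
partner's view of the two hands (forward kinematics of the mirrored
posture), with coordinates normalized by the total arm reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "Primitive",
    "PreferenceFSM",
    "PrimitiveWaveforms",
    "Trajectory",
    "LINK_LENGTHS",
    "REACH",
    "sample_primitive_sequence",
    "render_trajectory",
    "forward_kinematics",
    "observe",
    "generate_training_set",
    "robot_fsm",
]

#: link lengths of the planar 3-joint arm used for each side (unitless)
LINK_LENGTHS = (1.0, 1.0, 1.0)
#: total reach; exteroceptive coordinates are divided by this constant
REACH = float(sum(LINK_LENGTHS))

#: joint angle (normalized, [-1,1]) to radians
_JOINT_SCALE = np.pi / 2.0


class Primitive(IntEnum):
    """The three movement primitives, with a fixed serialization order."""

    A = 0
    B = 1
    C = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class PreferenceFSM:
    """Probabilistic finite state machine over primitives.

    From A the machine moves to B with probability ``p_ab`` and to C with
    probability ``p_ac = 1 - p_ab``; B and C return to A deterministically.
    """

    p_ab: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_ab <= 1.0):
            raise ValueError(f"p_ab must be in [0, 1], got {self.p_ab}")

    @property
    def p_ac(self) -> float:
        return 1.0 - self.p_ab


def robot_fsm(robot: int) -> PreferenceFSM:
    """The two conflicting preference machines: robot 1 favors C (80%),
    robot 2 favors B (80%)."""
    if robot == 1:
        return PreferenceFSM(p_ab=0.2)
    if robot == 2:
        return PreferenceFSM(p_ab=0.8)
    raise ValueError("robot must be 1 or 2")


def sample_primitive_sequence(
    fsm: PreferenceFSM, n_primitives: int, seed: int | np.random.Generator
) -> list[Primitive]:
    """Sample a primitive sequence A, {B|C}, A, {B|C}, ... of given length.

    The sequence starts at A and strictly alternates A with a
    probabilistically chosen B or C.
    """
    if n_primitives < 1:
        raise ValueError("n_primitives must be >= 1")
    rng = np.random.default_rng(seed)
    seq: list[Primitive] = []
    for i in range(n_primitives):
        if i % 2 == 0:
            seq.append(Primitive.A)
        else:
            seq.append(Primitive.B if rng.random() < fsm.p_ab else Primitive.C)
    return seq


def _waveform_bank(duration: int) -> np.ndarray:
    """Fixed per-primitive joint templates, shape (3, duration, 6).

    Low-order sinusoid/ramp mixtures; the three templates are pairwise
    distinct on every joint.  Deterministic constants, no randomness.
    """
    t = np.linspace(0.0, 1.0, duration, endpoint=False)
    bank = np.empty((3, duration, 6))
    # primitive A: slow symmetric swing, both arms in phase
    for j in range(6):
        bank[Primitive.A, :, j] = 0.7 * np.sin(2 * np.pi * t + j * np.pi / 6)
    # primitive B: faster, arms anti-phase, with a ramp component
    for j in range(6):
        sgn = 1.0 if j < 3 else -1.0
        bank[Primitive.B, :, j] = sgn * (
            0.5 * np.sin(4 * np.pi * t + j * np.pi / 8) + 0.4 * (2 * t - 1)
        )
    # primitive C: cosine burst, outer joints dominant
    for j in range(6):
        amp = 0.3 + 0.1 * j
        bank[Primitive.C, :, j] = amp * np.cos(2 * np.pi * t + j * np.pi / 4) - 0.15
    return np.clip(bank, -1.0, 1.0)


@dataclass(frozen=True)
class PrimitiveWaveforms:
    """Per-primitive joint-angle templates: (3, duration, 6) in [-1, 1]."""

    templates: np.ndarray

    @classmethod
    def default(cls, duration: int = 20) -> "PrimitiveWaveforms":
        return cls(templates=_waveform_bank(duration))

    @property
    def duration(self) -> int:
        return self.templates.shape[1]

    def __post_init__(self) -> None:
        tpl = self.templates
        if tpl.ndim != 3 or tpl.shape[0] != 3 or tpl.shape[2] != 6:
            raise ValueError("templates must have shape (3, D, 6)")
        if np.abs(tpl).max() > 1.0:
            raise ValueError("templates must lie in [-1, 1]")
        # pairwise distinguishability
        for a in range(3):
            for b in range(a + 1, 3):
                rms = np.sqrt(np.mean((tpl[a] - tpl[b]) ** 2))
                if rms <= 0:
                    raise ValueError("primitive templates must be pairwise distinct")


@dataclass
class Trajectory:
    """Paired proprioception (T, 6) and exteroception (T, 4), optional labels.

    ``extero`` is always the partner's view of the hands:
    ``observe(proprio)`` row-wise, coordinates normalized by the reach.
    """

    proprio: np.ndarray
    extero: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.proprio = np.asarray(self.proprio, dtype=float)
        self.extero = np.asarray(self.extero, dtype=float)
        if self.proprio.ndim != 2 or self.proprio.shape[1] != 6:
            raise ValueError("proprio must be (T, 6)")
        if self.extero.shape != (self.proprio.shape[0], 4):
            raise ValueError("extero must be (T, 4)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.proprio.shape[0],):
                raise ValueError("labels must be (T,)")

    def __len__(self) -> int:
        return self.proprio.shape[0]

    @property
    def observations(self) -> np.ndarray:
        """(T, 10) array: 6 proprio + 4 extero channels."""
        return np.concatenate([self.proprio, self.extero], axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"j{i+1}" for i in range(6)] + ["lx", "ly", "rx", "ry"]
        df = pd.DataFrame(self.observations, columns=cols)
        if self.labels is not None:
            df["label"] = [Primitive(v).name for v in self.labels]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        pro = df[[f"j{i+1}" for i in range(6)]].to_numpy()
        ext = df[["lx", "ly", "rx", "ry"]].to_numpy()
        labels = None
        if "label" in df.columns:
            labels = np.array([Primitive[v].value for v in df["label"]])
        return cls(proprio=pro, extero=ext, labels=labels)


def forward_kinematics(proprio_row: np.ndarray) -> np.ndarray:
    """Hand positions (lx, ly, rx, ry) of a planar 3-joint arm per side.

    Joints 1-3 drive the left hand, joints 4-6 the right; normalized joint
    values map to radians via pi/2, angles accumulate along the chain, and
    the right arm is laid out mirror-symmetrically (base angle pi - theta).
    Raw (unnormalized) coordinates are returned; |x|, |y| <= REACH.
    """
    row = np.asarray(proprio_row, dtype=float)
    if row.shape != (6,):
        raise ValueError("proprio_row must be a 6-vector")
    return _fk_many(row[None, :])[0]


def _fk_many(proprio: np.ndarray) -> np.ndarray:
    """Vectorized forward kinematics over (T, 6) -> raw (T, 4)."""
    q = np.asarray(proprio, dtype=float) * _JOINT_SCALE
    L = np.array(LINK_LENGTHS)
    ang_l = np.cumsum(q[:, :3], axis=1)
    lx = (L * np.cos(ang_l)).sum(axis=1)
    ly = (L * np.sin(ang_l)).sum(axis=1)
    base = (np.pi - q[:, 3])[:, None]
    ang_r = np.cumsum(np.concatenate([base, -q[:, 4:6]], axis=1), axis=1)
    rx = (L * np.cos(ang_r)).sum(axis=1)
    ry = (L * np.sin(ang_r)).sum(axis=1)
    return np.stack([lx, ly, rx, ry], axis=1)


def observe(proprio: np.ndarray) -> np.ndarray:
    """Partner's normalized exteroception of a posture or a trajectory.

    The partner sees a mirrored image: x coordinates are negated and the
    left/right hands swap.  Output coordinates are divided by REACH so the
    exteroceptive channels share the network's [-1, 1] range.  Accepts a
    single 6-vector or a (T, 6) array.
    """
    single = np.ndim(proprio) == 1
    raw = _fk_many(np.atleast_2d(proprio)) / REACH
    mirrored = np.empty_like(raw)
    mirrored[:, 0] = -raw[:, 2]  # partner's left = own right, x negated
    mirrored[:, 1] = raw[:, 3]
    mirrored[:, 2] = -raw[:, 0]
    mirrored[:, 3] = raw[:, 1]
    return mirrored[0] if single else mirrored


def render_trajectory(
    labels: list[Primitive] | np.ndarray,
    waveforms: PrimitiveWaveforms | None = None,
    crossfade: int = 2,
) -> Trajectory:
    """Render a primitive label sequence into a continuous trajectory.

    Each label occupies ``waveforms.duration`` steps; segment boundaries are
    linearly cross-faded over ``crossfade`` steps (0 disables smoothing).
    """
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    wf = waveforms or PrimitiveWaveforms.default()
    D = wf.duration
    labels = [Primitive(l) for l in labels]
    pro = np.concatenate([wf.templates[l] for l in labels], axis=0)
    if crossfade > 0:
        for s in range(1, len(labels)):
            if labels[s] == labels[s - 1]:
                continue
            b = s * D
            prev_tail = wf.templates[labels[s - 1], -1]
            for k in range(min(crossfade, D)):
                a = (k + 1) / (crossfade + 1)
                pro[b + k] = (1 - a) * prev_tail + a * pro[b + k]
    pro = np.clip(pro, -1.0, 1.0)
    step_labels = np.repeat([int(l) for l in labels], D)
    return Trajectory(proprio=pro, extero=observe(pro), labels=step_labels)


def generate_training_set(
    fsm: PreferenceFSM,
    n_sequences: int = 20,
    T: int = 400,
    seed: int = 0,
    waveforms: PrimitiveWaveforms | None = None,
    crossfade: int = 2,
) -> list[Trajectory]:
    """Generate a training set of FSM-driven trajectories.

    The defaults match the study conditions: 20 trajectories of 400 steps,
    each a continuous chain of T/D primitives.
    """
    wf = waveforms or PrimitiveWaveforms.default()
    if T % wf.duration != 0:
        raise ValueError(f"T={T} must be divisible by primitive duration {wf.duration}")
    n_prim = T // wf.duration
    rng = np.random.default_rng(seed)
    return [
        render_trajectory(
            sample_primitive_sequence(fsm, n_prim, rng), wf, crossfade=crossfade
        )
        for _ in range(n_sequences)
    ]
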