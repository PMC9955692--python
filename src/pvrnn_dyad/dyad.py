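"""Coupling of two PV-RNN agents in synchronous imitative interaction.

Each agent's exteroception is the mirrored hand-position view of the
partner's executed movement.  Updates are synchronous: both agents act at
step t, both then observe the partner's step-t output, infer within their
regression windows, and generate the step t+1 action.  Proprioceptive
predictions are executed verbatim (perfect actuation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net
from .inference import (InferenceConfig, MetaPriorSchedule, PosteriorWindow,
                        eval_schedule, infer_step, predict_next, slide_window)
from .movement import observe
from .network import NetworkParams

__all__ = ["AgentHandle", "InteractionTrace", "observe_partner",
           "run_interaction", "run_oscillation_experiment"]


def observe_partner(partner_proprio: np.ndarray) -> np.ndarray:
    """Exteroception of the partner's posture: mirrored forward kinematics,
    the same convention used for the training data."""
    return observe(partner_proprio)


@dataclass
class AgentHandle:
    """One interacting agent: frozen weights, inference settings, schedule."""

    params: NetworkParams
    cfg: InferenceConfig = field(default_factory=InferenceConfig)
    schedule: MetaPriorSchedule = field(default_factory=MetaPriorSchedule)

    @classmethod
    def from_model(cls, model, **kw) -> "AgentHandle":
        return cls(params=model.params, **kw)


@dataclass
class InteractionTrace:
    """Per-step record of a dyadic interaction (arrays indexed [agent, t])."""

    proprio: np.ndarray          # (2, T, 6) executed joint angles
    extero_observed: np.ndarray  # (2, T, 4) observed partner hands
    extero_predicted: np.ndarray  # (2, T, 4) own prediction of the above
    wi: np.ndarray               # (2, T) layer-1 interaction meta-prior
    f_first: np.ndarray          # (2, T) free energy before inner iterations
    f_last: np.ndarray           # (2, T) free energy after inner iterations
    kl_layers: np.ndarray        # (2, T, L) mean per-unit KL at window end
    mu_p1: np.ndarray            # (2, T, z1) layer-1 prior mean at window end
    mu_q1: np.ndarray            # (2, T, z1) layer-1 posterior mean

    @property
    def T(self) -> int:
        return self.proprio.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for agent in range(2):
            for t in range(self.T):
                row = {"agent": agent + 1, "t": t + 1,
                       "wi": self.wi[agent, t],
                       "F_first": self.f_first[agent, t],
                       "F_last": self.f_last[agent, t]}
                row.update({f"j{i+1}": self.proprio[agent, t, i] for i in range(6)})
                row.update({c: self.extero_observed[agent, t, i]
                            for i, c in enumerate(("lx", "ly", "rx", "ry"))})
                rows.append(row)
        return pd.DataFrame(rows)

    def save_hdf5(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            for name in ("proprio", "extero_observed", "extero_predicted",
                         "wi", "f_first", "f_last", "kl_layers",
                         "mu_p1", "mu_q1"):
                fh.create_dataset(name, data=getattr(self, name))


def run_interaction(
    agent1: AgentHandle,
    agent2: AgentHandle,
    T: int = 1000,
    seed: int = 0,
) -> InteractionTrace:
    """Run a full synchronous dyadic interaction of T steps.

    Both agents use independent random streams derived from ``seed``.
    Aborts with a RuntimeError carrying the partial trace length if free
    energy turns non-finite.
    """
    agents = (agent1, agent2)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(2)]
    L = max(a.params.L for a in agents)
    z1 = max(a.params.specs[0].z_dim for a in agents)

    windows = [PosteriorWindow(params=a.params) for a in agents]
    tr = InteractionTrace(
        proprio=np.zeros((2, T, 6)),
        extero_observed=np.zeros((2, T, 4)),
        extero_predicted=np.zeros((2, T, 4)),
        wi=np.zeros((2, T)),
        f_first=np.full((2, T), np.nan),
        f_last=np.full((2, T), np.nan),
        kl_layers=np.zeros((2, T, L)),
        mu_p1=np.zeros((2, T, z1)),
        mu_q1=np.zeros((2, T, z1)),
    )

    # first action from the initial prior, no observation yet
    for i, ag in enumerate(agents):
        pro, ext = predict_next(ag.params, windows[i], ag.cfg, rngs[i])
        tr.proprio[i, 0] = pro
        tr.extero_predicted[i, 0] = ext

    for t in range(1, T + 1):
        i0 = t - 1
        # both agents observe the partner's executed step-t posture
        for i in range(2):
            tr.extero_observed[i, i0] = observe_partner(tr.proprio[1 - i, i0])
        for i, ag in enumerate(agents):
            w_layers = eval_schedule(ag.schedule, t)[: ag.params.L]
            tr.wi[i, i0] = w_layers[0]
            slide_window(windows[i], ag.cfg.window_len)
            obs = tr.extero_observed[i, windows[i].t_start - 1: t]
            cache, f_trace = infer_step(
                ag.params, windows[i], obs, ag.cfg, w_layers, rngs[i])
            tr.f_first[i, i0] = f_trace[0]
            tr.f_last[i, i0] = f_trace[-1]
            for l in range(ag.params.L):
                tr.kl_layers[i, i0, l] = float(net.kl_unit(
                    cache.mup[-1][l], cache.sigp[-1][l],
                    cache.muq[-1][l], cache.sigq[-1][l]).mean())
            nz = ag.params.specs[0].z_dim
            tr.mu_p1[i, i0, :nz] = cache.mup[-1][0][0]
            tr.mu_q1[i, i0, :nz] = cache.muq[-1][0][0]
            if t < T:
                pro, ext = predict_next(ag.params, windows[i], ag.cfg, rngs[i])
                tr.proprio[i, t] = pro
                tr.extero_predicted[i, t] = ext
    return tr


def run_oscillation_experiment(
    agent1: AgentHandle,
    agent2: AgentHandle,
    lower: float = 0.0048,
    upper: float = 1.0461,
    period: int = 1280,
    onset: int = 80,
    n_periods: int = 3,
    seed: int = 0,
    onset_value: float = 0.5255,
) -> InteractionTrace:
    """Interaction with meta-priors oscillating sinusoidally in anti-phase.

    Total length T = n_periods * period + onset (defaults: 3*1280+80 =
    3920).  Agent 1 starts on the rising half-wave, agent 2 on the falling
    one (phase offset pi); both hold ``onset_value`` during the onset.
    """
    if not lower < upper:
        raise ValueError("lower must be < upper")
    kw = dict(kind="sinusoid", lower=lower, upper=upper, period=period,
              onset_len=onset, onset_value=onset_value)
    agent1 = AgentHandle(agent1.params, agent1.cfg,
                         MetaPriorSchedule(phase=0.0, **kw))
    agent2 = AgentHandle(agent2.params, agent2.cfg,
                         MetaPriorSchedule(phase=np.pi, **kw))
    T = n_periods * period + onset
    return run_interaction(agent1, agent2, T=T, seed=seed)
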