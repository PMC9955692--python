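"""Online error regression: sliding-window posterior inference.

At every interaction step the agent minimizes the windowed free energy
with respect to the adaptive posterior variables A only (weights frozen),
with the error computed on the exteroceptive channels and the complexity
term weighted by the interaction meta-prior w_i.  The window grows from a
single step at interaction onset up to ``window_len`` and then slides,
freezing evicted steps into the permanent record using the posterior mean.

Meta-prior schedules are specified by their layer-1 value; the x10 / x100
layer multipliers are applied when the schedule is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import network as net
from .network import NetworkParams
from .training import Adam

__all__ = ["InferenceConfig", "MetaPriorSchedule", "PosteriorWindow",
           "eval_schedule", "infer_step", "slide_window", "predict_next"]

#: per-layer multipliers applied to the layer-1 interaction meta-prior
LAYER_MULTIPLIERS = (1.0, 10.0, 100.0)

EXTERO_MASK = np.array([0.0] * net.N_PROPRIO + [1.0] * net.N_EXTERO)


@dataclass(frozen=True)
class InferenceConfig:
    """Online-inference settings (full-scale defaults: window 70, 50
    iterations; the inner Adam learning rate is a package default)."""

    window_len: int = 70
    iterations: int = 50
    inner_lr: float = 1e-3
    deterministic: bool = False  # propagate mu^q instead of sampling z
    resample_noise: bool = False  # fresh eps every inner iteration

    def __post_init__(self) -> None:
        if self.window_len < 1 or self.iterations < 1:
            raise ValueError("window_len and iterations must be >= 1")


@dataclass(frozen=True)
class MetaPriorSchedule:
    """Layer-1 interaction meta-prior as a function of the step index.

    ``kind='constant'`` holds ``value``; ``kind='sinusoid'`` holds
    ``onset_value`` for t <= onset_len and thereafter oscillates between
    ``lower`` and ``upper`` with the given period and phase (phase pi gives
    the anti-phase partner).
    """

    kind: str = "constant"
    value: float = 1.0
    lower: float = 0.0048
    upper: float = 1.0461
    period: int = 1280
    phase: float = 0.0
    onset_len: int = 80
    onset_value: float = 0.5255

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "sinusoid":
            if self.period < 2:
                raise ValueError("period must be >= 2")
            if min(self.lower, self.upper, self.onset_value) < 0:
                raise ValueError("meta-prior values must be >= 0")
        elif self.value < 0:
            raise ValueError("meta-prior values must be >= 0")


def eval_schedule(s: MetaPriorSchedule, t: int) -> np.ndarray:
    """Per-layer interaction meta-priors at step t (1-based).

    Returns the layer-1 schedule value scaled by (1, 10, 100).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if s.kind == "constant":
        w1 = s.value
    elif t <= s.onset_len:
        w1 = s.onset_value
    else:
        mid = 0.5 * (s.upper + s.lower)
        amp = 0.5 * (s.upper - s.lower)
        w1 = mid + amp * np.sin(2 * np.pi * (t - s.onset_len) / s.period + s.phase)
    return w1 * np.asarray(LAYER_MULTIPLIERS)


@dataclass
class PosteriorWindow:
    """Adaptive variables and cached pre-window state of one agent.

    ``a_mu[l]`` / ``a_sig[l]`` are (1, W_cur, z_l).  (h0, d0) is the frozen
    network state just before the window; ``t_start`` is the global
    (1-based) step of the window's first entry.  ``frozen_mu_q`` collects
    the layer-1 posterior means of evicted steps (the permanent record).
    """

    params: NetworkParams
    a_mu: list[np.ndarray] = field(default_factory=list)
    a_sig: list[np.ndarray] = field(default_factory=list)
    h0: list[np.ndarray] | None = None
    d0: list[np.ndarray] | None = None
    t_start: int = 1
    frozen_mu_q: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.a_mu:
            self.a_mu = [np.zeros((1, 0, s.z_dim)) for s in self.params.specs]
            self.a_sig = [np.zeros((1, 0, s.z_dim)) for s in self.params.specs]

    @property
    def length(self) -> int:
        return self.a_mu[0].shape[1]


def slide_window(window: PosteriorWindow, window_len: int) -> PosteriorWindow:
    """Append a zero-initialized step; evict the oldest when over capacity.

    Older A entries are retained unchanged (warm start).  An evicted step
    is folded into the pre-window state by advancing (h0, d0) one step with
    the posterior mean, and its layer-1 mu^q is appended to the permanent
    record.
    """
    specs = window.params.specs
    for l in range(len(specs)):
        pad = np.zeros((1, 1, specs[l].z_dim))
        window.a_mu[l] = np.concatenate([window.a_mu[l], pad], axis=1)
        window.a_sig[l] = np.concatenate([window.a_sig[l], pad], axis=1)
    if window.length > window_len:
        _evict_oldest(window)
    return window


def _evict_oldest(window: PosteriorWindow) -> None:
    params = window.params
    specs = params.specs
    if window.h0 is None:
        h = [np.zeros((1, s.d_dim)) for s in specs]
        d = [np.zeros((1, s.d_dim)) for s in specs]
    else:
        h, d = window.h0, window.d0
    z_now = []
    for l in range(len(specs)):
        post = net.compute_posterior(
            d[l], window.a_mu[l][:, 0], window.a_sig[l][:, 0], params, l)
        z_now.append(post.mu)  # frozen record uses the posterior mean
        if l == 0:
            window.frozen_mu_q.append(post.mu[0].copy())
    h, d = net.deterministic_update(h, d, z_now, params)
    window.h0, window.d0 = h, d
    window.t_start += 1
    for l in range(len(specs)):
        window.a_mu[l] = window.a_mu[l][:, 1:]
        window.a_sig[l] = window.a_sig[l][:, 1:]


def infer_step(
    params: NetworkParams,
    window: PosteriorWindow,
    observations: np.ndarray,
    cfg: InferenceConfig,
    w_layers: np.ndarray,
    rng: np.random.Generator,
) -> tuple[net.ForwardCache, list[float]]:
    """Optimize the window's A by gradient descent on the windowed free energy.

    ``observations`` is (W_cur, 4): the observed partner hand positions for
    every step in the window.  The error term uses the exteroceptive
    channels only; the KL of every window step is weighted by the current
    per-layer ``w_layers``.  Returns the final forward cache and the
    per-iteration free-energy trace.
    """
    W_cur = window.length
    if observations.shape != (W_cur, net.N_EXTERO):
        raise ValueError("observations must cover the window, shape (W, 4)")
    targets = np.zeros((1, W_cur, net.N_OUT))
    targets[0, :, net.N_PROPRIO:] = observations

    a_values: dict[str, np.ndarray] = {}
    for l in range(params.L):
        a_values[f"amu{l}"] = window.a_mu[l]
        a_values[f"asig{l}"] = window.a_sig[l]
    opt = Adam(a_values, lr=cfg.inner_lr)

    # reparameterization noise: drawn once per interaction step and held
    # fixed over the inner iterations (deterministic inner objective),
    # unless per-iteration resampling is requested
    fixed_eps = None
    if not cfg.deterministic and not cfg.resample_noise:
        fixed_eps = [[rng.standard_normal((1, s.z_dim)) for s in params.specs]
                     for _ in range(W_cur)]

    trace: list[float] = []
    cache = None
    for _ in range(cfg.iterations):
        cache = net.forward_sequence(
            params, window.a_mu, window.a_sig, rng=rng, eps=fixed_eps,
            h0=window.h0, d0=window.d0, t_start=window.t_start,
            use_mean=cfg.deterministic)
        terms, _, ga_mu, ga_sig = net.free_energy_and_grads(
            params, window.a_mu, window.a_sig, cache, targets,
            w_layers, EXTERO_MASK, w_at_t1=None, t_start=window.t_start,
            need_param_grads=False)
        if not np.isfinite(terms["F"]):
            raise RuntimeError(
                f"online inference produced non-finite free energy at window "
                f"t_start={window.t_start}, length={W_cur}")
        trace.append(terms["F"])
        grads = {f"amu{l}": ga_mu[l] for l in range(params.L)}
        grads.update({f"asig{l}": ga_sig[l] for l in range(params.L)})
        opt.step(a_values, grads)
    return cache, trace


def predict_next(
    params: NetworkParams,
    window: PosteriorWindow,
    cfg: InferenceConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One generative step beyond the window: the next action and prediction.

    Replays the window with the optimized A (posterior z), then advances a
    single step sampling z from the conditional prior.  Returns the
    6-channel proprioceptive command (executed as-is: perfect actuation)
    and the 4-channel exteroceptive prediction.
    """
    if window.length > 0:
        cache = net.forward_sequence(
            params, window.a_mu, window.a_sig, rng=rng,
            h0=window.h0, d0=window.d0, t_start=window.t_start,
            use_mean=cfg.deterministic)
        h = [hl.copy() for hl in cache.h[-1]]
        d = [dl.copy() for dl in cache.d[-1]]
        t_next = window.t_start + window.length
    else:
        h = [np.zeros((1, s.d_dim)) for s in params.specs]
        d = [np.zeros((1, s.d_dim)) for s in params.specs]
        t_next = window.t_start
    z_now = []
    for l in range(params.L):
        pri = net.compute_prior(d[l], params, l, t_next)
        z_now.append(pri.mu if cfg.deterministic else net.sample_latent(pri, rng))
    h, d = net.deterministic_update(h, d, z_now, params)
    out = net.output_map(d[0], params)[0]
    return out[:net.N_PROPRIO], out[net.N_PROPRIO:]
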