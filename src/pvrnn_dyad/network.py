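"""PV-RNN: a predictive-coding-inspired variational RNN.

The network stacks L layers of leaky-integrator ("multiple timescale")
deterministic units d with per-layer Gaussian latents z.  Layer l evolves

    h_t^l = (1 - 1/tau_l) h_{t-1}^l
            + (1/tau_l) [ W_dd d~_{t-1}^l + W_zd z_t^l
                          + W_up d~_{t-1}^{l+1} + W_dn d~_{t-1}^{l-1} + b_h ]
    d~_t^l = tanh(h_t^l)

with a conditional Gaussian prior (mu^p = tanh(W_mu d~_{t-1} + b_mu^p),
sigma^p = exp(W_sig d~_{t-1} + b_sig^p); standard normal at t = 1) and an
approximate posterior of the same form shifted by per-step adaptive
variables A (mu^q uses A_mu, sigma^q uses A_sig).  The 10-channel output
(6 proprioceptive + 4 exteroceptive) is tanh(W_out d~^1 + b_out).

The minimized free energy is the normalized form

    F = sum_t sum_l w_l(t) * mean_r delta(l, r, t)
        + (1/R_X) sum_t || mask * (X_t - X^bar_t) ||^2

where delta is the elementwise Gaussian KL of posterior from prior and
w_l(t) is the (possibly step-dependent) meta-prior of layer l.  Large w
pins the posterior to the prior (strong top-down intention / sensory
attenuation); small w lets sensory prediction error dominate.

Gradients for BPTT (training: all parameters + A; online inference: A
only) are hand-derived and exposed via :func:`free_energy_and_grads`;
tests verify them against central finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .movement import Trajectory, REACH, observe

__all__ = [
    "LayerSpec",
    "NetworkParams",
    "GaussianLatent",
    "ForwardCache",
    "table1_specs",
    "desk_specs",
    "init_params",
    "deterministic_update",
    "compute_prior",
    "compute_posterior",
    "sample_latent",
    "kl_unit",
    "output_map",
    "forward_sequence",
    "free_energy",
    "free_energy_and_grads",
    "prior_generate",
]

N_PROPRIO = 6
N_EXTERO = 4
N_OUT = N_PROPRIO + N_EXTERO


@dataclass(frozen=True)
class LayerSpec:
    """Dimensions, timescale and meta-priors of one PV-RNN layer."""

    d_dim: int
    z_dim: int
    tau: float
    w_train: float = 1.0
    w_interact: float = 1.0

    def __post_init__(self) -> None:
        if self.d_dim < 1 or self.z_dim < 1:
            raise ValueError("layer dimensions must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.w_train < 0 or self.w_interact < 0:
            raise ValueError("meta-priors must be >= 0")


def table1_specs(w1_train: float = 3.5, w1_interact: float = 1.0) -> list[LayerSpec]:
    """The full-scale 3-layer configuration: d = (40, 20, 10), z = (4, 2, 1),
    tau = (2, 4, 8); meta-priors scale by x10 per layer above layer 1."""
    return [
        LayerSpec(40, 4, 2.0, w1_train, w1_interact),
        LayerSpec(20, 2, 4.0, w1_train * 10, w1_interact * 10),
        LayerSpec(10, 1, 8.0, w1_train * 100, w1_interact * 100),
    ]


def desk_specs(w1_train: float = 0.35, w1_interact: float = 1.0) -> list[LayerSpec]:
    """A reduced 3-layer configuration for desk-scale runs: same timescale
    hierarchy and meta-prior layering, smaller widths.

    The training meta-prior default is rescaled (0.35 instead of 3.5)
    because the desk epoch budget is ~35x smaller than the full protocol;
    at 3.5 the complexity term dominates the short optimization and the
    reconstruction never takes off."""
    return [
        LayerSpec(16, 2, 2.0, w1_train, w1_interact),
        LayerSpec(8, 1, 4.0, w1_train * 10, w1_interact * 10),
        LayerSpec(4, 1, 8.0, w1_train * 100, w1_interact * 100),
    ]


@dataclass
class GaussianLatent:
    """Diagonal Gaussian with strictly positive scale."""

    mu: np.ndarray
    sigma: np.ndarray


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    bound = 1.0 / np.sqrt(shape[1])
    return rng.uniform(-bound, bound, size=shape)


class NetworkParams:
    """All PV-RNN weights, stored as a flat dict of numpy arrays.

    Keys (per layer l):
      Wdd{l}, Wzd{l}, Wup{l} (l < L-1), Wdn{l} (l > 0), bh{l};
      Wmu{l}, Wsig{l}, bmup{l}, bsigp{l}, bmuq{l}, bsigq{l};
      and, when prior/posterior heads are unshared, Wmuq{l}, Wsigq{l};
      output: Wout, bout.
    """

    def __init__(self, specs: list[LayerSpec], data: dict[str, np.ndarray],
                 shared_heads: bool = True, out_dim: int = N_OUT):
        self.specs = list(specs)
        self.data = data
        self.shared_heads = shared_heads
        self.out_dim = out_dim

    @property
    def L(self) -> int:
        return len(self.specs)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    def head_q(self, l: int) -> tuple[np.ndarray, np.ndarray]:
        """Posterior head weight matrices (mu, sigma) of layer l."""
        if self.shared_heads:
            return self.data[f"Wmu{l}"], self.data[f"Wsig{l}"]
        return self.data[f"Wmuq{l}"], self.data[f"Wsigq{l}"]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.specs, {k: v.copy() for k, v in self.data.items()},
            self.shared_heads, self.out_dim,
        )

    def save(self, path: str) -> None:
        """Checkpoint: npz archive with a JSON sidecar of the layer specs."""
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        np.savez(path, **self.data)
        meta = {
            "shared_heads": self.shared_heads,
            "out_dim": self.out_dim,
            "specs": [
                {"d_dim": s.d_dim, "z_dim": s.z_dim, "tau": s.tau,
                 "w_train": s.w_train, "w_interact": s.w_interact}
                for s in self.specs
            ],
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "NetworkParams":
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        with open(path + ".json") as fh:
            meta = json.load(fh)
        specs = [LayerSpec(**s) for s in meta["specs"]]
        archive = np.load(path)
        data = {k: archive[k] for k in archive.files}
        params = cls(specs, data, meta["shared_heads"], meta["out_dim"])
        params.validate()
        return params

    def validate(self) -> None:
        for l, s in enumerate(self.specs):
            if self.data[f"Wdd{l}"].shape != (s.d_dim, s.d_dim):
                raise ValueError(f"Wdd{l} shape mismatch")
            if self.data[f"Wzd{l}"].shape != (s.d_dim, s.z_dim):
                raise ValueError(f"Wzd{l} shape mismatch")
            if self.data[f"Wmu{l}"].shape != (s.z_dim, s.d_dim):
                raise ValueError(f"Wmu{l} shape mismatch")
        if self.data["Wout"].shape != (self.out_dim, self.specs[0].d_dim):
            raise ValueError("Wout shape mismatch")


def init_params(specs: list[LayerSpec], seed: int = 0,
                shared_heads: bool = True, out_dim: int = N_OUT) -> NetworkParams:
    """Uniform fan-in initialization of all weights; biases start at zero."""
    rng = np.random.default_rng(seed)
    L = len(specs)
    data: dict[str, np.ndarray] = {}
    for l, s in enumerate(specs):
        data[f"Wdd{l}"] = _uniform_fan_in(rng, (s.d_dim, s.d_dim))
        data[f"Wzd{l}"] = _uniform_fan_in(rng, (s.d_dim, s.z_dim))
        if l < L - 1:
            data[f"Wup{l}"] = _uniform_fan_in(rng, (s.d_dim, specs[l + 1].d_dim))
        if l > 0:
            data[f"Wdn{l}"] = _uniform_fan_in(rng, (s.d_dim, specs[l - 1].d_dim))
        data[f"bh{l}"] = np.zeros(s.d_dim)
        data[f"Wmu{l}"] = _uniform_fan_in(rng, (s.z_dim, s.d_dim))
        data[f"Wsig{l}"] = _uniform_fan_in(rng, (s.z_dim, s.d_dim))
        if not shared_heads:
            data[f"Wmuq{l}"] = _uniform_fan_in(rng, (s.z_dim, s.d_dim))
            data[f"Wsigq{l}"] = _uniform_fan_in(rng, (s.z_dim, s.d_dim))
        for name in (f"bmup{l}", f"bsigp{l}", f"bmuq{l}", f"bsigq{l}"):
            data[name] = np.zeros(s.z_dim)
    data["Wout"] = _uniform_fan_in(rng, (out_dim, specs[0].d_dim))
    data["bout"] = np.zeros(out_dim)
    return NetworkParams(specs, data, shared_heads, out_dim)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def deterministic_update(
    h_prev: list[np.ndarray],
    d_prev: list[np.ndarray],
    z_now: list[np.ndarray],
    params: NetworkParams,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One leaky-integrator step of every layer; returns (h, d~) lists.

    All per-layer arrays are (B, dim) batches.
    """
    L = params.L
    h, d = [], []
    for l, s in enumerate(params.specs):
        pre = d_prev[l] @ params[f"Wdd{l}"].T + z_now[l] @ params[f"Wzd{l}"].T \
            + params[f"bh{l}"]
        if l < L - 1:
            pre = pre + d_prev[l + 1] @ params[f"Wup{l}"].T
        if l > 0:
            pre = pre + d_prev[l - 1] @ params[f"Wdn{l}"].T
        hl = (1.0 - 1.0 / s.tau) * h_prev[l] + pre / s.tau
        h.append(hl)
        d.append(np.tanh(hl))
    return h, d


def compute_prior(d_prev: np.ndarray, params: NetworkParams, l: int,
                  t: int) -> GaussianLatent:
    """Conditional prior of layer l at step t (1-based); N(0, I) at t=1."""
    z = params.specs[l].z_dim
    if t <= 1:
        B = d_prev.shape[0] if d_prev.ndim == 2 else 1
        return GaussianLatent(np.zeros((B, z)), np.ones((B, z)))
    mu = np.tanh(d_prev @ params[f"Wmu{l}"].T + params[f"bmup{l}"])
    sigma = np.exp(d_prev @ params[f"Wsig{l}"].T + params[f"bsigp{l}"])
    return GaussianLatent(mu, sigma)


def compute_posterior(d_prev: np.ndarray, a_mu: np.ndarray, a_sig: np.ndarray,
                      params: NetworkParams, l: int) -> GaussianLatent:
    """Approximate posterior of layer l, shifted by adaptive variables A."""
    Wmu_q, Wsig_q = params.head_q(l)
    mu = np.tanh(d_prev @ Wmu_q.T + a_mu + params[f"bmuq{l}"])
    sigma = np.exp(d_prev @ Wsig_q.T + a_sig + params[f"bsigq{l}"])
    return GaussianLatent(mu, sigma)


def sample_latent(g: GaussianLatent, rng: np.random.Generator,
                  eps: np.ndarray | None = None) -> np.ndarray:
    """Reparameterized sample z = mu + sigma * eps, eps ~ N(0, I)."""
    if eps is None:
        eps = rng.standard_normal(g.mu.shape)
    return g.mu + g.sigma * eps


def kl_unit(mu_p, sigma_p, mu_q, sigma_q):
    """Elementwise KL(q || p) between two diagonal Gaussians.

    delta = log(sigma_p/sigma_q) + ((mu_q - mu_p)^2 + sigma_q^2)
            / (2 sigma_p^2) - 1/2, nonnegative, zero iff q = p.
    """
    sigma_p = np.asarray(sigma_p, dtype=float)
    sigma_q = np.asarray(sigma_q, dtype=float)
    if np.any(sigma_p <= 0) or np.any(sigma_q <= 0):
        raise ValueError("sigma must be strictly positive")
    mu_p = np.asarray(mu_p, dtype=float)
    mu_q = np.asarray(mu_q, dtype=float)
    return (np.log(sigma_p / sigma_q)
            + ((mu_q - mu_p) ** 2 + sigma_q ** 2) / (2.0 * sigma_p ** 2) - 0.5)


def output_map(d_layer1: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Bounded 10-channel output X^bar = tanh(W_out d~^1 + b_out)."""
    return np.tanh(d_layer1 @ params["Wout"].T + params["bout"])


# ---------------------------------------------------------------------------
# sequence forward / free energy / gradients
# ---------------------------------------------------------------------------

@dataclass
class ForwardCache:
    """Everything the backward pass needs, per step: lists of length T."""

    h: list[list[np.ndarray]] = field(default_factory=list)
    d: list[list[np.ndarray]] = field(default_factory=list)
    mup: list[list[np.ndarray]] = field(default_factory=list)
    sigp: list[list[np.ndarray]] = field(default_factory=list)
    muq: list[list[np.ndarray]] = field(default_factory=list)
    sigq: list[list[np.ndarray]] = field(default_factory=list)
    z: list[list[np.ndarray]] = field(default_factory=list)
    eps: list[list[np.ndarray]] = field(default_factory=list)
    xbar: list[np.ndarray] = field(default_factory=list)


def forward_sequence(
    params: NetworkParams,
    a_mu: list[np.ndarray],
    a_sig: list[np.ndarray],
    rng: np.random.Generator | None = None,
    eps: list[list[np.ndarray]] | None = None,
    h0: list[np.ndarray] | None = None,
    d0: list[np.ndarray] | None = None,
    t_start: int = 1,
    use_mean: bool = False,
) -> ForwardCache:
    """Posterior-driven forward pass over a window of T steps.

    ``a_mu[l]`` and ``a_sig[l]`` are (B, T, z_l) adaptive variables.  The
    pass starts from state (h0, d0) at global step ``t_start`` (1-based;
    when t_start == 1 the state is zero and the prior of the first step is
    standard normal).  z is sampled via reparameterization unless
    ``use_mean`` (z = mu^q) or explicit ``eps[t][l]`` noise is given.
    """
    L = params.L
    B, T = a_mu[0].shape[0], a_mu[0].shape[1]
    if h0 is None:
        h = [np.zeros((B, s.d_dim)) for s in params.specs]
        d = [np.zeros((B, s.d_dim)) for s in params.specs]
    else:
        h, d = [x.copy() for x in h0], [x.copy() for x in d0]
    cache = ForwardCache()
    for i in range(T):
        t = t_start + i
        z_now, mup_t, sigp_t, muq_t, sigq_t, eps_t = [], [], [], [], [], []
        for l in range(L):
            pri = compute_prior(d[l], params, l, t)
            post = compute_posterior(d[l], a_mu[l][:, i], a_sig[l][:, i], params, l)
            if use_mean:
                e = np.zeros_like(post.mu)
            elif eps is not None:
                e = eps[i][l]
            else:
                e = rng.standard_normal(post.mu.shape)
            z_now.append(post.mu + post.sigma * e)
            mup_t.append(pri.mu); sigp_t.append(pri.sigma)
            muq_t.append(post.mu); sigq_t.append(post.sigma)
            eps_t.append(e)
        h, d = deterministic_update(h, d, z_now, params)
        cache.h.append(h); cache.d.append(d)
        cache.mup.append(mup_t); cache.sigp.append(sigp_t)
        cache.muq.append(muq_t); cache.sigq.append(sigq_t)
        cache.z.append(z_now); cache.eps.append(eps_t)
        cache.xbar.append(output_map(d[0], params))
    return cache


def _w_schedule(params: NetworkParams, T: int, t_start: int,
                w_per_layer: np.ndarray, w_at_t1: float | None) -> np.ndarray:
    """(T, L) per-step, per-layer meta-prior weights."""
    W = np.tile(np.asarray(w_per_layer, dtype=float), (T, 1))
    if w_at_t1 is not None and t_start == 1:
        W[0, :] = w_at_t1
    return W


def free_energy(
    cache: ForwardCache,
    targets: np.ndarray,
    params: NetworkParams,
    w_per_layer: np.ndarray,
    mask: np.ndarray,
    w_at_t1: float | None = None,
    t_start: int = 1,
) -> dict[str, float]:
    """Normalized free energy of a forward pass against target observations.

    ``targets``: (B, T, 10); ``mask``: length-10 0/1 channel mask selecting
    which channels enter the error term (all 10 during training, the 4
    exteroceptive ones during interaction).  Returns total F plus its
    complexity/error decomposition, summed over the batch.
    """
    mask = np.asarray(mask, dtype=float)
    R_X = int(mask.sum())
    if R_X == 0:
        raise ValueError("channel mask must select at least one channel")
    T = len(cache.xbar)
    W = _w_schedule(params, T, t_start, w_per_layer, w_at_t1)
    complexity = 0.0
    for i in range(T):
        for l in range(params.L):
            delta = kl_unit(cache.mup[i][l], cache.sigp[i][l],
                            cache.muq[i][l], cache.sigq[i][l])
            complexity += W[i, l] * float(delta.mean(axis=1).sum())
    err = 0.0
    for i in range(T):
        resid = (targets[:, i] - cache.xbar[i]) * mask
        err += float((resid ** 2).sum())
    err /= R_X
    return {"F": complexity + err, "complexity": complexity, "error": err}


def free_energy_and_grads(
    params: NetworkParams,
    a_mu: list[np.ndarray],
    a_sig: list[np.ndarray],
    cache: ForwardCache,
    targets: np.ndarray,
    w_per_layer: np.ndarray,
    mask: np.ndarray,
    w_at_t1: float | None = None,
    t_start: int = 1,
    need_param_grads: bool = True,
) -> tuple[dict[str, float], dict[str, np.ndarray],
           list[np.ndarray], list[np.ndarray]]:
    """Free energy and its exact gradients via backpropagation through time.

    Returns (terms, param_grads, ga_mu, ga_sig); param_grads is empty when
    ``need_param_grads`` is False (online inference updates A only).  The
    noise eps recorded in ``cache`` is treated as fixed, so these are the
    reparameterized pathwise gradients.
    """
    L = params.L
    specs = params.specs
    B, T = a_mu[0].shape[0], a_mu[0].shape[1]
    mask = np.asarray(mask, dtype=float)
    R_X = int(mask.sum())
    W = _w_schedule(params, T, t_start, w_per_layer, w_at_t1)

    terms = free_energy(cache, targets, params, w_per_layer, mask,
                        w_at_t1, t_start)

    g: dict[str, np.ndarray] = {}
    if need_param_grads:
        g = {k: np.zeros_like(v) for k, v in params.data.items()}
    ga_mu = [np.zeros_like(a) for a in a_mu]
    ga_sig = [np.zeros_like(a) for a in a_sig]

    def d_at(i: int, l: int) -> np.ndarray:
        if i < 0:
            return np.zeros((B, specs[l].d_dim))
        return cache.d[i][l]

    gh_carry = [np.zeros((B, s.d_dim)) for s in specs]
    gd_next = [np.zeros((B, s.d_dim)) for s in specs]  # adjoint of d~_t from t+1

    for i in range(T - 1, -1, -1):
        t = t_start + i
        # ---- adjoint of d~_t ---------------------------------------
        gd = [gd_next[l].copy() for l in range(L)]
        # output error at step i (layer 0)
        resid = (cache.xbar[i] - targets[:, i]) * mask
        gpre_out = (2.0 / R_X) * resid * (1.0 - cache.xbar[i] ** 2)
        gd[0] += gpre_out @ params["Wout"]
        if need_param_grads:
            g["Wout"] += gpre_out.T @ cache.d[i][0]
            g["bout"] += gpre_out.sum(axis=0)
        # ---- adjoint of h_t ----------------------------------------
        gh = [gd[l] * (1.0 - cache.d[i][l] ** 2) + gh_carry[l] for l in range(L)]

        gd_prev = [np.zeros((B, s.d_dim)) for s in specs]
        for l, s in enumerate(specs):
            inv_tau = 1.0 / s.tau
            gpre = gh[l] * inv_tau
            dp_self = d_at(i - 1, l)
            if need_param_grads:
                g[f"Wdd{l}"] += gpre.T @ dp_self
                g[f"Wzd{l}"] += gpre.T @ cache.z[i][l]
                g[f"bh{l}"] += gpre.sum(axis=0)
                if l < L - 1:
                    g[f"Wup{l}"] += gpre.T @ d_at(i - 1, l + 1)
                if l > 0:
                    g[f"Wdn{l}"] += gpre.T @ d_at(i - 1, l - 1)
            gd_prev[l] += gpre @ params[f"Wdd{l}"]
            if l < L - 1:
                gd_prev[l + 1] += gpre @ params[f"Wup{l}"]
            if l > 0:
                gd_prev[l - 1] += gpre @ params[f"Wdn{l}"]

            # ---- z -> posterior heads; KL -> both heads ------------
            gz = gpre @ params[f"Wzd{l}"]
            mup, sigp = cache.mup[i][l], cache.sigp[i][l]
            muq, sigq = cache.muq[i][l], cache.sigq[i][l]
            c = W[i, l] / s.z_dim
            diff = muq - mup
            gmuq = gz + c * diff / sigp ** 2
            gsigq = gz * cache.eps[i][l] + c * (sigq / sigp ** 2 - 1.0 / sigq)
            # posterior head
            gpre_mu_q = gmuq * (1.0 - muq ** 2)
            gpre_sig_q = gsigq * sigq
            ga_mu[l][:, i] = gpre_mu_q
            ga_sig[l][:, i] = gpre_sig_q
            Wmu_q, Wsig_q = params.head_q(l)
            gd_prev[l] += gpre_mu_q @ Wmu_q + gpre_sig_q @ Wsig_q
            if need_param_grads:
                keymu = f"Wmu{l}" if params.shared_heads else f"Wmuq{l}"
                keysig = f"Wsig{l}" if params.shared_heads else f"Wsigq{l}"
                g[keymu] += gpre_mu_q.T @ dp_self
                g[keysig] += gpre_sig_q.T @ dp_self
                g[f"bmuq{l}"] += gpre_mu_q.sum(axis=0)
                g[f"bsigq{l}"] += gpre_sig_q.sum(axis=0)
            # prior head (fixed N(0,I) at global step 1: no gradient)
            if t > 1:
                gmup = -c * diff / sigp ** 2
                gsigp = c * (1.0 / sigp - (diff ** 2 + sigq ** 2) / sigp ** 3)
                gpre_mu_p = gmup * (1.0 - mup ** 2)
                gpre_sig_p = gsigp * sigp
                gd_prev[l] += gpre_mu_p @ params[f"Wmu{l}"] \
                    + gpre_sig_p @ params[f"Wsig{l}"]
                if need_param_grads:
                    g[f"Wmu{l}"] += gpre_mu_p.T @ dp_self
                    g[f"Wsig{l}"] += gpre_sig_p.T @ dp_self
                    g[f"bmup{l}"] += gpre_mu_p.sum(axis=0)
                    g[f"bsigp{l}"] += gpre_sig_p.sum(axis=0)

            gh_carry[l] = (1.0 - inv_tau) * gh[l]
        gd_next = gd_prev

    return terms, g, ga_mu, ga_sig


def prior_generate(
    params: NetworkParams,
    T: int,
    seed: int | np.random.Generator = 0,
    h0: list[np.ndarray] | None = None,
    d0: list[np.ndarray] | None = None,
    t_start: int = 1,
    use_mean: bool = False,
) -> Trajectory:
    """Closed-loop rollout sampling z from the learned prior at every step.

    No inference is performed; this is the network's spontaneous behavior.
    At global step 1 the prior is standard normal.  Returns a Trajectory of
    the T predicted observations (6 proprio + 4 extero channels); the
    exteroception stored is the network's own prediction, not recomputed
    from kinematics.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    L = params.L
    if h0 is None:
        h = [np.zeros((1, s.d_dim)) for s in params.specs]
        d = [np.zeros((1, s.d_dim)) for s in params.specs]
    else:
        h, d = [x.copy() for x in h0], [x.copy() for x in d0]
    out = np.empty((T, params.out_dim))
    for i in range(T):
        t = t_start + i
        z_now = []
        for l in range(L):
            pri = compute_prior(d[l], params, l, t)
            z_now.append(pri.mu if use_mean else sample_latent(pri, rng))
        h, d = deterministic_update(h, d, z_now, params)
        out[i] = output_map(d[0], params)[0]
    return Trajectory(proprio=out[:, :N_PROPRIO], extero=out[:, N_PROPRIO:])
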