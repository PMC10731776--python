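"""Multi-scale variational graph autoencoder with a Wasserstein prior.

The encoder stacks two shared graph-convolution layers on the
symmetrically normalized self-looped similarity network, then branches
into parallel variational heads of different widths (the scales). Each
head emits per-node Gaussian means and log-variances; reparameterized
samples from all heads are concatenated into the node embedding Z. The
main decoder reconstructs the similarity network as sigmoid(Z Z^T); two
auxiliary MLP decoders reconstruct the first- and second-layer hidden
activations from Z (multi-order node-embedding reconstruction). The prior
term replaces the usual KL divergence with a 2-Wasserstein distance
between each scale's latent sample cloud and an equal-size standard-normal
cloud, approximated by Sinkhorn (a closed-form per-node diagonal-Gaussian
W2 is available as an alternative mode).

Everything is dense NumPy: the graphs here are similarity networks with at
most a few thousand nodes, so full-graph gradient steps with hand-derived
reverse-mode gradients, Adam, and a step-decayed learning rate are both
simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SimilarityMatrix
from .ot import sinkhorn_plan

__all__ = [
    "GraphInputs",
    "LossBreakdown",
    "normalize_adjacency",
    "init_params",
    "encode",
    "reparameterize",
    "decode_adjacency",
    "decode_aux",
    "total_loss",
    "train",
    "embed",
    "MultiScaleVGAE",
]


# ---------------------------------------------------------------- containers

@dataclass
class GraphInputs:
    """One graph-side input: weighted adjacency SM in [0,1], node feature
    matrix X, and the normalized self-looped adjacency."""

    SM: np.ndarray
    X: np.ndarray
    SM_norm: np.ndarray = field(init=False)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.SM = np.asarray(self.SM, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.SM.shape[0] != self.X.shape[0]:
            raise ValueError("adjacency and features disagree on node count")
        self.SM_norm = normalize_adjacency(self.SM)


@dataclass
class LossBreakdown:
    bce_adj: float
    wd_prior: float
    aux_1: float
    aux_2: float

    @property
    def total(self) -> float:
        return self.bce_adj + self.wd_prior + 0.5 * (self.aux_1 + self.aux_2)


# ------------------------------------------------------------------- algebra

def normalize_adjacency(SM: np.ndarray) -> np.ndarray:
    """D~^{-1/2} (SM + I) D~^{-1/2}: add self-loops, then symmetric degree
    normalization. Self-loops guarantee positive degrees."""
    SM = np.asarray(SM, dtype=float)
    if SM.ndim != 2 or SM.shape[0] != SM.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(SM - SM.T).max(initial=0.0) > 1e-9:
        raise ValueError("adjacency must be symmetric")
    if SM.min(initial=0.0) < 0:
        raise ValueError("adjacency must be nonnegative")
    A = SM + np.eye(SM.shape[0])
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    out = dinv[:, None] * A * dinv[None, :]
    return (out + out.T) / 2.0


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(rng: np.random.Generator, n_features: int,
                hidden_dims: tuple[int, int], scales: tuple[int, ...],
                aux_hidden: int = 128) -> dict:
    """Glorot-initialized weights for encoder, variational heads, and the
    two auxiliary MLP decoders."""
    d1, d2 = hidden_dims
    dz = int(sum(scales))
    # variance heads start small so early sampling noise does not swamp
    # the reconstruction gradient
    params = {
        "W0": _glorot(rng, n_features, d1),
        "b0": np.zeros(d1),
        "W1": _glorot(rng, d1, d2),
        "b1": np.zeros(d2),
        "W_mu": [_glorot(rng, d2, s) for s in scales],
        "b_mu": [np.zeros(s) for s in scales],
        "W_sigma": [0.1 * _glorot(rng, d2, s) for s in scales],
        "b_sigma": [np.zeros(s) for s in scales],
    }
    for l, target_dim in ((1, d1), (2, d2)):
        params[f"mlp{l}_U1"] = _glorot(rng, dz, aux_hidden)
        params[f"mlp{l}_b1"] = np.zeros(aux_hidden)
        params[f"mlp{l}_U2"] = _glorot(rng, aux_hidden, target_dim)
        params[f"mlp{l}_b2"] = np.zeros(target_dim)
    return params


def encode(inputs: GraphInputs, params: dict) -> dict:
    """Two shared GCN layers with ReLU, then linear per-scale heads for
    mean and log-variance (no activation on the heads)."""
    N = inputs.SM_norm
    P1 = N @ inputs.X @ params["W0"] + params["b0"]
    H1 = np.maximum(P1, 0.0)
    P2 = N @ H1 @ params["W1"] + params["b1"]
    H2 = np.maximum(P2, 0.0)
    NH2 = N @ H2
    mu = [NH2 @ Wm + b for Wm, b in zip(params["W_mu"], params["b_mu"])]
    log_sigma = [NH2 @ Ws + b
                 for Ws, b in zip(params["W_sigma"], params["b_sigma"])]
    for arrays in (mu, log_sigma):
        for a in arrays:
            if not np.all(np.isfinite(a)):
                raise FloatingPointError("non-finite activation in encoder head")
    return {"P1": P1, "H1": H1, "P2": P2, "H2": H2, "NH2": NH2,
            "mu": mu, "log_sigma": log_sigma}


def reparameterize(state: dict, rng: np.random.Generator | None = None,
                   sample: bool = True) -> dict:
    """Draw Z_i = mu_i + exp(log_sigma_i) * eps with eps ~ N(0, 1), drawn
    independently per scale; concatenate into Z. With ``sample=False``
    (evaluation mode) Z_i = mu_i."""
    mu, log_sigma = state["mu"], state["log_sigma"]
    if sample:
        if rng is None:
            raise ValueError("sampling requires an rng")
        eps = [rng.standard_normal(m.shape) for m in mu]
        Z_list = [m + np.exp(ls) * e for m, ls, e in zip(mu, log_sigma, eps)]
    else:
        eps = [np.zeros_like(m) for m in mu]
        Z_list = [m.copy() for m in mu]
    out = dict(state)
    out["eps"] = eps
    out["Z_list"] = Z_list
    out["Z"] = np.concatenate(Z_list, axis=1)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode_adjacency(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder: sigmoid(Z Z^T); symmetric, entries in (0,1)."""
    return _sigmoid(Z @ Z.T)


def _mlp_forward(Z: np.ndarray, params: dict, l: int) -> dict:
    pre = Z @ params[f"mlp{l}_U1"] + params[f"mlp{l}_b1"]
    A = np.maximum(pre, 0.0)
    logits = A @ params[f"mlp{l}_U2"] + params[f"mlp{l}_b2"]
    return {"pre": pre, "A": A, "logits": logits, "out": _sigmoid(logits)}


def decode_aux(Z: np.ndarray, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Auxiliary decoders: project Z back onto the dimensions of the first
    and second hidden layers through one-hidden-layer MLPs with sigmoid."""
    return _mlp_forward(Z, params, 1)["out"], _mlp_forward(Z, params, 2)["out"]


def _minmax_target(H: np.ndarray) -> np.ndarray:
    """Per-column min-max normalization of a hidden activation into [0,1]
    (constant columns map to 0); used as a detached BCE target."""
    lo = H.min(axis=0)
    hi = H.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    T = (H - lo) / safe
    T[:, span == 0] = 0.0
    return T


def _bce_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy from logits and its gradient w.r.t. logits."""
    if target.min() < 0 or target.max() > 1:
        raise ValueError("BCE target outside [0, 1]; normalization missing")
    loss = float(np.mean(np.logaddexp(0.0, logits) - target * logits))
    grad = (_sigmoid(logits) - target) / logits.size
    return loss, grad


def _balanced_bce_logits(logits: np.ndarray, target: np.ndarray
                         ) -> tuple[float, np.ndarray]:
    """Class-balanced adjacency cross entropy (the canonical graph-
    autoencoder reconstruction objective): positive mass is reweighted by
    (n^2 - S) / S and the whole term rescaled by n^2 / (2 (n^2 - S)), with
    S the total target mass, so sparse similarity networks do not let the
    decoder idle at sigmoid = 1/2. Reduces to plain mean BCE when the
    target is half ones."""
    if target.min() < 0 or target.max() > 1:
        raise ValueError("BCE target outside [0, 1]; normalization missing")
    n2 = target.size
    S = float(target.sum())
    if not 0.0 < S < n2:
        return _bce_logits(logits, target)
    pos_weight = (n2 - S) / S
    norm = n2 / (2.0 * (n2 - S))
    sp_neg = np.logaddexp(0.0, -logits)  # -log sigmoid
    sp_pos = np.logaddexp(0.0, logits)   # -log(1 - sigmoid)
    loss = norm * float(np.mean(pos_weight * target * sp_neg
                                + (1.0 - target) * sp_pos))
    sig = _sigmoid(logits)
    grad = norm * ((1.0 - target) * sig
                   - pos_weight * target * (1.0 - sig)) / n2
    return loss, grad


# ------------------------------------------------------------ loss & gradient

def _wd_prior(Z_list, mu, log_sigma, rng, mode, epsilon, iters):
    """Prior term and its gradients.

    sinkhorn mode: (1/M) sum_i W2(sample cloud of scale i, equal-size
    N(0, I) cloud), with the transport plan held fixed for the gradient
    (envelope rule). gaussian mode: (1/M) sum_i mean-node closed-form W2
    between N(mu_n, diag sigma_n^2) and N(0, I).
    """
    M = len(Z_list)
    total = 0.0
    dZ = [np.zeros_like(z) for z in Z_list]
    dmu = [np.zeros_like(z) for z in Z_list]
    dls = [np.zeros_like(z) for z in Z_list]
    if mode == "sinkhorn":
        for i, Zi in enumerate(Z_list):
            G = rng.standard_normal(Zi.shape)
            plan, C, _ = sinkhorn_plan(Zi, G, epsilon, iters, tol=1e-9)
            w2 = np.sqrt(max((plan * C).sum(), 0.0))
            total += w2 / M
            if w2 > 1e-12:
                a = plan.sum(axis=1)
                dcost = 2.0 * (a[:, None] * Zi - plan @ G)
                dZ[i] = dcost / (2.0 * w2 * M)
    elif mode == "gaussian":
        for i, (m, ls) in enumerate(zip(mu, log_sigma)):
            sigma = np.exp(ls)
            per_node = np.sqrt((m**2).sum(axis=1) + ((sigma - 1.0) ** 2).sum(axis=1))
            n = m.shape[0]
            total += float(per_node.mean()) / M
            safe = np.where(per_node > 1e-12, per_node, np.inf)
            dmu[i] = m / safe[:, None] / (n * M)
            dls[i] = (sigma - 1.0) * sigma / safe[:, None] / (n * M)
    else:
        raise ValueError("wd mode must be 'sinkhorn' or 'gaussian'")
    return total, dZ, dmu, dls


def total_loss(inputs: GraphInputs, state: dict, params: dict,
               rng: np.random.Generator | None = None,
               wd_mode: str = "sinkhorn", sinkhorn_epsilon: float = 0.01,
               sinkhorn_iters: int = 100,
               with_grads: bool = False):
    """Full objective: adjacency BCE + Wasserstein prior + 1/2 * (sum of
    the two auxiliary reconstruction BCEs). Optionally returns gradients
    for every learnable weight (hand-derived reverse mode)."""
    N = inputs.SM_norm
    Z = state["Z"]
    scales = [m.shape[1] for m in state["mu"]]

    logits_adj = Z @ Z.T
    bce_adj, g_adj = _balanced_bce_logits(logits_adj, inputs.SM)

    aux = {}
    for l, H in ((1, state["H1"]), (2, state["H2"])):
        fwd = _mlp_forward(Z, params, l)
        target = _minmax_target(H)  # detached
        loss_l, g_l = _bce_logits(fwd["logits"], target)
        aux[l] = (loss_l, g_l, fwd, target)

    if rng is None:
        rng = np.random.default_rng(0)
    wd, dZ_wd, dmu_wd, dls_wd = _wd_prior(
        state["Z_list"], state["mu"], state["log_sigma"], rng,
        wd_mode, sinkhorn_epsilon, sinkhorn_iters,
    )

    breakdown = LossBreakdown(bce_adj=bce_adj, wd_prior=wd,
                              aux_1=aux[1][0], aux_2=aux[2][0])
    if not with_grads:
        return breakdown

    grads = {k: np.zeros_like(v) for k, v in params.items()
             if isinstance(v, np.ndarray)}
    for key in ("W_mu", "W_sigma", "b_mu", "b_sigma"):
        grads[key] = [np.zeros_like(w) for w in params[key]]

    # dL/dZ from adjacency decoder
    dZ = (g_adj + g_adj.T) @ Z
    # from auxiliary decoders (each weighted 1/2 in the total)
    for l in (1, 2):
        _, g_l, fwd, _ = aux[l]
        g_l = 0.5 * g_l
        grads[f"mlp{l}_U2"] = fwd["A"].T @ g_l
        grads[f"mlp{l}_b2"] = g_l.sum(axis=0)
        dA = g_l @ params[f"mlp{l}_U2"].T
        dpre = dA * (fwd["pre"] > 0)
        grads[f"mlp{l}_U1"] = Z.T @ dpre
        grads[f"mlp{l}_b1"] = dpre.sum(axis=0)
        dZ = dZ + dpre @ params[f"mlp{l}_U1"].T

    # split dZ per scale, add prior-term gradients, pull back through the
    # reparameterization Z_i = mu_i + exp(log_sigma_i) * eps_i
    dmu_list, dls_list = [], []
    offset = 0
    for i, s in enumerate(scales):
        dZi = dZ[:, offset:offset + s] + dZ_wd[i]
        offset += s
        sigma = np.exp(state["log_sigma"][i])
        dmu_list.append(dZi + dmu_wd[i])
        dls_list.append(dZi * state["eps"][i] * sigma + dls_wd[i])

    # heads: mu_i = (N H2) W_mu^i, log_sigma_i likewise
    NH2 = state["NH2"]
    dNH2 = np.zeros_like(NH2)
    for i in range(len(scales)):
        grads["W_mu"][i] = NH2.T @ dmu_list[i]
        grads["b_mu"][i] = dmu_list[i].sum(axis=0)
        grads["W_sigma"][i] = NH2.T @ dls_list[i]
        grads["b_sigma"][i] = dls_list[i].sum(axis=0)
        dNH2 += dmu_list[i] @ params["W_mu"][i].T
        dNH2 += dls_list[i] @ params["W_sigma"][i].T
    dH2 = N @ dNH2  # N symmetric

    dP2 = dH2 * (state["P2"] > 0)
    NH1 = N @ state["H1"]
    grads["W1"] = NH1.T @ dP2
    grads["b1"] = dP2.sum(axis=0)
    dH1 = N @ (dP2 @ params["W1"].T)
    dP1 = dH1 * (state["P1"] > 0)
    NX = N @ inputs.X
    grads["W0"] = NX.T @ dP1
    grads["b0"] = dP1.sum(axis=0)
    return breakdown, grads


# ----------------------------------------------------------------- training

class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = self._zeros_like(params)
        self.v = self._zeros_like(params)

    @staticmethod
    def _zeros_like(params):
        out = {}
        for k, v in params.items():
            out[k] = ([np.zeros_like(x) for x in v] if isinstance(v, list)
                      else np.zeros_like(v))
        return out

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k in params:
            if isinstance(params[k], list):
                for i in range(len(params[k])):
                    self.m[k][i] = b1 * self.m[k][i] + (1 - b1) * grads[k][i]
                    self.v[k][i] = b2 * self.v[k][i] + (1 - b2) * grads[k][i] ** 2
                    mhat = self.m[k][i] / corr1
                    vhat = self.v[k][i] / corr2
                    params[k][i] -= lr * mhat / (np.sqrt(vhat) + self.eps)
            else:
                self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
                self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
                mhat = self.m[k] / corr1
                vhat = self.v[k] / corr2
                params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(inputs: GraphInputs, *, scales=(16, 32, 64), hidden_dims=(256, 128),
          aux_hidden: int = 128, learning_rate: float = 0.001,
          lr_step: int = 300, lr_gamma: float = 0.5, epochs: int = 1200,
          wd_mode: str = "sinkhorn", sinkhorn_epsilon: float = 0.1,
          sinkhorn_iters: int = 30, seed: int = 0
          ) -> tuple[dict, dict, list[LossBreakdown]]:
    """Full-graph training with Adam and a step-decayed learning rate.

    Returns (params, final evaluation-mode state, per-epoch loss history).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    params = init_params(rng, inputs.X.shape[1], tuple(hidden_dims),
                         tuple(scales), aux_hidden)
    opt = _Adam(params, learning_rate)
    history: list[LossBreakdown] = []
    for epoch in range(epochs):
        state = reparameterize(encode(inputs, params), rng, sample=True)
        breakdown, grads = total_loss(
            inputs, state, params, rng=rng, wd_mode=wd_mode,
            sinkhorn_epsilon=sinkhorn_epsilon, sinkhorn_iters=sinkhorn_iters,
            with_grads=True,
        )
        if not np.isfinite(breakdown.total):
            raise FloatingPointError(f"loss became non-finite at epoch {epoch}")
        lr = learning_rate * lr_gamma ** (epoch // lr_step)
        opt.step(params, grads, lr)
        history.append(breakdown)
    final_state = reparameterize(encode(inputs, params), sample=False)
    return params, final_state, history


def embed(inputs: GraphInputs, params: dict) -> np.ndarray:
    """Evaluation-mode node embedding: concatenated per-scale means
    (no sampling), rows ordered as the input labels."""
    state = reparameterize(encode(inputs, params), sample=False)
    return state["Z"]


# ----------------------------------------------------------------- estimator

class MultiScaleVGAE(BaseEstimator, TransformerMixin):
    """sklearn-style graph transformer around :func:`train` / :func:`embed`.

    ``fit(adjacency, features)`` trains on one graph;
    ``transform(adjacency, features)`` embeds a graph with the learned
    weights (defaults to the training graph). Fitted attributes:
    ``params_``, ``loss_history_``, ``embedding_``, ``labels_``.
    """

    def __init__(self, scales=(16, 32, 64), hidden_dims=(256, 128),
                 aux_hidden=128, learning_rate=0.001, lr_step=300,
                 lr_gamma=0.5, epochs=1200, wd_mode="sinkhorn",
                 sinkhorn_epsilon=0.1, sinkhorn_iters=30, random_state=0):
        self.scales = scales
        self.hidden_dims = hidden_dims
        self.aux_hidden = aux_hidden
        self.learning_rate = learning_rate
        self.lr_step = lr_step
        self.lr_gamma = lr_gamma
        self.epochs = epochs
        self.wd_mode = wd_mode
        self.sinkhorn_epsilon = sinkhorn_epsilon
        self.sinkhorn_iters = sinkhorn_iters
        self.random_state = random_state

    def _inputs(self, adjacency, features) -> GraphInputs:
        labels = None
        if isinstance(adjacency, SimilarityMatrix):
            labels = list(adjacency.labels)
            adjacency = adjacency.values
        return GraphInputs(adjacency, np.asarray(features, dtype=float),
                           labels=labels)

    def fit(self, adjacency, features):
        inputs = self._inputs(adjacency, features)
        params, state, history = train(
            inputs, scales=tuple(self.scales), hidden_dims=tuple(self.hidden_dims),
            aux_hidden=self.aux_hidden, learning_rate=self.learning_rate,
            lr_step=self.lr_step, lr_gamma=self.lr_gamma, epochs=self.epochs,
            wd_mode=self.wd_mode, sinkhorn_epsilon=self.sinkhorn_epsilon,
            sinkhorn_iters=self.sinkhorn_iters, seed=self.random_state,
        )
        self.params_ = params
        self.loss_history_ = history
        self.embedding_ = state["Z"]
        self.labels_ = inputs.labels
        self.n_features_in_ = inputs.X.shape[1]
        return self

    def transform(self, adjacency=None, features=None):
        if not hasattr(self, "params_"):
            raise AttributeError("MultiScaleVGAE is not fitted")
        if adjacency is None:
            return self.embedding_
        return embed(self._inputs(adjacency, features), self.params_)

    def fit_transform(self, adjacency, features=None, **fit_params):
        return self.fit(adjacency, features).transform(None)
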