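"""Hypergraph variational autoencoder (HGVAE).

The encoder applies two hypergraph-convolution layers

    X^(l+1) = ReLU(A X^(l) Theta^(l)),   A = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}

with the second layer forking into two linear heads that emit the mean and
log-variance of a diagonal Gaussian posterior per node. A latent sample
z_i = mu_i + sigma_i * eps_i (reparameterization trick) feeds two heads of
the decoder: (i) an attention module that pools the member latents of every
hyperedge into a hyperedge embedding e_k via a two-layer LeakyReLU scoring
network and a softmax over members, and (ii) an inner-product reconstruction
H_hat[i,k] = sigmoid(z_i . e_k) of the incidence matrix. Training minimizes
the negative evidence lower bound: (positive-class weighted) binary
cross-entropy of H_hat against H plus the closed-form KL divergence of the
posterior from the standard-normal prior.

Everything is plain NumPy: the backward pass is hand-derived and checked
against finite differences in the test suite. Training is full batch, which
is adequate for networks up to ~10^4 nodes.

Ablation switches: ``feature_mode="onehot"`` replaces the sequence features
with node identity (topology only); ``propagation="identity"`` bypasses the
network smoothing (sequence only); ``propagation="gcn"`` together with
``decoder="adjacency"`` gives a conventional variational graph autoencoder
that reconstructs the pairwise adjacency matrix instead of the incidence.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._optim import Adam
from .hypergraph import AttributedHypergraph, propagation_operator

__all__ = [
    "HGVAEConfig",
    "LatentState",
    "hgnn_layer",
    "reparameterize",
    "hyperedge_pool",
    "decode",
    "elbo_loss",
    "kl_divergence",
    "train_hgvae",
    "save_hgvae",
    "load_hgvae",
    "HGVAE",
]

_EPS = 1e-7  # probability clamp in the reconstruction likelihood


@dataclass
class HGVAEConfig:
    input_dim: int = 343
    hidden_dim: int = 256
    latent_dim: int = 100
    proj_dim: int = 64            # width of the attention scoring network
    learning_rate: float = 1e-3
    epochs: int = 200
    dropout_rate: float = 0.0
    seed: int = 0
    reconstruction_pos_weight_mode: str = "auto"   # "auto" | "none"
    leaky_slope: float = 0.01
    feature_mode: str = "ct"       # "ct" | "onehot"
    propagation: str = "hypergraph"  # "hypergraph" | "identity" | "gcn"
    decoder: str = "hyperedge"     # "hyperedge" | "adjacency"

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid HGVAE configuration")


@dataclass
class LatentState:
    mu: np.ndarray                      # |V| x d
    log_var: np.ndarray                 # |V| x d
    z: np.ndarray                       # |V| x d sample
    hyperedge_embed: np.ndarray | None  # |E| x d
    attention: list[np.ndarray] | None  # per-hyperedge weights, each sums to 1


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def hgnn_layer(X_in: np.ndarray, A: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """One hypergraph-convolution layer: ReLU(A X theta).

    The final encoder layer (emitting mu and log-var) omits the ReLU; that
    variant is simply ``A @ X_in @ theta``.
    """
    if X_in.shape[1] != theta.shape[0] or A.shape[1] != X_in.shape[0]:
        raise ValueError(
            f"shape mismatch: A {A.shape}, X {X_in.shape}, theta {theta.shape}"
        )
    return np.maximum(A @ X_in @ theta, 0.0)


def reparameterize(
    mu: np.ndarray, log_var: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """z = mu + exp(log_var / 2) * eps with eps ~ N(0, I) from a seeded RNG."""
    if mu.shape != log_var.shape:
        raise ValueError("mu and log_var shapes differ")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eps = rng.standard_normal(mu.shape)
    return mu + np.exp(0.5 * log_var) * eps


def kl_divergence(mu: np.ndarray, log_var: np.ndarray) -> float:
    """Closed-form KL(q || N(0, I)) averaged over nodes:
    (1/2n) sum(mu^2 + sigma^2 - 1 - log sigma^2)."""
    n = mu.shape[0]
    return float(0.5 * np.sum(mu**2 + np.exp(log_var) - 1.0 - log_var) / n)


def elbo_loss(
    H: np.ndarray,
    H_hat: np.ndarray,
    mu: np.ndarray,
    log_var: np.ndarray,
    pos_weight: float = 1.0,
) -> float:
    """Negative ELBO: weighted BCE reconstruction (mean over entries) + KL.

    Probabilities at exactly 0 or 1 are clamped to [_EPS, 1 - _EPS].
    """
    P = np.clip(H_hat, _EPS, 1.0 - _EPS)
    bce = -(pos_weight * H * np.log(P) + (1.0 - H) * np.log(1.0 - P)).mean()
    return bce + kl_divergence(mu, log_var)


def _segment_softmax(
    scores: np.ndarray, starts: np.ndarray, edge_idx: np.ndarray
) -> np.ndarray:
    """Softmax of a flat score vector within contiguous segments."""
    seg_max = np.maximum.reduceat(scores, starts)
    ex = np.exp(scores - seg_max[edge_idx])
    seg_sum = np.add.reduceat(ex, starts)
    return ex / seg_sum[edge_idx]


def hyperedge_pool(
    z: np.ndarray,
    hg: AttributedHypergraph,
    proj_params: dict[str, np.ndarray],
    leaky_slope: float = 0.01,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Attention-pool node latents into hyperedge embeddings.

    Per hyperedge k with member latents Z_k: each member receives a scalar
    score from a two-layer LeakyReLU projection; the softmax of the scores
    over the members gives the attention weights; the hyperedge embedding is
    LeakyReLU of the attention-weighted sum of member latents.
    """
    if z.shape[0] != hg.n_nodes:
        raise ValueError("z rows must align with hypergraph nodes")
    node_idx, edge_idx = hg.memberships()
    counts = hg.H.sum(axis=0).astype(int)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    zm = z[node_idx]
    t1 = zm @ proj_params["P1"] + proj_params["bp1"]
    a1 = _leaky(t1, leaky_slope)
    s = _leaky((a1 @ proj_params["P2"]).ravel() + proj_params["bp2"][0], leaky_slope)
    att = _segment_softmax(s, starts, edge_idx)
    pooled = np.zeros((hg.n_hyperedges, z.shape[1]))
    np.add.at(pooled, edge_idx, att[:, None] * zm)
    embed = _leaky(pooled, leaky_slope)
    att_list = [
        att[starts[k] : starts[k] + counts[k]] for k in range(hg.n_hyperedges)
    ]
    return embed, att_list


def decode(z: np.ndarray, hyperedge_embed: np.ndarray) -> np.ndarray:
    """Inner-product reconstruction: H_hat[i,j] = sigmoid(z_i . e_j)."""
    if z.shape[1] != hyperedge_embed.shape[1]:
        raise ValueError("latent dimensions differ")
    return _sigmoid(z @ hyperedge_embed.T)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class HGVAE:
    """The autoencoder: parameters, forward/backward passes, training loop."""

    def __init__(self, config: HGVAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.params: dict[str, np.ndarray] = {
            "W1": _glorot(rng, c.input_dim, c.hidden_dim),
            "b1": np.zeros(c.hidden_dim),
            "Wmu": _glorot(rng, c.hidden_dim, c.latent_dim),
            "bmu": np.zeros(c.latent_dim),
            "Wlv": _glorot(rng, c.hidden_dim, c.latent_dim),
            "blv": np.zeros(c.latent_dim),
        }
        if c.decoder == "hyperedge":
            self.params.update(
                {
                    "P1": _glorot(rng, c.latent_dim, c.proj_dim),
                    "bp1": np.zeros(c.proj_dim),
                    "P2": _glorot(rng, c.proj_dim, 1),
                    "bp2": np.zeros(1),
                }
            )
        self._rng = rng
        self.loss_trace: list[float] = []

    # ---------------------------------------------------------------- forward

    def encode(self, A: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic encoder pass: (mu, log_var), each |V| x d."""
        p = self.params
        h = np.maximum(A @ X @ p["W1"] + p["b1"], 0.0)
        Ah = A @ h
        return Ah @ p["Wmu"] + p["bmu"], Ah @ p["Wlv"] + p["blv"]

    def _forward_backward(
        self,
        A: np.ndarray,
        X: np.ndarray,
        target: np.ndarray,
        eps: np.ndarray,
        memb: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None,
        pos_weight: float,
        dropout_mask: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """One full-batch loss evaluation plus hand-derived gradients.

        ``target`` is the incidence matrix H (hyperedge decoder) or the
        self-looped adjacency (adjacency decoder). ``memb`` carries the
        flattened hyperedge membership arrays or None for adjacency mode.
        """
        p = self.config
        par = self.params
        n = X.shape[0]

        AX = A @ X
        h_pre = AX @ par["W1"] + par["b1"]
        h = np.maximum(h_pre, 0.0)
        if dropout_mask is not None:
            h = h * dropout_mask
        Ah = A @ h
        mu = Ah @ par["Wmu"] + par["bmu"]
        lv = Ah @ par["Wlv"] + par["blv"]
        sig = np.exp(0.5 * lv)
        z = mu + sig * eps

        if memb is not None:
            node_idx, edge_idx, starts, counts = memb
            zm = z[node_idx]
            t1 = zm @ par["P1"] + par["bp1"]
            a1 = _leaky(t1, p.leaky_slope)
            s_pre = (a1 @ par["P2"]).ravel() + par["bp2"][0]
            s = _leaky(s_pre, p.leaky_slope)
            att = _segment_softmax(s, starts, edge_idx)
            pooled = np.zeros((len(counts), z.shape[1]))
            np.add.at(pooled, edge_idx, att[:, None] * zm)
            e = _leaky(pooled, p.leaky_slope)
            logits = z @ e.T
        else:
            logits = z @ z.T

        sgm = _sigmoid(logits)
        P = np.clip(sgm, _EPS, 1.0 - _EPS)
        N = logits.size
        bce = -(
            pos_weight * target * np.log(P) + (1.0 - target) * np.log(1.0 - P)
        ).mean()
        kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv) / n
        loss = bce + kl

        # ---- backward ----
        G = (sgm * (pos_weight * target + 1.0 - target) - pos_weight * target) / N
        grads: dict[str, np.ndarray] = {}

        if memb is not None:
            gz = G @ e
            ge = G.T @ z
            gpooled = ge * _leaky_grad(pooled, p.leaky_slope)
            gatt = np.einsum("md,md->m", gpooled[edge_idx], zm)
            gzm = att[:, None] * gpooled[edge_idx]
            seg_dot = np.add.reduceat(att * gatt, starts)
            gs = att * (gatt - seg_dot[edge_idx])
            gs = gs * _leaky_grad(s_pre, p.leaky_slope)
            grads["P2"] = a1.T @ gs[:, None]
            grads["bp2"] = np.array([gs.sum()])
            ga1 = gs[:, None] * par["P2"].ravel()[None, :]
            gt1 = ga1 * _leaky_grad(t1, p.leaky_slope)
            grads["P1"] = zm.T @ gt1
            grads["bp1"] = gt1.sum(axis=0)
            gzm = gzm + gt1 @ par["P1"].T
            gz_att = np.zeros_like(z)
            np.add.at(gz_att, node_idx, gzm)
            gz = gz + gz_att
        else:
            gz = (G + G.T) @ z

        gmu = gz + mu / n
        glv = gz * (0.5 * sig * eps) + 0.5 * (np.exp(lv) - 1.0) / n

        gAh = gmu @ par["Wmu"].T + glv @ par["Wlv"].T
        grads["Wmu"] = Ah.T @ gmu
        grads["bmu"] = gmu.sum(axis=0)
        grads["Wlv"] = Ah.T @ glv
        grads["blv"] = glv.sum(axis=0)
        gh = A.T @ gAh
        if dropout_mask is not None:
            gh = gh * dropout_mask
        gh_pre = gh * (h_pre > 0)
        grads["W1"] = AX.T @ gh_pre
        grads["b1"] = gh_pre.sum(axis=0)
        return loss, grads

    # ----------------------------------------------------------------- train

    def fit(self, hg: AttributedHypergraph) -> LatentState:
        c = self.config
        if c.feature_mode == "onehot":
            X = np.eye(hg.n_nodes)
        else:
            if hg.X is None:
                raise ValueError("hypergraph carries no feature matrix")
            X = hg.X
        if X.shape[1] != c.input_dim:
            raise ValueError(
                f"config.input_dim={c.input_dim} but features have {X.shape[1]} columns"
            )

        if c.propagation == "identity":
            A = np.eye(hg.n_nodes)
        elif c.propagation == "gcn":
            A = _gcn_operator(hg)
        elif c.propagation == "hypergraph":
            A = propagation_operator(hg)
        else:
            raise ValueError(f"unknown propagation mode {c.propagation!r}")

        if c.decoder == "hyperedge":
            target = hg.H
            node_idx, edge_idx = hg.memberships()
            counts = hg.H.sum(axis=0).astype(int)
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            memb = (node_idx, edge_idx, starts, counts)
        elif c.decoder == "adjacency":
            adj = (hg.H @ hg.H.T > 0).astype(float)
            np.fill_diagonal(adj, 1.0)
            target, memb = adj, None
        else:
            raise ValueError(f"unknown decoder mode {c.decoder!r}")

        n_ones = target.sum()
        n_zeros = target.size - n_ones
        if c.reconstruction_pos_weight_mode == "auto" and n_ones > 0:
            pos_weight = float(n_zeros / n_ones)
        else:
            pos_weight = 1.0

        opt = Adam(self.params, lr=c.learning_rate)
        rng = self._rng
        self.loss_trace = []
        n, d = hg.n_nodes, c.latent_dim
        for _ in range(c.epochs):
            eps = rng.standard_normal((n, d))
            mask = None
            if c.dropout_rate > 0:
                keep = 1.0 - c.dropout_rate
                mask = (rng.random((n, c.hidden_dim)) < keep) / keep
            loss, grads = self._forward_backward(
                A, X, target, eps, memb, pos_weight, mask
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {len(self.loss_trace)}: {loss}"
                )
            self.loss_trace.append(float(loss))
            opt.step(grads)

        mu, lv = self.encode(A, X)
        z = reparameterize(mu, lv, rng)
        if c.decoder == "hyperedge":
            embed, att = hyperedge_pool(
                mu, hg, self.params, leaky_slope=c.leaky_slope
            )
        else:
            embed, att = None, None
        return LatentState(
            mu=mu, log_var=lv, z=z, hyperedge_embed=embed, attention=att
        )


def _gcn_operator(hg: AttributedHypergraph) -> np.ndarray:
    """Symmetric GCN normalization D^{-1/2}(Adj + I)D^{-1/2} of the pairwise
    adjacency implied by hyperedge co-membership."""
    adj = (hg.H @ hg.H.T > 0).astype(float)
    np.fill_diagonal(adj, 1.0)
    deg = adj.sum(axis=1)
    dis = 1.0 / np.sqrt(deg)
    return dis[:, None] * adj * dis[None, :]


def train_hgvae(
    hg: AttributedHypergraph, config: HGVAEConfig
) -> tuple[HGVAE, LatentState]:
    """Train an HGVAE on an attributed hypergraph; returns the trained model
    and the latent state, whose ``mu`` is the canonical node embedding."""
    model = HGVAE(config)
    latent = model.fit(hg)
    return model, latent


def _node_order_hash(nodes: list[str]) -> str:
    return hashlib.sha256("\n".join(nodes).encode()).hexdigest()[:16]


def save_hgvae(model: HGVAE, nodes: list[str], path: str | Path) -> None:
    """Checkpoint: parameters + config + node-order hash (npz + json sidecar)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    meta = {"config": asdict(model.config), "node_order_hash": _node_order_hash(nodes)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_hgvae(path: str | Path, nodes: list[str] | None = None) -> HGVAE:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if nodes is not None and meta["node_order_hash"] != _node_order_hash(nodes):
        raise ValueError("node order does not match checkpoint")
    model = HGVAE(HGVAEConfig(**meta["config"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.params = {k: data[k] for k in data.files}
    return model
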