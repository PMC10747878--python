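"""The learnable multimodal pipeline, implemented in plain numpy.

Architecture, per subject:

* two edge-weighted graph-convolution layers
  ``h_i <- W1 h_i + W2 sum_{j in N_i} omega_ji h_j``
  (node features R -> d1 -> d2), each followed by batch normalization and a
  ReLU; the edge weights omega are |partial correlation|;
* global max pooling over nodes gives the graph representation g (length d2);
* a phenotypic feature extractor (MLP with L hidden layers, default L=1,
  output dimension d2) gives p' from the encoded phenotype vector;
* the concatenation A = g ⊕ p' (length D = 2 d2) is re-weighted by
  scaled dot-product self-attention computed *per subject*: the D x D score
  matrix A Aᵀ / D is row-softmaxed and applied to A;
* a classifier head (dense -> ReLU -> dense) emits 2 logits, trained with
  mean cross-entropy.

Forward and backward passes are written out explicitly; the analytic
gradients are validated against finite differences in the test suite.  All
randomness (initialization, batching) flows from explicit seeds, so training
is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MultimodalGraphClassifier",
    "Adam",
    "cross_entropy_loss",
    "global_max_pool",
    "graphconv_forward",
    "attention_fuse",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
LOG_EPS = 1e-12  # clamp inside log() of the loss


def graphconv_forward(
    node_feats: np.ndarray, adjacency: np.ndarray, w_self: np.ndarray, w_neigh: np.ndarray
) -> np.ndarray:
    """One edge-weighted graph convolution: ``X W1 + (A X) W2``.

    ``adjacency`` is the dense symmetric weighted adjacency (zero diagonal);
    an isolated node receives only its self term.  Accepts a single graph
    (R x d) or a batch (B x R x d with B x R x R adjacency).
    """
    x = np.asarray(node_feats, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    return x @ w_self + (a @ x) @ w_neigh


def global_max_pool(node_feats: np.ndarray) -> np.ndarray:
    """Elementwise maximum over nodes: the graph-level representation."""
    x = np.asarray(node_feats, dtype=float)
    if x.shape[-2] == 0:
        raise ValueError("empty node set")
    return x.max(axis=-2)


def attention_fuse(g: np.ndarray, p_prime: np.ndarray | None) -> np.ndarray:
    """Scaled dot-product self-attention over the fused vector, per subject.

    A = g ⊕ p' (p' omitted when None); scores S = (A outer A) / D, rows
    softmaxed to alpha; returns alpha @ A.  Stateless convenience wrapper for
    a single subject or a batch.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if p_prime is not None:
        p_prime = np.atleast_2d(np.asarray(p_prime, dtype=float))
        if p_prime.shape != g.shape:
            raise ValueError("g and p_prime must have the same shape")
        a = np.concatenate([g, p_prime], axis=1)
    else:
        a = g
    fused, _ = _attention_forward(a)
    return fused[0] if fused.shape[0] == 1 and np.asarray(g).ndim == 1 else fused


def _attention_forward(a: np.ndarray):
    d = a.shape[1]
    s = a[:, :, None] * a[:, None, :] / d
    s = s - s.max(axis=2, keepdims=True)
    e = np.exp(s)
    alpha = e / e.sum(axis=2, keepdims=True)
    fused = np.einsum("bij,bj->bi", alpha, a)
    return fused, alpha


def _attention_backward(dfused: np.ndarray, a: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    d = a.shape[1]
    # direct path: fused_i = sum_j alpha_ij a_j
    da = np.einsum("bij,bi->bj", alpha, dfused)
    dalpha = np.einsum("bi,bj->bij", dfused, a)
    ds = alpha * (dalpha - (dalpha * alpha).sum(axis=2, keepdims=True))
    da += np.einsum("bij,bj->bi", ds, a) / d
    da += np.einsum("bij,bi->bj", ds, a) / d
    return da


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray, eps: float = LOG_EPS) -> float:
    """Mean negative log-probability of the true class, log clamped at eps."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("probs must be K x 2")
    if probs.shape[0] == 0:
        raise ValueError("need at least one subject")
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p_true, eps))))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    lim = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-lim, lim, size=shape)


class MultimodalGraphClassifier:
    """Two GraphConv layers + PFE + attention fusion + classifier head.

    Parameters
    ----------
    n_roi : node count R (node features are the R-dim Pearson rows).
    pheno_dim : length of the encoded phenotype vector (0 disables the branch).
    d1, d2 : hidden widths of the two graph convolutions.
    clf_hidden : width of the classifier's hidden dense layer.
    pfe_layers : number of affine+activation layers in the PFE (the default
        single layer is ``p' = ReLU(W p + b)``).
    use_phenotype : when False the model is imaging-only (A = g, D = d2).
    """

    def __init__(
        self,
        n_roi: int,
        pheno_dim: int = 0,
        d1: int = 64,
        d2: int = 16,
        clf_hidden: int = 32,
        pfe_layers: int = 1,
        use_phenotype: bool = True,
        seed: int = 0,
    ):
        self.n_roi = n_roi
        self.pheno_dim = pheno_dim
        self.d1, self.d2 = d1, d2
        self.clf_hidden = clf_hidden
        self.pfe_layers = pfe_layers
        self.use_phenotype = use_phenotype and pheno_dim > 0
        rng = np.random.default_rng(seed)

        p: dict[str, np.ndarray] = {}
        p["conv1_w_self"] = _glorot(rng, (n_roi, d1))
        p["conv1_w_neigh"] = _glorot(rng, (n_roi, d1))
        p["bn1_gamma"] = np.ones(d1)
        p["bn1_beta"] = np.zeros(d1)
        p["conv2_w_self"] = _glorot(rng, (d1, d2))
        p["conv2_w_neigh"] = _glorot(rng, (d1, d2))
        p["bn2_gamma"] = np.ones(d2)
        p["bn2_beta"] = np.zeros(d2)
        if self.use_phenotype:
            din = pheno_dim
            for layer in range(pfe_layers):
                p[f"pfe_w{layer}"] = _glorot(rng, (din, d2))
                p[f"pfe_b{layer}"] = np.zeros(d2)
                din = d2
        fuse_dim = 2 * d2 if self.use_phenotype else d2
        p["clf_w1"] = _glorot(rng, (fuse_dim, clf_hidden))
        p["clf_b1"] = np.zeros(clf_hidden)
        p["clf_w2"] = _glorot(rng, (clf_hidden, 2))
        p["clf_b2"] = np.zeros(2)
        self.params = p
        self.fuse_dim = fuse_dim

        # batch-norm running statistics (state, not trainable parameters)
        self.bn_state = {
            "bn1_mean": np.zeros(d1),
            "bn1_var": np.ones(d1),
            "bn2_mean": np.zeros(d2),
            "bn2_var": np.ones(d2),
        }

    # ---------------------------------------------------------------- forward

    def _bn_forward(self, z: np.ndarray, name: str, training: bool):
        gamma, beta = self.params[f"{name}_gamma"], self.params[f"{name}_beta"]
        flat = z.reshape(-1, z.shape[-1])
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            st = self.bn_state
            st[f"{name}_mean"] = (1 - _BN_MOMENTUM) * st[f"{name}_mean"] + _BN_MOMENTUM * mean
            st[f"{name}_var"] = (1 - _BN_MOMENTUM) * st[f"{name}_var"] + _BN_MOMENTUM * var
        else:
            mean = self.bn_state[f"{name}_mean"]
            var = self.bn_state[f"{name}_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (flat - mean) * inv_std
        out = (gamma * xhat + beta).reshape(z.shape)
        return out, (xhat, inv_std, z.shape, training)

    def _bn_backward(self, dout: np.ndarray, name: str, cache):
        xhat, inv_std, shape, training = cache
        gamma = self.params[f"{name}_gamma"]
        dflat = dout.reshape(-1, dout.shape[-1])
        dgamma = (dflat * xhat).sum(axis=0)
        dbeta = dflat.sum(axis=0)
        if training:
            n = dflat.shape[0]
            dxhat = dflat * gamma
            dx = inv_std * (
                dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
            )
        else:
            dx = dflat * gamma * inv_std
        return dx.reshape(shape), dgamma, dbeta

    def forward(
        self,
        node_feats: np.ndarray,
        adjacency: np.ndarray,
        pheno: np.ndarray | None,
        training: bool = False,
    ):
        """Batched forward pass; returns (logits, cache).

        ``node_feats``: B x R x R, ``adjacency``: B x R x R (symmetric,
        zero-diagonal, nonnegative weights), ``pheno``: B x pheno_dim.
        """
        p = self.params
        x = np.asarray(node_feats, dtype=float)
        a = np.asarray(adjacency, dtype=float)

        m1 = a @ x
        z1 = x @ p["conv1_w_self"] + m1 @ p["conv1_w_neigh"]
        b1, bn1_cache = self._bn_forward(z1, "bn1", training)
        h1 = np.maximum(b1, 0.0)

        m2 = a @ h1
        z2 = h1 @ p["conv2_w_self"] + m2 @ p["conv2_w_neigh"]
        b2, bn2_cache = self._bn_forward(z2, "bn2", training)
        h2 = np.maximum(b2, 0.0)

        argmax = h2.argmax(axis=1)  # B x d2 node index of each channel max
        g = np.take_along_axis(h2, argmax[:, None, :], axis=1)[:, 0, :]

        pfe_cache = []
        if self.use_phenotype:
            cur = np.asarray(pheno, dtype=float)
            for layer in range(self.pfe_layers):
                pre = cur @ p[f"pfe_w{layer}"] + p[f"pfe_b{layer}"]
                out = np.maximum(pre, 0.0)
                pfe_cache.append((cur, pre))
                cur = out
            fused_in = np.concatenate([g, cur], axis=1)
        else:
            fused_in = g

        fused, alpha = _attention_forward(fused_in)

        c1 = fused @ p["clf_w1"] + p["clf_b1"]
        hclf = np.maximum(c1, 0.0)
        logits = hclf @ p["clf_w2"] + p["clf_b2"]

        cache = dict(
            x=x, a=a, m1=m1, b1=b1, bn1_cache=bn1_cache, h1=h1,
            m2=m2, b2=b2, bn2_cache=bn2_cache, h2=h2, argmax=argmax,
            pfe_cache=pfe_cache, fused_in=fused_in, fused=fused, alpha=alpha,
            c1=c1, hclf=hclf,
        )
        return logits, cache

    # --------------------------------------------------------------- backward

    def loss_and_grads(self, node_feats, adjacency, pheno, labels, training: bool = True):
        """Mean cross-entropy loss and analytic gradients for one batch."""
        labels = np.asarray(labels, dtype=int)
        logits, cache = self.forward(node_feats, adjacency, pheno, training=training)
        probs = _softmax(logits)
        k = len(labels)
        loss = cross_entropy_loss(probs, labels)

        p = self.params
        grads = {name: np.zeros_like(val) for name, val in p.items()}

        dlogits = probs.copy()
        dlogits[np.arange(k), labels] -= 1.0
        dlogits /= k

        grads["clf_w2"] = cache["hclf"].T @ dlogits
        grads["clf_b2"] = dlogits.sum(axis=0)
        dhclf = dlogits @ p["clf_w2"].T
        dc1 = dhclf * (cache["c1"] > 0)
        grads["clf_w1"] = cache["fused"].T @ dc1
        grads["clf_b1"] = dc1.sum(axis=0)
        dfused = dc1 @ p["clf_w1"].T

        dfused_in = _attention_backward(dfused, cache["fused_in"], cache["alpha"])

        if self.use_phenotype:
            dg = dfused_in[:, : self.d2]
            dcur = dfused_in[:, self.d2 :]
            for layer in reversed(range(self.pfe_layers)):
                inp, pre = cache["pfe_cache"][layer]
                dpre = dcur * (pre > 0)
                grads[f"pfe_w{layer}"] = inp.T @ dpre
                grads[f"pfe_b{layer}"] = dpre.sum(axis=0)
                dcur = dpre @ p[f"pfe_w{layer}"].T
        else:
            dg = dfused_in

        dh2 = np.zeros_like(cache["h2"])
        np.put_along_axis(dh2, cache["argmax"][:, None, :], dg[:, None, :], axis=1)

        db2 = dh2 * (cache["b2"] > 0)
        dz2, grads["bn2_gamma"], grads["bn2_beta"] = self._bn_backward(
            db2, "bn2", cache["bn2_cache"]
        )
        grads["conv2_w_self"] = np.einsum("bri,brj->ij", cache["h1"], dz2)
        grads["conv2_w_neigh"] = np.einsum("bri,brj->ij", cache["m2"], dz2)
        dm2 = dz2 @ p["conv2_w_neigh"].T
        dh1 = dz2 @ p["conv2_w_self"].T + np.einsum("bsr,bsj->brj", cache["a"], dm2)

        db1 = dh1 * (cache["b1"] > 0)
        dz1, grads["bn1_gamma"], grads["bn1_beta"] = self._bn_backward(
            db1, "bn1", cache["bn1_cache"]
        )
        grads["conv1_w_self"] = np.einsum("bri,brj->ij", cache["x"], dz1)
        grads["conv1_w_neigh"] = np.einsum("bri,brj->ij", cache["m1"], dz1)

        return loss, grads

    def decay_exempt_params(self) -> set[str]:
        """Names of parameters excluded from L2 weight decay: batch-norm
        gains/shifts and every bias vector."""
        exempt = set()
        for name in self.params:
            if name.startswith("bn") or name.startswith("pfe_b") or name in {"clf_b1", "clf_b2"}:
                exempt.add(name)
        return exempt

    # ------------------------------------------------------------- inference

    def predict_proba(self, node_feats, adjacency, pheno=None) -> np.ndarray:
        """Class probabilities in evaluation mode (running BN statistics)."""
        logits, _ = self.forward(node_feats, adjacency, pheno, training=False)
        return _softmax(logits)

    # ----------------------------------------------------------- persistence

    def state_dict(self) -> dict:
        return {
            "config": {
                "n_roi": self.n_roi,
                "pheno_dim": self.pheno_dim,
                "d1": self.d1,
                "d2": self.d2,
                "clf_hidden": self.clf_hidden,
                "pfe_layers": self.pfe_layers,
                "use_phenotype": self.use_phenotype,
            },
            "params": {k: v.tolist() for k, v in self.params.items()},
            "bn_state": {k: v.tolist() for k, v in self.bn_state.items()},
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MultimodalGraphClassifier":
        cfg = state["config"]
        model = cls(
            n_roi=cfg["n_roi"],
            pheno_dim=cfg["pheno_dim"],
            d1=cfg["d1"],
            d2=cfg["d2"],
            clf_hidden=cfg["clf_hidden"],
            pfe_layers=cfg["pfe_layers"],
            use_phenotype=cfg["use_phenotype"],
        )
        model.params = {k: np.asarray(v, dtype=float) for k, v in state["params"].items()}
        model.bn_state = {k: np.asarray(v, dtype=float) for k, v in state["bn_state"].items()}
        return model


class Adam:
    """Adam with L2 weight decay (decay added to the gradient) and bias
    correction.  Parameters named in ``no_decay`` — by convention the batch
    normalization gains/shifts and all bias vectors — are exempt from decay,
    the standard treatment that keeps normalization scales from collapsing."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        no_decay: set[str] | frozenset[str] = frozenset(),
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.no_decay = set(no_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, theta in self.params.items():
            wd = 0.0 if k in self.no_decay else self.weight_decay
            g = grads[k] + wd * theta
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            theta -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
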