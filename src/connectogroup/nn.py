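"""Graph neural networks for connectome classification, in numpy + numba.

Two message-passing variants are implemented:

* node concat (GCN):                psi(x_i, x_j) = MLP(x_i || x_j)
* node concat with attention (GAT): psi(x_i, x_j) = MLP(x_i || (x_j a_ij))

where ``||`` is vector concatenation and ``a_ij`` is a learned attention
coefficient computed from the endpoint features and normalized over each
node's neighborhood (single head).  With all a_ij fixed at 1 the attention
variant reduces exactly to the plain variant.  Messages are aggregated by
neighborhood mean, node states are mean-pooled into a graph embedding, and
a linear readout produces the class logit.

Because the message MLP's first stage is linear, the pair tensor never has
to be materialized: the i-part and j-part are projected separately
(x_i Wa + a_ij x_j Wb) and combined inside a fused numba kernel, which also
carries the hand-derived reverse-mode gradients.  Training uses Adam on a
class-weighted binary cross-entropy.  Everything is deterministic given the
seed.  :func:`message_pass` is the plain-numpy reference definition of the
operation, used as the oracle for the fused layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

LEAKY_ALPHA = 0.2


@dataclass(frozen=True)
class MessagePassingSpec:
    """Architecture of the message-passing stack."""

    variant: str = "node_concat"        # node_concat | node_concat_attention
    hidden_size: int = 16
    n_layers: int = 2
    readout: str = "mean"               # mean pooling over nodes

    def __post_init__(self) -> None:
        if self.variant not in ("node_concat", "node_concat_attention"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_layers < 1 or self.hidden_size < 1:
            raise ValueError("n_layers and hidden_size must be >= 1")
        if self.readout != "mean":
            raise ValueError("only mean-pool readout is implemented")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 30
    learning_rate: float = 1e-2
    batch_size: int = 16
    weight_decay: float = 1e-4
    class_weighted: bool = True


def message_pass(node_features: np.ndarray, adjacency: np.ndarray,
                 mlp=None, attention: np.ndarray | None = None) -> np.ndarray:
    """Reference single-layer message passing (the operation's definition).

    For every ordered neighbor pair (i, j) with w_ij > 0 the message is
    ``mlp(x_i || (x_j * a_ij))`` and node i's update is the mean of its
    incoming messages (nodes without neighbors keep a zero update).
    ``mlp=None`` is the identity (output dimension 2d); ``attention=None``
    means unit coefficients — the plain node-concat variant.
    """
    x = np.asarray(node_features, dtype=float)
    w = np.asarray(adjacency, dtype=float)
    n = x.shape[0]
    if w.shape != (n, n):
        raise ValueError(f"adjacency {w.shape} inconsistent with {n} node features")
    a = np.ones((n, n)) if attention is None else np.asarray(attention, dtype=float)
    if a.shape != (n, n):
        raise ValueError("attention matrix shape mismatch")
    if mlp is None:
        mlp = lambda z: z
    mask = w > 0
    pair = np.concatenate([
        np.broadcast_to(x[:, None, :], (n, n, x.shape[1])),
        a[:, :, None] * x[None, :, :],
    ], axis=-1)
    msg = mlp(pair.reshape(n * n, -1)).reshape(n, n, -1)
    msg = msg * mask[:, :, None]
    deg = mask.sum(axis=1)
    return msg.sum(axis=1) / np.maximum(deg, 1)[:, None]


# -- fused kernels -----------------------------------------------------------
# pre_ij = a1_i + att_ij * b1_j + bias; msg = relu(pre); out_i = mean_j msg.


@njit(cache=True)
def _fwd_kernel(a1, b1, bias, att, mask, deg, out, pre):
    B, N, h = a1.shape
    for b in range(B):
        for i in range(N):
            d = deg[b, i]
            for j in range(N):
                if mask[b, i, j]:
                    for k in range(h):
                        v = a1[b, i, k] + att[b, i, j] * b1[b, j, k] + bias[k]
                        pre[b, i, j, k] = v
                        if v > 0.0:
                            out[b, i, k] += v / d


@njit(cache=True)
def _bwd_kernel(dout, pre, att, b1, mask, deg, da1, db1, dbias, datt):
    B, N, h = dout.shape
    for b in range(B):
        for i in range(N):
            d = deg[b, i]
            for j in range(N):
                if mask[b, i, j]:
                    acc_att = 0.0
                    for k in range(h):
                        if pre[b, i, j, k] > 0.0:
                            g = dout[b, i, k] / d
                            dbias[k] += g
                            da1[b, i, k] += g
                            db1[b, j, k] += att[b, i, j] * g
                            acc_att += g * b1[b, j, k]
                    datt[b, i, j] += acc_att


def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / shape[0]), size=shape)


class GNNClassifier:
    """Binary graph classifier over fixed-size connectome graphs.

    Inputs are batches ``X`` of node-feature tensors (B, N, d) — connection
    profiles, so d = N — together with adjacency tensors (B, N, N) whose
    positive entries define the neighborhoods.
    """

    def __init__(self, n_node_features: int,
                 spec: MessagePassingSpec = MessagePassingSpec(),
                 train_cfg: TrainingConfig = TrainingConfig(),
                 seed: int = 0, unit_attention: bool = False):
        self.spec = spec
        self.cfg = train_cfg
        self.unit_attention = unit_attention
        rng = np.random.default_rng(seed)
        self._rng = rng
        h = spec.hidden_size
        self.params: dict[str, np.ndarray] = {}
        d_in = n_node_features
        for layer in range(spec.n_layers):
            self.params[f"Wa{layer}"] = _he(rng, (d_in, h))
            self.params[f"Wb{layer}"] = _he(rng, (d_in, h))
            self.params[f"b{layer}"] = np.zeros(h)
            if self._attentive:
                self.params[f"ua{layer}"] = rng.normal(0.0, 0.1, size=d_in)
                self.params[f"ub{layer}"] = rng.normal(0.0, 0.1, size=d_in)
            d_in = h
        self.params["w_out"] = rng.normal(0.0, 0.1, size=d_in)
        self.params["b_out"] = np.zeros(1)

    @property
    def _attentive(self) -> bool:
        return self.spec.variant == "node_concat_attention"

    # -- forward -------------------------------------------------------------

    def _layer_forward(self, layer: int, x: np.ndarray, mask: np.ndarray):
        """x: (B, N, d) -> (B, N, h), plus the cache for backprop."""
        p = self.params
        a1 = x @ p[f"Wa{layer}"]                        # (B, N, h)
        b1 = x @ p[f"Wb{layer}"]
        cache = {"x": x, "b1": b1, "mask": mask}
        if self._attentive and not self.unit_attention:
            pa = x @ p[f"ua{layer}"]                    # (B, N)
            qa = x @ p[f"ub{layer}"]
            e_raw = pa[:, :, None] + qa[:, None, :]
            e = np.where(e_raw > 0, e_raw, LEAKY_ALPHA * e_raw)
            e = np.where(mask, e, -np.inf)
            e_max = np.max(e, axis=2, keepdims=True)
            e_max = np.where(np.isfinite(e_max), e_max, 0.0)
            ex = np.exp(e - e_max) * mask
            denom = ex.sum(axis=2, keepdims=True)
            att = np.divide(ex, denom, out=np.zeros_like(ex), where=denom > 0)
            cache.update(e_raw=e_raw, att=att)
        else:
            att = np.ascontiguousarray(mask, dtype=float)
            cache["att"] = att
        B, N, h = a1.shape
        deg = np.maximum(mask.sum(axis=2), 1).astype(float)
        out = np.zeros((B, N, h))
        pre = np.zeros((B, N, N, h))
        _fwd_kernel(a1, b1, p[f"b{layer}"], att, mask, deg, out, pre)
        cache.update(pre=pre, deg=deg)
        return out, cache

    def forward(self, x: np.ndarray, adjacency: np.ndarray):
        """Logits (B,) plus caches for the backward pass."""
        x = np.ascontiguousarray(x, dtype=float)
        mask = np.ascontiguousarray(adjacency > 0)
        caches = []
        for layer in range(self.spec.n_layers):
            x, cache = self._layer_forward(layer, x, mask)
            caches.append(cache)
        g = x.mean(axis=1)                              # (B, h) mean-pool readout
        logits = g @ self.params["w_out"] + self.params["b_out"][0]
        return logits, (caches, g, x.shape[1])

    # -- backward ------------------------------------------------------------

    def _layer_backward(self, layer: int, dout: np.ndarray, cache: dict,
                        grads: dict[str, np.ndarray]) -> np.ndarray:
        p = self.params
        x, b1, att, mask = cache["x"], cache["b1"], cache["att"], cache["mask"]
        da1 = np.zeros_like(dout)
        db1 = np.zeros_like(b1)
        dbias = np.zeros_like(p[f"b{layer}"])
        datt = np.zeros_like(att)
        _bwd_kernel(np.ascontiguousarray(dout), cache["pre"], att, b1, mask,
                    cache["deg"], da1, db1, dbias, datt)
        grads[f"b{layer}"] += dbias
        d_flat, h = x.shape[-1], dout.shape[-1]
        grads[f"Wa{layer}"] += x.reshape(-1, d_flat).T @ da1.reshape(-1, h)
        grads[f"Wb{layer}"] += x.reshape(-1, d_flat).T @ db1.reshape(-1, h)
        dx = da1 @ p[f"Wa{layer}"].T + db1 @ p[f"Wb{layer}"].T
        if self._attentive and not self.unit_attention:
            de = att * (datt - (datt * att).sum(axis=2, keepdims=True))
            dz = de * np.where(cache["e_raw"] > 0, 1.0, LEAKY_ALPHA)
            dpa = dz.sum(axis=2)                        # (B, N)
            dqa = dz.sum(axis=1)
            grads[f"ua{layer}"] += np.einsum("bnd,bn->d", x, dpa)
            grads[f"ub{layer}"] += np.einsum("bnd,bn->d", x, dqa)
            dx += dpa[:, :, None] * p[f"ua{layer}"] + dqa[:, :, None] * p[f"ub{layer}"]
        return dx

    def backward(self, dlogits: np.ndarray, aux) -> dict[str, np.ndarray]:
        caches, g, n_nodes = aux
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["w_out"] += dlogits @ g
        grads["b_out"] += dlogits.sum()
        B = dlogits.shape[0]
        dx = np.tile((dlogits[:, None] * self.params["w_out"])[:, None, :] / n_nodes,
                     (1, n_nodes, 1))
        for layer in reversed(range(self.spec.n_layers)):
            dx = self._layer_backward(layer, dx, caches[layer], grads)
        return grads

    # -- training ------------------------------------------------------------

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    def loss_and_grads(self, x, adjacency, y, class_weight):
        logits, aux = self.forward(x, adjacency)
        prob = self._sigmoid(logits)
        cw = class_weight[y.astype(int)]
        eps = 1e-12
        loss = -np.mean(cw * (y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        dlogits = cw * (prob - y) / y.size
        grads = self.backward(dlogits, aux)
        for k in grads:
            if k.startswith(("Wa", "Wb")):
                loss += 0.5 * self.cfg.weight_decay * float((self.params[k] ** 2).sum())
                grads[k] += self.cfg.weight_decay * self.params[k]
        return loss, grads

    def fit(self, x: np.ndarray, adjacency: np.ndarray, y: np.ndarray) -> list[float]:
        """Adam on minibatches; y is 0/1 with 1 = positive class (PD)."""
        y = np.asarray(y, dtype=float)
        if self.cfg.class_weighted:
            n1 = y.sum()
            n0 = y.size - n1
            if n1 == 0 or n0 == 0:
                raise ValueError("training set contains a single class")
            class_weight = np.array([y.size / (2 * n0), y.size / (2 * n1)])
        else:
            class_weight = np.ones(2)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        step = 0
        history = []
        idx = np.arange(y.size)
        for epoch in range(self.cfg.epochs):
            self._rng.shuffle(idx)
            epoch_loss = 0.0
            for start in range(0, y.size, self.cfg.batch_size):
                sel = idx[start:start + self.cfg.batch_size]
                loss, grads = self.loss_and_grads(x[sel], adjacency[sel], y[sel],
                                                  class_weight)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, step {step}")
                step += 1
                lr = self.cfg.learning_rate
                for k, gk in grads.items():
                    m[k] = b1m * m[k] + (1 - b1m) * gk
                    v[k] = b2m * v[k] + (1 - b2m) * gk ** 2
                    mh = m[k] / (1 - b1m ** step)
                    vh = v[k] / (1 - b2m ** step)
                    self.params[k] -= lr * mh / (np.sqrt(vh) + eps)
                epoch_loss += loss * sel.size
            history.append(epoch_loss / y.size)
        return history

    def decision_function(self, x: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x, adjacency)
        return logits

    def predict_proba(self, x: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
        return self._sigmoid(self.decision_function(x, adjacency))

    def predict(self, x: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x, adjacency) >= 0.5).astype(int)
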