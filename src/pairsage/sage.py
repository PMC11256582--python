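"""Supervised GraphSAGE on the implicit drug-target pair graph.

A from-scratch numpy implementation: fixed-fanout neighbor sampling,
a choice of mean / max-pooling / LSTM aggregators, the concat-transform
layer update ``h^k = sigma(W_k . concat(h^{k-1}_self, AGG(h^{k-1}_nbrs)))``,
a sigmoid scoring head trained with binary cross-entropy, and manual
backpropagation with Adam.  Works for any depth K = len(fanouts).

The pair graph is never materialized: the sampler draws uniform neighbors
of pair node (i, j) directly from the closed form "same drug, other target"
/ "same target, other drug", so sampling a minibatch tree is a handful of
vectorized index operations even when the graph has a million nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dtp import DTPIndex

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration and parameters


@dataclass
class SageConfig:
    """Hyperparameters of the GraphSAGE stage.

    ``fanouts = (S1, S2)`` are the per-layer neighbor sample sizes; depth
    K equals ``len(fanouts)``.  Defaults follow the standard finding that
    two layers with S1*S2 <= 500 suffice: K=2, S1=50, S2=10.
    """

    fanouts: tuple[int, ...] = (50, 10)
    aggregator: str = "mean"  # mean | pooling | lstm
    hidden_dim: int = 128
    learning_rate: float = 0.001
    epochs: int = 15
    batch_size: int = 256
    seed: int = 0
    nonlinearity: str = "relu"
    dtype: str = "float32"  # float32 | float64 (numerics checks use float64)

    @property
    def K(self) -> int:
        return len(self.fanouts)

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.fanouts):
            raise ValueError("fanouts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.aggregator not in ("mean", "pooling", "lstm"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.nonlinearity not in ("relu", "tanh"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if int(np.prod(self.fanouts)) > 500:
            warnings.warn(
                "product of fanouts exceeds 500; two layers with S1*S2 <= 500 "
                "are usually sufficient and much cheaper"
            )


@dataclass
class SageParams:
    """Trained weights: per-layer W_k, aggregator state, scoring head."""

    W: list[np.ndarray]
    agg: list[dict[str, np.ndarray]]
    head_w: np.ndarray
    head_b: float

    def flat(self) -> list[tuple[str, np.ndarray]]:
        out = [(f"W{k}", self.W[k]) for k in range(len(self.W))]
        for k, d in enumerate(self.agg):
            out += [(f"agg{k}.{name}", arr) for name, arr in sorted(d.items())]
        out.append(("head_w", self.head_w))
        return out


@dataclass
class RefinedFeatures:
    """h^K vectors (the refined pair representations) for requested nodes."""

    node_ids: np.ndarray
    vectors: np.ndarray


# --------------------------------------------------------------------------
# elementary operations (exposed for direct use and testing)


def aggregate_mean(neighbor_feats) -> np.ndarray:
    """Element-wise arithmetic mean of a non-empty list of equal-length
    vectors."""
    arr = np.asarray(neighbor_feats, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty list of equal-length vectors")
    return arr.mean(axis=0)


def layer_update(h_self, h_nbr, W, nonlinearity: str = "relu") -> np.ndarray:
    """sigma(W . concat(h_self, h_nbr)) — the GraphSAGE layer update."""
    h_self = np.asarray(h_self, dtype=float)
    h_nbr = np.asarray(h_nbr, dtype=float)
    cat = np.concatenate([h_self, h_nbr])
    W = np.asarray(W, dtype=float)
    if W.shape[1] != cat.size:
        raise ValueError(f"W has {W.shape[1]} columns but concat input has {cat.size}")
    return _act(W @ cat, nonlinearity)


def cross_entropy(y, yhat) -> float:
    """Mean binary cross-entropy; predictions clipped to (1e-12, 1-1e-12)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("label and prediction lengths differ")
    p = np.clip(yhat, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(kind)


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "tanh":
        return 1.0 - a**2
    raise ValueError(kind)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# --------------------------------------------------------------------------
# neighbor samplers


class FullDTPSampler:
    """Uniform neighbor sampling from the full implicit pair graph.

    Every pair (i, j) has N_T - 1 same-drug and N_D - 1 same-target
    neighbors; a neighbor "rank" r < N_T - 1 maps to the r-th other
    target, larger ranks map to other drugs.  Sampling is therefore pure
    index arithmetic and never touches an adjacency structure.
    """

    def __init__(self, index: DTPIndex):
        self.index = index

    def sample_batch(self, nodes: np.ndarray, fanout: int, rng: np.random.Generator) -> np.ndarray:
        nodes = np.asarray(nodes, dtype=np.int64)
        nd, nt = self.index.n_drugs, self.index.n_targets
        deg = nd + nt - 2
        B = nodes.size
        if deg == 0:  # single-node graph: fill with the node itself
            return np.repeat(nodes[:, None], fanout, axis=1)
        if deg >= fanout:
            # distinct ranks per row via random-key argpartition
            keys = rng.random((B, deg))
            ranks = np.argpartition(keys, fanout - 1, axis=1)[:, :fanout]
        else:
            ranks = rng.integers(0, deg, size=(B, fanout))
        i, j = np.divmod(nodes, nt)
        is_drug_side = ranks < nt - 1
        jp = ranks + (ranks >= j[:, None])  # skip own target index
        same_drug = i[:, None] * nt + jp
        rp = ranks - (nt - 1)
        ip = rp + (rp >= i[:, None])  # skip own drug index
        same_target = ip * nt + j[:, None]
        return np.where(is_drug_side, same_drug, same_target)


class RestrictedSampler:
    """Neighbor sampling restricted to a given node subset (desk-scale
    "subgraph-only" mode: neighbors are drawn only among labeled sample
    nodes sharing the drug or the target)."""

    def __init__(self, index: DTPIndex, nodes: np.ndarray):
        self.index = index
        nodes = np.asarray(sorted(set(np.asarray(nodes, dtype=np.int64).tolist())))
        by_drug: dict[int, list[int]] = {}
        by_target: dict[int, list[int]] = {}
        for u in nodes.tolist():
            i, j = index.pair_of(int(u))
            by_drug.setdefault(i, []).append(u)
            by_target.setdefault(j, []).append(u)
        self._nbrs: dict[int, np.ndarray] = {}
        for u in nodes.tolist():
            i, j = index.pair_of(int(u))
            cand = set(by_drug[i]) | set(by_target[j])
            cand.discard(u)
            self._nbrs[u] = np.asarray(sorted(cand), dtype=np.int64)

    def neighbors(self, u: int) -> np.ndarray:
        return self._nbrs.get(int(u), np.empty(0, dtype=np.int64))

    def sample_batch(self, nodes: np.ndarray, fanout: int, rng: np.random.Generator) -> np.ndarray:
        nodes = np.asarray(nodes, dtype=np.int64)
        out = np.empty((nodes.size, fanout), dtype=np.int64)
        for b, u in enumerate(nodes.tolist()):
            nbrs = self.neighbors(u)
            if nbrs.size == 0:
                out[b] = u  # isolated: filled with the node itself
            elif nbrs.size >= fanout:
                out[b] = rng.choice(nbrs, size=fanout, replace=False)
            else:
                out[b] = rng.choice(nbrs, size=fanout, replace=True)
        return out


def dense_feature_fn(feature_fn, n_pairs: int, dtype, limit: int = 300_000):
    """Materialize all pair features once (in the training dtype) when the
    grid is small enough, so minibatch gathers are single fancy-index
    operations instead of repeated concatenations."""
    if n_pairs > limit:
        return feature_fn
    F = np.ascontiguousarray(
        feature_fn(np.arange(n_pairs, dtype=np.int64)), dtype=dtype
    )
    return F.__getitem__


def sample_neighborhood(
    sampler, u: int, fanouts: tuple[int, ...], seed: int = 0
) -> list[np.ndarray]:
    """Layered sample tree rooted at ``u``: layer 0 is ``[u]``, layer k
    holds ``fanouts[k-1]`` sampled neighbors of every layer-(k-1) node.

    Sampling is without replacement when a node's degree is at least the
    fanout (so the layer entries below one parent are distinct), with
    replacement otherwise; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    layers = [np.asarray([u], dtype=np.int64)]
    for k, fanout in enumerate(fanouts):
        parents = layers[-1].reshape(-1)
        child = sampler.sample_batch(parents, fanout, rng)
        layers.append(child.reshape(layers[-1].shape + (fanout,)))
    return layers


# --------------------------------------------------------------------------
# aggregators (batched forward/backward over (M, S, d) neighbor blocks)


class _MeanAgg:
    name = "mean"

    def init(self, rng: np.random.Generator, d: int) -> dict:
        return {}

    def forward(self, F: np.ndarray, params: dict):
        return F.mean(axis=1), (F.shape,)

    def backward(self, dout: np.ndarray, cache, params: dict, need_dF: bool = True):
        (shape,) = cache
        M, S, d = shape
        if not need_dF:
            return None, {}
        dF = np.repeat(dout[:, None, :] / S, S, axis=1)
        return dF, {}


class _PoolingAgg:
    """Max-pooling aggregator: element-wise max of relu(W_p x + b_p)."""

    name = "pooling"

    def init(self, rng: np.random.Generator, d: int) -> dict:
        scale = np.sqrt(2.0 / d)
        return {"Wp": rng.normal(0.0, scale, size=(d, d)), "bp": np.zeros(d)}

    def forward(self, F: np.ndarray, params: dict):
        z = F @ params["Wp"].T + params["bp"]
        a = np.maximum(z, 0.0)
        idx = a.argmax(axis=1)  # (M, d)
        out = np.take_along_axis(a, idx[:, None, :], axis=1)[:, 0, :]
        return out, (F, z, idx)

    def backward(self, dout: np.ndarray, cache, params: dict, need_dF: bool = True):
        F, z, idx = cache
        da = np.zeros_like(z)
        np.put_along_axis(da, idx[:, None, :], dout[:, None, :], axis=1)
        dz = da * (z > 0)
        dF = dz @ params["Wp"] if need_dF else None
        dWp = np.einsum("msp,msd->pd", dz, F)
        dbp = dz.sum(axis=(0, 1))
        return dF, {"Wp": dWp, "bp": dbp}


class _LSTMAgg:
    """LSTM aggregator: neighbors fed as a sequence (in sampled order,
    which is random), final hidden state is the aggregate.  Not
    permutation invariant — by design of the original formulation."""

    name = "lstm"

    def init(self, rng: np.random.Generator, d: int) -> dict:
        scale = 1.0 / np.sqrt(d)
        return {
            "Wx": rng.normal(0.0, scale, size=(4 * d, d)),
            "Wh": rng.normal(0.0, scale, size=(4 * d, d)),
            "b": np.zeros(4 * d),
        }

    def forward(self, F: np.ndarray, params: dict):
        M, S, d = F.shape
        Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
        h = np.zeros((M, d))
        c = np.zeros((M, d))
        steps = []
        for t in range(S):
            x = F[:, t, :]
            gates = x @ Wx.T + h @ Wh.T + b
            i = _sigmoid(gates[:, :d])
            f = _sigmoid(gates[:, d : 2 * d])
            o = _sigmoid(gates[:, 2 * d : 3 * d])
            g = np.tanh(gates[:, 3 * d :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((x, h, c, i, f, o, g, tc))
            h, c = h_new, c_new
        return h, (F.shape, steps)

    def backward(self, dout: np.ndarray, cache, params: dict, need_dF: bool = True):
        (M, S, d), steps = cache
        Wx, Wh = params["Wx"], params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(params["Wh"])
        db = np.zeros_like(params["b"])
        dF = np.zeros((M, S, d))
        dh = dout.copy()
        dc = np.zeros((M, d))
        for t in range(S - 1, -1, -1):
            x, h_prev, c_prev, i, f, o, g, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g**2)],
                axis=1,
            )
            dWx += dgates.T @ x
            dWh += dgates.T @ h_prev
            db += dgates.sum(axis=0)
            dF[:, t, :] = dgates @ Wx
            dh = dgates @ Wh
            dc = dc * f
        return dF, {"Wx": dWx, "Wh": dWh, "b": db}


_AGGS = {"mean": _MeanAgg, "pooling": _PoolingAgg, "lstm": _LSTMAgg}


# --------------------------------------------------------------------------
# model


class SageModel:
    """GraphSAGE network + sigmoid head over an implicit pair graph."""

    def __init__(self, cfg: SageConfig, in_dim: int):
        self.cfg = cfg
        self.in_dim = in_dim
        self.dtype = np.dtype(cfg.dtype)
        self.aggs = [_AGGS[cfg.aggregator]() for _ in range(cfg.K)]
        rng = np.random.default_rng(cfg.seed)
        dims = [in_dim] + [cfg.hidden_dim] * cfg.K
        W = []
        aggp = []
        for k in range(cfg.K):
            fan_in = 2 * dims[k]
            W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(dims[k + 1], fan_in)).astype(self.dtype))
            aggp.append({n: a.astype(self.dtype) for n, a in self.aggs[k].init(rng, dims[k]).items()})
        head_w = rng.normal(0.0, 1.0 / np.sqrt(dims[-1]), size=dims[-1]).astype(self.dtype)
        self.params = SageParams(W=W, agg=aggp, head_w=head_w, head_b=0.0)

    # -- forward / backward over one sampled minibatch tree ---------------

    def _forward_tree(self, X: list[np.ndarray]):
        """X[t]: h^0 features of depth-t tree nodes, shape (n_t, in_dim)
        with n_t = B * prod(fanouts[:t]).  Returns h^K of the batch nodes
        plus caches for backprop."""
        cfg, p = self.cfg, self.params
        H = list(X)
        caches = []
        for k in range(1, cfg.K + 1):
            agg = self.aggs[k - 1]
            newH = []
            layer_cache = []
            for t in range(cfg.K - k + 1):
                fanout = cfg.fanouts[t]
                n_t = H[t].shape[0]
                d = H[t].shape[1]
                nbr = H[t + 1].reshape(n_t, fanout, d)
                m, agg_cache = agg.forward(nbr, p.agg[k - 1])
                cat = np.concatenate([H[t], m], axis=1)
                z = cat @ p.W[k - 1].T
                a = _act(z, cfg.nonlinearity)
                newH.append(a)
                layer_cache.append((cat, z, a, agg_cache, n_t, fanout, d))
            H = newH
            caches.append(layer_cache)
        return H[0], caches

    def _backward_tree(self, dhK: np.ndarray, caches) -> SageParams:
        cfg, p = self.cfg, self.params
        grads = SageParams(
            W=[np.zeros_like(w) for w in p.W],
            agg=[{k: np.zeros_like(v) for k, v in d.items()} for d in p.agg],
            head_w=np.zeros_like(p.head_w),
            head_b=0.0,
        )
        dH = [dhK]
        for k in range(cfg.K, 0, -1):
            agg = self.aggs[k - 1]
            layer_cache = caches[k - 1]
            n_levels = len(layer_cache)
            dH_prev = [None] * (n_levels + 1)
            for t in range(n_levels):
                cat, z, a, agg_cache, n_t, fanout, d = layer_cache[t]
                da = dH[t]
                if da is None:
                    continue
                dz = da * _act_grad(z, a, cfg.nonlinearity)
                grads.W[k - 1] += dz.T @ cat
                dcat = dz @ p.W[k - 1]
                dself, dm = dcat[:, :d], dcat[:, d:]
                # at the innermost layer (k == 1) the h^0 input gradients
                # are never consumed; skipping them avoids materializing
                # the largest neighbor-block tensors
                dnbr, dagg = agg.backward(dm, agg_cache, p.agg[k - 1], need_dF=k > 1)
                for name, g in dagg.items():
                    grads.agg[k - 1][name] += g
                if k > 1:
                    if dH_prev[t] is None:
                        dH_prev[t] = dself
                    else:
                        dH_prev[t] += dself
                    flat = dnbr.reshape(n_t * fanout, d)
                    if dH_prev[t + 1] is None:
                        dH_prev[t + 1] = flat
                    else:
                        dH_prev[t + 1] += flat
            dH = dH_prev
        return grads

    def forward_nodes(
        self,
        node_ids: np.ndarray,
        feature_fn,
        sampler,
        rng: np.random.Generator,
        return_tree: bool = False,
    ):
        """h^K (and score) for the given pair nodes with fresh sampling."""
        cfg = self.cfg
        ids = [np.asarray(node_ids, dtype=np.int64)]
        for t in range(cfg.K):
            ids.append(sampler.sample_batch(ids[t].reshape(-1), cfg.fanouts[t], rng).reshape(-1))
        X = [np.ascontiguousarray(feature_fn(layer), dtype=self.dtype) for layer in ids]
        hK, caches = self._forward_tree(X)
        score = _sigmoid(hK @ self.params.head_w + self.params.head_b)
        if return_tree:
            return hK, score, caches
        return hK, score

    # -- training ----------------------------------------------------------

    def fit(
        self,
        node_ids: np.ndarray,
        labels: np.ndarray,
        feature_fn,
        sampler,
    ) -> list[float]:
        """Minibatch Adam training of the full network + head with binary
        cross-entropy.  Returns the per-epoch mean training loss."""
        cfg = self.cfg
        node_ids = np.asarray(node_ids, dtype=np.int64)
        labels = np.asarray(labels, dtype=self.dtype)
        if node_ids.size == 0:
            raise ValueError("empty training sample")
        rng = np.random.default_rng(cfg.seed)
        opt = _Adam(self.params, lr=cfg.learning_rate)
        history: list[float] = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(node_ids.size)
            losses = []
            for lo in range(0, node_ids.size, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                batch, y = node_ids[idx], labels[idx]
                hK, score, caches = self.forward_nodes(
                    batch, feature_fn, sampler, rng, return_tree=True
                )
                loss = cross_entropy(y, score)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                losses.append(loss)
                # backprop through head then tree
                dz_head = (score - y) / y.size
                grads = self._backward_tree(
                    np.outer(dz_head, self.params.head_w), caches
                )
                grads.head_w = hK.T @ dz_head
                grads.head_b = float(dz_head.sum())
                opt.step(self.params, grads)
            history.append(float(np.mean(losses)))
            logger.debug("graphsage epoch %d loss %.5f", epoch, history[-1])
        return history

    def refine(
        self, node_ids: np.ndarray, feature_fn, sampler, seed: int | None = None
    ) -> RefinedFeatures:
        """Refined representations h^K (F'_DTP) for the requested nodes."""
        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
        node_ids = np.asarray(node_ids, dtype=np.int64)
        outs = []
        for lo in range(0, node_ids.size, self.cfg.batch_size):
            hK, _ = self.forward_nodes(node_ids[lo : lo + self.cfg.batch_size], feature_fn, sampler, rng)
            outs.append(hK)
        vecs = np.concatenate(outs, axis=0) if outs else np.empty((0, self.cfg.hidden_dim))
        return RefinedFeatures(node_ids=node_ids, vectors=vecs)

    def predict_scores(
        self, node_ids: np.ndarray, feature_fn, sampler, seed: int | None = None
    ) -> np.ndarray:
        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
        node_ids = np.asarray(node_ids, dtype=np.int64)
        outs = []
        for lo in range(0, node_ids.size, self.cfg.batch_size):
            _, s = self.forward_nodes(node_ids[lo : lo + self.cfg.batch_size], feature_fn, sampler, rng)
            outs.append(s)
        return np.concatenate(outs) if outs else np.empty(0)


class _Adam:
    def __init__(self, params: SageParams, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr in params.flat()}
        self.v = {name: np.zeros_like(arr) for name, arr in params.flat()}
        self.mb = 0.0
        self.vb = 0.0

    def step(self, params: SageParams, grads: SageParams) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for (name, arr), (_, g) in zip(params.flat(), grads.flat()):
            m = self.m[name] = b1 * self.m[name] + (1 - b1) * g
            v = self.v[name] = b2 * self.v[name] + (1 - b2) * g**2
            arr -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
        self.mb = b1 * self.mb + (1 - b1) * grads.head_b
        self.vb = b2 * self.vb + (1 - b2) * grads.head_b**2
        params.head_b -= self.lr * (self.mb / corr1) / (np.sqrt(self.vb / corr2) + self.eps)


def train(
    index: DTPIndex,
    feature_fn,
    node_ids: np.ndarray,
    labels: np.ndarray,
    cfg: SageConfig,
    sampler=None,
) -> tuple[SageModel, list[float]]:
    """Train GraphSAGE on labeled pair nodes of the implicit DTP graph.

    ``feature_fn(node_ids) -> (n, d)`` supplies h^0 features (normally
    ``DTPFeatures.matrix_for``); ``sampler`` defaults to uniform sampling
    over the full implicit graph.  Returns the model and the per-epoch
    loss history (empty when ``cfg.epochs == 0``, in which case the model
    keeps its random initialization).
    """
    sampler = sampler or FullDTPSampler(index)
    in_dim = feature_fn(np.asarray([0], dtype=np.int64)).shape[1]
    model = SageModel(cfg, in_dim)
    history = model.fit(node_ids, labels, feature_fn, sampler) if cfg.epochs > 0 else []
    return model, history
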