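"""3D convolutional affinity scorer with Boltzmann pose aggregation.

Architecture (default): five valid-padding conv layers of
32×3³, 64×3³, 64×3³, 64×3³, 64×2³ (filters × cubic kernel edge), each followed
by a rectified-linear unit, then a fully connected layer with 256 ReLU hidden
units and one linear output.  Strides (1, 2, 2, 2, 1) collapse a 30³ input to
1³ before the dense head.  A reduced configuration is provided for desk-scale
CPU training on 16³ grids.

Per-pose scores s_i are combined into a single affinity by weighted Boltzmann
averaging,

    S = Σ_i s_i·exp(β·s_i) / Σ_i exp(β·s_i),

which interpolates between the arithmetic mean (β=0) and the maximum (β→∞)
and is computed max-shifted for overflow safety.  Training minimizes mean
squared error between aggregated scores and affinity labels on the pKi/pIC50
scale (−log10 molar), with the aggregation inside the loss (it is
differentiable), using Adam on shuffled minibatches of 64 examples.

Everything is plain NumPy (float32) with explicit im2col/col2im convolutions,
so runs are reproducible on a single CPU without a deep-learning framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .featurize import GridSpec


class ArchitectureError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """(filters, kernel_edge, stride) per conv layer + dense head width."""

    conv: tuple = ((32, 3, 1), (64, 3, 2), (64, 3, 2), (64, 3, 2), (64, 2, 1))
    fc_hidden: int = 256

    @classmethod
    def reduced(cls) -> "NetworkConfig":
        """Small stack for 16³ grids / CPU-minute training budgets."""
        return cls(conv=((8, 3, 2), (16, 3, 2), (16, 3, 1)), fc_hidden=32)

    def spatial_sizes(self, edge: int) -> list[int]:
        sizes = [edge]
        d = edge
        for (_, k, s) in self.conv:
            if d < k:
                raise ArchitectureError("architecture_invalid")
            d = (d - k) // s + 1
            sizes.append(d)
        return sizes

    def n_parameters(self, in_channels: int, edge: int) -> int:
        n, c = 0, in_channels
        d = edge
        for (f, k, s) in self.conv:
            if d < k:
                raise ArchitectureError("architecture_invalid")
            n += k ** 3 * c * f + f
            c = f
            d = (d - k) // s + 1
        flat = c * d ** 3
        n += flat * self.fc_hidden + self.fc_hidden
        n += self.fc_hidden * 1 + 1
        return n


@dataclass
class AggregationConfig:
    beta: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError("beta must be finite and >= 0")


def boltzmann_aggregate(scores, beta: float = 1.0):
    """Softmax-weighted mean of pose scores; bounded by min/max of the input."""
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[None, :]
        squeeze = True
    else:
        squeeze = False
    if s.shape[-1] == 0:
        raise ValueError("empty score list")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite scores")
    z = beta * s
    z = z - z.max(axis=-1, keepdims=True)  # overflow-safe shift
    w = np.exp(z)
    w /= w.sum(axis=-1, keepdims=True)
    out = (w * s).sum(axis=-1)
    return float(out[0]) if squeeze else out


def _boltzmann_grad(s: np.ndarray, beta: float):
    """Aggregate and its gradient dS/ds_i = w_i·(1 + β(s_i − S))."""
    z = beta * s
    z = z - z.max(axis=-1, keepdims=True)
    w = np.exp(z)
    w /= w.sum(axis=-1, keepdims=True)
    agg = (w * s).sum(axis=-1)
    grad = w * (1.0 + beta * (s - agg[..., None]))
    return agg, grad


# ---------------------------------------------------------------------------
# layers

class _Conv3d:
    """Valid-padding strided 3D convolution + ReLU via cached im2col indices."""

    def __init__(self, in_ch, in_edge, filters, kernel, stride, rng):
        self.cin, self.d, self.f, self.k, self.s = in_ch, in_edge, filters, kernel, stride
        if in_edge < kernel:
            raise ArchitectureError("architecture_invalid")
        self.od = (in_edge - kernel) // stride + 1
        fan_in = kernel ** 3 * in_ch
        self.W = (rng.standard_normal((fan_in, filters)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self._build_indices()
        self._cache = None

    def _build_indices(self):
        D, k, s, C = self.d, self.k, self.s, self.cin
        xs = np.arange(self.od) * s
        a, b, g = np.meshgrid(xs, xs, xs, indexing="ij")
        dx, dy, dz = np.meshgrid(np.arange(k), np.arange(k), np.arange(k), indexing="ij")
        x = a.reshape(-1, 1) + dx.reshape(1, -1)
        y = b.reshape(-1, 1) + dy.reshape(1, -1)
        z = g.reshape(-1, 1) + dz.reshape(1, -1)
        spatial = (x * D + y) * D + z                       # (P, k^3)
        P = spatial.shape[0]
        idx = (np.arange(C)[None, :, None] * D ** 3 + spatial[:, None, :]).reshape(P, C * k ** 3)
        self.idx = idx
        self.P, self.CK = idx.shape
        # inverse map for col2im: input flat position -> slots in (P*CK) cols
        N = C * D ** 3
        flat = (np.arange(P)[:, None] * self.CK + np.arange(self.CK)[None, :]).ravel()
        targets = idx.ravel()
        order = np.argsort(targets, kind="stable")
        tsorted = targets[order]
        counts = np.bincount(targets, minlength=N)
        start = np.concatenate(([0], np.cumsum(counts)))[:-1]
        rank = np.arange(len(tsorted)) - start[tsorted]
        self.inv = np.full((N, counts.max()), P * self.CK, dtype=np.int64)
        self.inv[tsorted, rank] = flat[order]

    @property
    def out_dim(self):
        return self.f * self.od ** 3

    def forward(self, x, train=False):
        # x: (B, cin*d^3) float32
        cols = x[:, self.idx]                               # (B, P, CK)
        z = cols @ self.W + self.b
        mask = z > 0
        a = np.where(mask, z, 0.0)
        if train:
            self._cache = (x, mask)
        return a.transpose(0, 2, 1).reshape(x.shape[0], -1).astype(np.float32, copy=False)

    def backward(self, dout):
        x, mask = self._cache
        B = x.shape[0]
        da = dout.reshape(B, self.f, self.P).transpose(0, 2, 1)
        dz = np.where(mask, da, 0.0).astype(np.float32)
        cols = x[:, self.idx]
        self.dW = (cols.reshape(-1, self.CK).T @ dz.reshape(-1, self.f)).astype(np.float32)
        self.db = dz.sum(axis=(0, 1)).astype(np.float32)
        dcols = (dz @ self.W.T).reshape(B, -1)              # (B, P*CK)
        dcols = np.concatenate([dcols, np.zeros((B, 1), dtype=np.float32)], axis=1)
        dx = dcols[:, self.inv].sum(axis=2)                 # gather-based col2im
        self._cache = None
        return dx.astype(np.float32)

    def params(self):
        return [("W", self), ("b", self)]


class _Dense:
    def __init__(self, n_in, n_out, rng, relu=True):
        self.relu = relu
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._cache = None
        self.out_dim = n_out

    def forward(self, x, train=False):
        z = x @ self.W + self.b
        if self.relu:
            mask = z > 0
            out = np.where(mask, z, 0.0).astype(np.float32)
        else:
            mask = None
            out = z.astype(np.float32)
        if train:
            self._cache = (x, mask)
        return out

    def backward(self, dout):
        x, mask = self._cache
        dz = np.where(mask, dout, 0.0).astype(np.float32) if self.relu else dout.astype(np.float32)
        self.dW = (x.T @ dz).astype(np.float32)
        self.db = dz.sum(axis=0).astype(np.float32)
        self._cache = None
        return (dz @ self.W.T).astype(np.float32)


class ScoringModel:
    """Network weights + aggregation temperature + grid-spec fingerprint.

    Refuses grids whose GridSpec differs from the one it was built for.
    """

    def __init__(self, cfg: NetworkConfig, grid_spec: GridSpec, seed: int = 0,
                 agg: AggregationConfig | None = None):
        self.cfg = cfg
        self.grid_spec = grid_spec
        self.agg = agg or AggregationConfig()
        self.fingerprint = grid_spec.fingerprint()
        rng = np.random.default_rng(seed)
        self.layers = []
        c, d = grid_spec.n_channels, grid_spec.edge_voxels
        for (f, k, s) in cfg.conv:
            layer = _Conv3d(c, d, f, k, s, rng)
            self.layers.append(layer)
            c, d = f, layer.od
        if d < 1:
            raise ArchitectureError("architecture_invalid")
        self.layers.append(_Dense(c * d ** 3, cfg.fc_hidden, rng, relu=True))
        self.layers.append(_Dense(cfg.fc_hidden, 1, rng, relu=False))

    # -- inference -----------------------------------------------------------

    def _check(self, grids):
        g = np.asarray(grids)
        expected = (self.grid_spec.n_channels,) + (self.grid_spec.edge_voxels,) * 3
        if g.shape[-4:] != expected:
            raise ValueError(f"grid spec mismatch: got {g.shape[-4:]}, model expects {expected}")
        return g.reshape(-1, int(np.prod(expected))).astype(np.float32)

    def forward(self, grids, train=False, chunk=256) -> np.ndarray:
        """Per-grid scalar scores, shape (n_grids,)."""
        x = self._check(grids)
        if train:
            for layer in self.layers:
                x = layer.forward(x, train=True)
            return x[:, 0]
        outs = []
        for lo in range(0, len(x), chunk):
            xc = x[lo:lo + chunk]
            for layer in self.layers:
                xc = layer.forward(xc, train=False)
            outs.append(xc[:, 0])
        return np.concatenate(outs) if outs else np.zeros(0, dtype=np.float32)

    def backward(self, dscores):
        d = np.asarray(dscores, dtype=np.float32)[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_affinity(self, pose_grids):
        """Score a pose ensemble: per-pose forward passes then Boltzmann
        aggregation.  Returns (aggregate, per_pose_scores)."""
        scores = self.forward(pose_grids)
        return boltzmann_aggregate(scores, self.agg.beta), scores

    # -- persistence ---------------------------------------------------------

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend([layer.W, layer.b])
        return out

    def gradients(self):
        out = []
        for layer in self.layers:
            out.extend([layer.dW, layer.db])
        return out

    def save(self, path):
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        meta = {
            "conv": list(map(list, self.cfg.conv)),
            "fc_hidden": self.cfg.fc_hidden,
            "grid_spec": self.grid_spec.to_dict(),
            "beta": self.agg.beta,
        }
        np.savez(path, __meta__=np.bytes_(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "ScoringModel":
        with np.load(path, allow_pickle=False) as fh:
            meta = json.loads(bytes(fh["__meta__"]).decode())
            model = cls(
                NetworkConfig(conv=tuple(map(tuple, meta["conv"])), fc_hidden=meta["fc_hidden"]),
                GridSpec(**meta["grid_spec"]),
                agg=AggregationConfig(beta=meta["beta"]),
            )
            for i, p in enumerate(model.parameters()):
                p[...] = fh[f"p{i}"]
        return model


def init_network(cfg: NetworkConfig | None = None, grid_spec: GridSpec | None = None,
                 seed: int = 0, beta: float = 1.0) -> ScoringModel:
    return ScoringModel(cfg or NetworkConfig(), grid_spec or GridSpec(), seed=seed,
                        agg=AggregationConfig(beta=beta))


# ---------------------------------------------------------------------------
# training

def _rot90_orientations():
    """The 24 proper rotations of a cube as (axis permutation, flips)."""
    import itertools

    out = []
    for perm in itertools.permutations(range(3)):
        parity = sum(1 for i in range(3) for j in range(i + 1, 3) if perm[i] > perm[j]) % 2
        for flips in itertools.product((False, True), repeat=3):
            det = (-1) ** sum(flips) * (-1) ** parity
            if det == 1:
                out.append((perm, flips))
    return out


_ORIENTATIONS = _rot90_orientations()


def _apply_orientation(grids: np.ndarray, which: int) -> np.ndarray:
    """Rotate the three spatial axes (last three dims) by a cube rotation.
    Occupancy counts are exactly preserved."""
    perm, flips = _ORIENTATIONS[which]
    nd = grids.ndim
    axes = tuple(range(nd - 3)) + tuple(nd - 3 + p for p in perm)
    g = np.transpose(grids, axes)
    flip_axes = [nd - 3 + i for i, f in enumerate(flips) if f]
    if flip_axes:
        g = np.flip(g, axis=flip_axes)
    return np.ascontiguousarray(g)

@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    init_output_bias: bool = True   # start the linear head at the label mean
    weight_decay: float = 1e-4      # decoupled (AdamW-style), weights only
    augment_rot90: bool = True      # random proper cube rotation per example


def train(model: ScoringModel, pose_grids, labels, tcfg: TrainConfig | None = None):
    """Fit the scorer by MSE between Boltzmann-aggregated pose scores and
    affinity labels.  ``pose_grids``: (n, n_poses, C, e, e, e); ``labels``: (n,).

    Returns the per-epoch mean-loss trace.  Raises on divergence.
    """
    tcfg = tcfg or TrainConfig()
    if tcfg.batch_size < 1:
        raise ValueError("minibatch >= 1 required")
    G = np.asarray(pose_grids)
    y = np.asarray(labels, dtype=np.float32)
    if G.ndim != 6 or len(G) != len(y) or len(y) == 0:
        raise ValueError("need (n, poses, C, e, e, e) grids and matching labels")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    n, P = G.shape[0], G.shape[1]
    rng = np.random.default_rng(tcfg.seed)
    if tcfg.init_output_bias:
        model.layers[-1].b[:] = y.mean()
    params = model.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2 = tcfg.adam_betas
    step = 0
    trace = []
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, tcfg.batch_size):
            batch = order[lo:lo + tcfg.batch_size]
            B = len(batch)
            gb = G[batch]
            if tcfg.augment_rot90:
                gb = np.stack([
                    _apply_orientation(gb[i], int(rng.integers(24))) for i in range(B)
                ])
            scores = model.forward(gb.reshape((B * P,) + G.shape[2:]), train=True)
            s = scores.reshape(B, P).astype(float)
            agg, dsd = _boltzmann_grad(s, model.agg.beta)
            resid = agg - y[batch]
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise RuntimeError("diverged")
            losses.append(loss)
            dscores = ((2.0 / B) * resid[:, None] * dsd).reshape(B * P)
            model.backward(dscores)
            step += 1
            # overflow here is how divergence manifests; it is caught via the
            # loss check above, so silence the per-element warnings
            with np.errstate(over="ignore", invalid="ignore"):
                for p, g, mi, vi in zip(params, model.gradients(), m, v):
                    mi *= b1
                    mi += (1 - b1) * g
                    vi *= b2
                    vi += (1 - b2) * g * g
                    mhat = mi / (1 - b1 ** step)
                    vhat = vi / (1 - b2 ** step)
                    p -= tcfg.learning_rate * mhat / (np.sqrt(vhat) + tcfg.adam_eps)
                    if tcfg.weight_decay and p.ndim > 1:  # weights, not biases
                        p -= tcfg.learning_rate * tcfg.weight_decay * p
        trace.append(float(np.mean(losses)))
    return trace
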