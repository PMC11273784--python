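"""PointNet-style extractor of fixed-length hemodynamic-cloud features.

The network consumes 1024 randomly selected points of a hemodynamic cloud
(7 attributes per point), aligns the spatial coordinates with a learned 3x3
transform (input T-Net), lifts each point through a shared two-layer MLP
7 -> C1 -> C2, aligns the per-point features with a learned C2 x C2 transform
(feature T-Net), lifts again through C2 -> C3 -> C4, and max-pools over points
into a single 1 x C4 global feature vector — the *hemodynamic cloud features*.

Channel presets and the feature dimensions they yield:

    (64, 64, 128, 1024) -> 1024    (8, 16, 32, 64) -> 64
    (8, 8, 16, 32)      -> 32      (8, 8, 16, 16)  -> 16

Because max-pooling is a symmetric function and every other stage acts
point-wise, the global feature is invariant under any permutation of the
input points (bit-identical with fixed weights).

Training is supervised: a small two-layer head maps the global feature to
rupture logits, minimised with cross-entropy plus an orthogonality penalty
||A A^T - I||_F^2 on the feature transform; the head is discarded after
training.  Batch norm runs in eval mode (frozen running statistics) during
extraction so features are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields

import numpy as np

from .autodiff import Tensor, batch_norm, concat, softmax_cross_entropy
from .io import get_logger
from .types import HemodynamicCloud, ValidationError

logger = get_logger()

#: the four published channel settings, keyed by the feature dimension C4
CHANNEL_PRESETS = {
    1024: (64, 64, 128, 1024),
    64: (8, 16, 32, 64),
    32: (8, 8, 16, 32),
    16: (8, 8, 16, 16),
}


@dataclass
class ExtractorConfig:
    """Channel widths and training hyper-parameters of the extractor."""

    channels: tuple[int, int, int, int] = (8, 8, 16, 16)
    n_input_points: int = 1024
    n_attributes: int = 7
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-2
    ortho_weight: float = 1e-3
    input_transform_mode: str = "xyz"  # "xyz" (3x3 on coordinates) or "full" (7x7)
    seed: int = 0

    def __post_init__(self) -> None:
        c1, c2, c3, c4 = self.channels
        if not (0 < c1 <= c2 and 0 < c3 <= c4):
            raise ValidationError(
                "channel widths must satisfy C1 <= C2 and C3 <= C4 (gradually increasing)"
            )
        if self.n_attributes != 7:
            raise ValidationError("clouds carry exactly 7 attributes per point")
        if self.input_transform_mode not in ("xyz", "full"):
            raise ValidationError("input_transform_mode must be 'xyz' or 'full'")


def feature_dimension(config: ExtractorConfig) -> int:
    """Length of the global feature vector (C4)."""
    return config.channels[3]


@dataclass
class CloudFeatureVector:
    case_id: str
    values: np.ndarray  # (C4,)


# ---------------------------------------------------------------------------
# layers


#: network dtype; single precision keeps the point-wise passes memory-light
DTYPE = np.float32


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Linear:
    """Affine layer shared across points: x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False, bias_init: np.ndarray | None = None):
        w = np.zeros((n_in, n_out), dtype=DTYPE) if zero_init else _he(rng, n_in, (n_in, n_out))
        b = np.zeros(n_out, dtype=DTYPE) if bias_init is None else np.asarray(bias_init, dtype=DTYPE)
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class BatchNorm:
    """Per-channel batch norm over all leading axes; eval mode uses running stats."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            out, mean, var = batch_norm(x, self.gamma, self.beta, self.eps)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
            return out
        scale = self.gamma * Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        return (x - Tensor(self.running_mean)) * scale + self.beta

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return [self.running_mean, self.running_var]


class SharedMLP:
    """Stack of (Linear, BatchNorm, ReLU) applied point-wise with shared weights."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.linears = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.bns = [BatchNorm(b) for b in widths[1:]]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        for lin, bn in zip(self.linears, self.bns):
            x = bn(lin(x), training).relu()
        return x

    def params(self):
        return [p for lin in self.linears for p in lin.params()] + [
            p for bn in self.bns for p in bn.params()
        ]

    def state(self):
        return [s for bn in self.bns for s in bn.state()]


class TNet:
    """Alignment sub-network predicting a d x d transform from the point set.

    Shared MLP d -> h1 -> h2, max-pool over points, FC h2 -> h3 -> d*d.  The
    final layer starts at zero weights with an identity bias so the transform
    is the identity at initialisation.
    """

    def __init__(self, d: int, hidden: tuple[int, int, int], rng: np.random.Generator):
        h1, h2, h3 = hidden
        self.d = d
        self.mlp = SharedMLP([d, h1, h2], rng)
        self.fc1 = Linear(h2, h3, rng)
        self.bn1 = BatchNorm(h3)
        self.fc2 = Linear(h3, d * d, rng, zero_init=True, bias_init=np.eye(d).ravel())

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        """x: (B, n, d) -> transform matrices (B, d, d)."""
        h = self.mlp(x, training)
        pooled = h.max(axis=1)  # (B, h2)
        h = self.bn1(self.fc1(pooled), training).relu()
        return self.fc2(h).reshape(-1, self.d, self.d)

    def params(self):
        return self.mlp.params() + self.fc1.params() + self.bn1.params() + self.fc2.params()

    def state(self):
        return self.mlp.state() + self.bn1.state()


def orthogonality_penalty(matrix: Tensor) -> Tensor:
    """||A A^T - I||_F^2, averaged over the batch for (B, k, k) input."""
    if len(matrix.shape) == 2:
        matrix = matrix.reshape(1, *matrix.shape)
    k = matrix.shape[-1]
    gram = matrix @ matrix.swapaxes(-1, -2)
    dev = gram - Tensor(np.eye(k))
    return (dev * dev).sum() * (1.0 / matrix.shape[0])


# ---------------------------------------------------------------------------
# the extractor


class PointNetExtractor:
    """The full extractor; holds all weights and the training history."""

    def __init__(self, config: ExtractorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3, c4 = config.channels
        d_in = 3 if config.input_transform_mode == "xyz" else 7
        self.input_tnet = TNet(d_in, (c1, c2, max(c2 // 2, 8)), rng)
        self.mlp1 = SharedMLP([7, c1, c2], rng)
        self.feature_tnet = TNet(c2, (c2, c4, max(c4 // 2, 8)), rng)
        self.mlp2 = SharedMLP([c2, c3, c4], rng)
        head_hidden = max(8, c4 // 2)
        self.head1 = Linear(c4, head_hidden, rng)
        self.head2 = Linear(head_hidden, 2, rng)
        self.history: list[float] = []

    # -- forward ----------------------------------------------------------
    def input_transform(self, x: Tensor, training: bool) -> tuple[Tensor, Tensor]:
        """Align the point cloud; physical attributes pass through untouched in 'xyz' mode."""
        if self.config.input_transform_mode == "full":
            t = self.input_tnet(x, training)
            return x @ t, t
        # slice columns via constant selector matrices so gradients flow if needed
        sel = np.zeros((7, 3), dtype=DTYPE); sel[:3, :3] = np.eye(3)
        xyz = x @ Tensor(sel)           # (B, n, 3)
        attr_sel = np.zeros((7, 4), dtype=DTYPE); attr_sel[3:, :] = np.eye(4)
        attrs = x @ Tensor(attr_sel)    # (B, n, 4)
        t = self.input_tnet(xyz, training)  # (B, 3, 3)
        return concat([xyz @ t, attrs], axis=-1), t

    def forward(self, x: np.ndarray | Tensor, training: bool = False) -> dict:
        """x: (B, n, 7) standardized points -> global feature, logits, transforms."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        aligned, t_in = self.input_transform(x, training)
        local = self.mlp1(aligned, training)                 # (B, n, C2)
        t_feat = self.feature_tnet(local, training)          # (B, C2, C2)
        aligned_feat = local @ t_feat
        lifted = self.mlp2(aligned_feat, training)           # (B, n, C4)
        global_feat = lifted.max(axis=1)                     # (B, C4)
        logits = self.head2(self.head1(global_feat).relu())
        return {
            "global": global_feat,
            "logits": logits,
            "input_transform": t_in,
            "feature_transform": t_feat,
            "per_point": lifted,
        }

    # -- bookkeeping ------------------------------------------------------
    def params(self) -> list[Tensor]:
        return (
            self.input_tnet.params() + self.mlp1.params() + self.feature_tnet.params()
            + self.mlp2.params() + self.head1.params() + self.head2.params()
        )

    def state(self) -> list[np.ndarray]:
        return self.input_tnet.state() + self.mlp1.state() + self.feature_tnet.state() + self.mlp2.state()

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params())}
        arrays.update({f"state_{i}": s for i, s in enumerate(self.state())})
        meta = {f.name: getattr(self.config, f.name) for f in fields(self.config)}
        meta["channels"] = list(meta["channels"])
        np.savez(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "PointNetExtractor":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        meta["channels"] = tuple(meta["channels"])
        net = cls(ExtractorConfig(**meta))
        for i, p in enumerate(net.params()):
            arr = data[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValidationError("weight file does not match config shapes")
            p.data = arr
        state = net.state()
        for i in range(len(state)):
            state[i][...] = data[f"state_{i}"]
        return net


# ---------------------------------------------------------------------------
# sampling, preprocessing, extraction


def sample_input_points(
    cloud: HemodynamicCloud, n: int = 1024, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Randomly select ``n`` points (without replacement when the cloud is big enough)."""
    if cloud.n_points < 1:
        raise ValidationError("empty cloud")
    rng = rng or np.random.default_rng()
    mat = cloud.matrix
    replace = cloud.n_points < n
    idx = rng.choice(cloud.n_points, size=n, replace=replace)
    return mat[idx]


def standardize_points(points: np.ndarray) -> np.ndarray:
    """Centre coordinates at the centroid; z-score the 4 physical attributes.

    Units are heterogeneous (mm, Pa, m/s), so per-cloud standardisation keeps
    any one attribute from dominating the shared MLP.
    """
    out = np.array(points, dtype=np.float64)
    out[:, :3] -= out[:, :3].mean(axis=0)
    for j in range(3, 7):
        sd = out[:, j].std()
        mu = out[:, j].mean()
        out[:, j] = (out[:, j] - mu) / sd if sd > 0 else 0.0
    return out.astype(DTYPE)


def extract_features(
    cloud: HemodynamicCloud,
    network: PointNetExtractor,
    rng: np.random.Generator | None = None,
    points: np.ndarray | None = None,
) -> CloudFeatureVector:
    """Global 1 x C4 feature of one cloud (deterministic given weights and sample)."""
    if points is None:
        points = sample_input_points(cloud, network.config.n_input_points, rng)
    x = standardize_points(points)[None]
    out = network.forward(x, training=False)
    values = out["global"].data[0]
    if not np.isfinite(values).all():
        raise ValidationError("non-finite feature values")
    return CloudFeatureVector(case_id=cloud.case_id, values=values)


# ---------------------------------------------------------------------------
# training


class Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train_extractor(
    clouds: list[HemodynamicCloud],
    labels: np.ndarray,
    config: ExtractorConfig,
) -> PointNetExtractor:
    """Supervised training of the extractor on rupture labels.

    Point samples are drawn once per cloud (seeded) and held fixed across
    epochs; the classification head is kept on the returned network but is not
    used by :func:`extract_features`.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if (counts < 2).any():
        raise ValidationError("training requires at least 2 cases per class")
    net = PointNetExtractor(config)
    rng = np.random.default_rng(config.seed)
    X = np.stack(
        [
            standardize_points(sample_input_points(c, config.n_input_points, rng))
            for c in clouds
        ]
    )
    if config.epochs == 0:
        return net
    opt = Adam(net.params(), config.learning_rate)
    n = len(clouds)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out = net.forward(X[idx], training=True)
            loss = softmax_cross_entropy(out["logits"], labels[idx])
            loss = loss + config.ortho_weight * orthogonality_penalty(
                out["feature_transform"]
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        net.history.append(epoch_loss)
        logger.debug("extractor epoch %d loss %.4f", epoch, epoch_loss)
    return net
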