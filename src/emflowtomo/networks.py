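"""Network architectures and training for the CAE-CNN reconstruction chain.

Three networks are defined:

* a convolutional auto-encoder (CAE) that compresses the m x n weight
  matrix into an m x m x p feature tensor W' (encoder) and reconstructs
  the input from it (decoder, kept for reconstruction-error diagnostics);
* a reconstruction CNN that maps velocity-domain features v' (m x p) to
  the n-vector of cell velocities;
* a fully-connected baseline (BP) mapping the m raw voltages directly to
  the n velocities.

The reference architectures reproduce the published layer tables exactly
(encoder 11x2601 -> 11x11x60, decoder back to 11x2601x1, CNN flatten
length 1584); all convolutions and max-poolings are stride 1 with valid
padding except the first two decoder deconvolutions, which are stride-2
same-padded (these strides are forced by the layer output sizes).
Scaled-down variants with the same block pattern are generated for any
reconstruction-unit count n, for use on small benchmarks.

All three are trained with mean-absolute-error loss and the
adaptive-moment (Adam) optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .forward import WeightMatrix

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainConfig",
    "TrainedModel",
    "TrainingDiverged",
    "propagate_shapes",
    "mae",
    "cae_specs",
    "scaled_cae_plan",
    "cnn_spec",
    "bp_spec",
    "build_network",
    "standardize",
    "normalize_features",
    "train_cae",
    "encode",
    "train_cnn",
    "predict",
    "train_bp",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer row: kind, 1 x kernel extent, filters/units, stride,
    padding, activation; ``out_width`` for bilinear, ``rate`` for dropout."""

    kind: str  # conv | deconv | maxpool | bilinear | flatten | dense | dropout | batchnorm
    kernel: int = 1
    filters: int = 1
    stride: int = 1
    padding: str = "valid"
    activation: str = "none"  # tanh | sigmoid | relu | none
    out_width: int = 0
    rate: float = 0.0

    def __post_init__(self):
        if self.kernel < 1:
            raise ValueError("kernel extent must be >= 1")
        if self.kind in ("conv", "deconv", "dense") and self.filters < 1:
            raise ValueError("filters must be >= 1")


@dataclass
class NetworkSpec:
    name: str
    input_shape: tuple[int, int, int]  # (H, W, C)
    layers: list[LayerSpec] = field(default_factory=list)


@dataclass
class TrainConfig:
    """MAE + Adam training protocol.

    Defaults follow the reference protocol for the reconstruction CNN:
    learning rate 1e-5, batch size 817, 1500 iterations; the CAE is
    trained full-batch (the single weight matrix) at 1e-4 for 3000
    iterations.  Scaled benchmarks override these.
    """

    learning_rate: float = 1e-5
    iterations: int = 1500
    batch_size: int = 817
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.iterations < 1:
            raise ValueError("iteration count must be >= 1")


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


@dataclass
class TrainedModel:
    """Trained network(s) with loss history and the normalization
    statistics needed to reproduce predictions."""

    name: str  # cae | cnn | bp
    networks: dict          # e.g. {"encoder": Sequential, "decoder": Sequential}
    specs: dict             # name -> NetworkSpec
    train_config: TrainConfig
    loss_history: np.ndarray
    input_stats: dict
    label_stats: dict | None = None


# ---------------------------------------------------------------------------
# shape propagation


def propagate_shapes(spec: NetworkSpec, input_shape: tuple[int, int, int] | None = None) -> list[tuple[int, int, int]]:
    """Output shape (H, W, C) after each layer.

    Raises ``ValueError`` naming the first layer whose output would have a
    non-positive extent.
    """
    h, w, c = input_shape if input_shape is not None else spec.input_shape
    shapes = []
    for i, ls in enumerate(spec.layers):
        if ls.kind == "conv":
            if ls.padding == "same":
                w = -(-w // ls.stride)
            else:
                w = (w - ls.kernel) // ls.stride + 1
            c = ls.filters
        elif ls.kind == "deconv":
            w = w * ls.stride if ls.padding == "same" else (w - 1) * ls.stride + ls.kernel
            c = ls.filters
        elif ls.kind == "maxpool":
            w = (w - ls.kernel) // ls.stride + 1
        elif ls.kind == "bilinear":
            w = ls.out_width
        elif ls.kind == "flatten":
            h, w, c = 1, 1, h * w * c
        elif ls.kind == "dense":
            h, w, c = 1, 1, ls.filters
        elif ls.kind in ("dropout", "batchnorm"):
            pass
        else:
            raise ValueError(f"unknown layer kind {ls.kind!r}")
        if w <= 0 or h <= 0 or c <= 0:
            raise ValueError(f"layer {i + 1} ({ls.kind}) produces non-positive extent {(h, w, c)}")
        shapes.append((h, w, c))
    return shapes


def mae(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute elementwise difference."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# architecture definitions

_PAPER_CAE_WIDTHS = [2000, 1000, 800, 400, 200, 100, 50, 25, 11]
_PAPER_CAE_FILTERS = [2, 4, 8, 16, 32, 60]


def scaled_cae_plan(n: int, m: int = 11, p: int = 12) -> tuple[list[int], list[int]]:
    """Width/filter plan honoring the reference CAE block pattern for a
    reduced input width n.

    Tail widths are pinned so the stride-2 same-padded deconvolutions of
    the mirrored decoder land exactly: c5 = 2*c6 and p2 = 2*c5.
    """
    c6 = m + 2
    c5 = 2 * c6
    p2 = 2 * c5
    c1 = round(0.77 * n)
    c2 = round(c1 / 2)
    p1 = round(0.8 * c2)
    c3 = round(0.735 * p1)
    c4 = round(0.6 * c3)
    widths = [c1, c2, p1, c3, c4, p2, c5, c6, m]
    seq = [n] + widths
    if any(seq[i] <= seq[i + 1] for i in range(len(seq) - 1)):
        # small inputs cannot keep the reference compression ratios in the
        # head; fall back to evenly spaced head widths down to p2
        head = np.round(np.linspace(n, p2, 6)).astype(int)[1:5]
        c1, c2, p1, c3 = (int(v) for v in head)
        c4 = int(round((c3 + p2) / 2))
        widths = [c1, c2, p1, c3, c4, p2, c5, c6, m]
        seq = [n] + widths
        if any(seq[i] <= seq[i + 1] for i in range(len(seq) - 1)):
            raise ValueError(f"input width n={n} too small for the scaled CAE plan (widths {widths})")
    return widths, [2, 4, 4, 8, 8, p]


def cae_specs(
    m: int = 11,
    n: int = 2601,
    widths: list[int] | None = None,
    filters: list[int] | None = None,
    p: int = 12,
) -> tuple[NetworkSpec, NetworkSpec]:
    """Encoder and decoder specs.

    With default arguments at (m=11, n=2601) this is the reference
    architecture; other n values get a scaled plan with the same
    conv-conv-pool / bilinear-deconv-deconv block pattern.
    """
    if widths is None:
        if (m, n) == (11, 2601):
            widths, filters = _PAPER_CAE_WIDTHS, _PAPER_CAE_FILTERS
        else:
            widths, filters = scaled_cae_plan(n, m, p)
    if filters is None or len(widths) != 9 or len(filters) != 6:
        raise ValueError("CAE plan needs 9 widths and 6 filter counts")
    c1, c2, p1, c3, c4, p2, c5, c6, p3 = widths
    f1, f2, f3, f4, f5, f6 = filters
    if c5 != 2 * c6 or p2 != 2 * c5:
        raise ValueError("decoder stride-2 deconvolutions require c5 = 2*c6 and p2 = 2*c5")

    enc = NetworkSpec(
        name="cae_encoder",
        input_shape=(m, n, 1),
        layers=[
            LayerSpec("conv", n - c1 + 1, f1, activation="tanh"),
            LayerSpec("conv", c1 - c2 + 1, f2, activation="tanh"),
            LayerSpec("maxpool", c2 - p1 + 1),
            LayerSpec("conv", p1 - c3 + 1, f3, activation="tanh"),
            LayerSpec("conv", c3 - c4 + 1, f4, activation="tanh"),
            LayerSpec("maxpool", c4 - p2 + 1),
            LayerSpec("conv", p2 - c5 + 1, f5, activation="tanh"),
            LayerSpec("conv", c5 - c6 + 1, f6, activation="tanh"),
            LayerSpec("maxpool", c6 - p3 + 1),
        ],
    )
    dec = NetworkSpec(
        name="cae_decoder",
        input_shape=(m, p3, f6),
        layers=[
            LayerSpec("bilinear", out_width=c6),
            LayerSpec("deconv", c5 - c6 + 1, f6, stride=2, padding="same", activation="tanh"),
            LayerSpec("deconv", p2 - c5 + 1, f5, stride=2, padding="same", activation="tanh"),
            LayerSpec("bilinear", out_width=c4),
            LayerSpec("deconv", c3 - c4 + 1, f4, activation="tanh"),
            LayerSpec("deconv", p1 - c3 + 1, f3, activation="tanh"),
            LayerSpec("bilinear", out_width=c2),
            LayerSpec("deconv", c1 - c2 + 1, f2, activation="tanh"),
            LayerSpec("deconv", n - c1 + 1, f1, activation="tanh"),
            LayerSpec("conv", 1, 1, padding="same", activation="tanh"),
        ],
    )
    return enc, dec


def cnn_spec(m: int = 11, p: int = 60, n_out: int = 2601) -> NetworkSpec:
    """Reconstruction CNN: three conv+BN+activation+pool blocks, then two
    dense layers with mid-network dropout 0.5.

    The reference configuration (p=60) uses kernels 1x31 / 1x1 / 1x1,
    filters 6/12/24 and pools 1x16 / 1x9 / 1x2, flattening to 1584.
    Other p values shrink the first kernel and the pools proportionally.
    """
    if p == 60:
        k1, pools, filters = 31, (16, 9, 2), (6, 12, 24)
    else:
        k1 = p // 2 + 1
        pools, filters = (2, 2, 2), (4, 8, 12)
    layers = []
    for i, (f, pk, act) in enumerate(zip(filters, pools, ("sigmoid", "sigmoid", "relu"))):
        layers.append(LayerSpec("conv", k1 if i == 0 else 1, f))
        layers.append(LayerSpec("batchnorm", activation=act))
        layers.append(LayerSpec("maxpool", pk))
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", filters=n_out, activation="relu"),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("dense", filters=n_out),
    ]
    return NetworkSpec(name="cnn", input_shape=(m, p, 1), layers=layers)


def bp_spec(m: int = 11, n_out: int = 2601, hidden: tuple[int, ...] = (512,)) -> NetworkSpec:
    """Fully-connected baseline: m -> hidden -> n_out (relu hidden, linear out)."""
    layers = [LayerSpec("flatten")]
    for h in hidden:
        layers.append(LayerSpec("dense", filters=h, activation="relu"))
    layers.append(LayerSpec("dense", filters=n_out))
    return NetworkSpec(name="bp", input_shape=(1, m, 1), layers=layers)


_ACTS = {"tanh": nn.Tanh, "sigmoid": nn.Sigmoid, "relu": nn.Relu}


def build_network(spec: NetworkSpec, rng: np.random.Generator) -> nn.Sequential:
    """Instantiate runtime layers with Glorot-uniform initialization."""
    shapes = propagate_shapes(spec)
    layers: list[nn.Layer] = []
    h, w, c = spec.input_shape
    for ls, out_shape in zip(spec.layers, shapes):
        if ls.kind == "conv":
            layers.append(nn.Conv(ls.kernel, c, ls.filters, ls.stride, ls.padding, rng))
        elif ls.kind == "deconv":
            layers.append(nn.Deconv(ls.kernel, c, ls.filters, ls.stride, ls.padding, rng))
        elif ls.kind == "maxpool":
            layers.append(nn.MaxPool(ls.kernel, ls.stride))
        elif ls.kind == "bilinear":
            layers.append(nn.Bilinear(ls.out_width))
        elif ls.kind == "flatten":
            layers.append(nn.Flatten())
        elif ls.kind == "dense":
            layers.append(nn.Dense(h * w * c, ls.filters, rng, bias_init=0.1))
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(ls.rate))
        elif ls.kind == "batchnorm":
            layers.append(nn.BatchNorm(c))
        if ls.activation != "none":
            layers.append(_ACTS[ls.activation]())
        h, w, c = out_shape
    return nn.Sequential(layers)


# ---------------------------------------------------------------------------
# normalization


def standardize(W: np.ndarray, stats: dict | None = None) -> tuple[np.ndarray, dict]:
    """Global z-score with a guarded scale floor; reapplies ``stats`` if given."""
    W = np.asarray(W, dtype=float)
    if stats is None:
        stats = {"mean": float(W.mean()), "std": float(max(W.std(), 1e-12))}
    return (W - stats["mean"]) / stats["std"], stats


def normalize_features(X: np.ndarray, stats: dict | None = None) -> tuple[np.ndarray, dict]:
    """Per-feature z-score over the sample axis (axis 0)."""
    X = np.asarray(X, dtype=float)
    if stats is None:
        mean = X.mean(axis=0)
        std = np.maximum(X.std(axis=0), 1e-12)
        stats = {"mean": mean, "std": std}
    return (X - stats["mean"]) / stats["std"], stats


# ---------------------------------------------------------------------------
# training


def _check_finite(loss: float, history: list, what: str) -> None:
    if not np.isfinite(loss):
        raise TrainingDiverged(f"{what} training diverged (non-finite loss)", history)


def train_cae(
    W: WeightMatrix | np.ndarray,
    cfg: TrainConfig | None = None,
    widths: list[int] | None = None,
    filters: list[int] | None = None,
    p: int = 12,
) -> TrainedModel:
    """Train the auto-encoder on the (standardized) weight matrix.

    The CAE sees a single training example -- the weight matrix itself --
    so each iteration is one full-batch Adam step on MAE(W, W_hat).
    """
    cfg = cfg if cfg is not None else TrainConfig(learning_rate=1e-4, iterations=3000, batch_size=1)
    Wm = W.W if isinstance(W, WeightMatrix) else np.asarray(W)
    m, n = Wm.shape
    Wstd, stats = standardize(Wm)
    enc_spec, dec_spec = cae_specs(m, n, widths, filters, p)

    ss = np.random.SeedSequence([cfg.seed, 0xCAE])
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    enc = build_network(enc_spec, init_rng)
    dec = build_network(dec_spec, init_rng)
    full = nn.Sequential(enc.layers + dec.layers)
    opt = nn.Adam(full, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)

    x = Wstd[None, :, :, None]
    history = []
    for _ in range(cfg.iterations):
        y = full.forward(x, train=True)
        loss, grad = nn.mae_loss(y, x)
        _check_finite(loss, history, "CAE")
        history.append(loss)
        full.backward(grad)
        opt.step()
    return TrainedModel(
        name="cae",
        networks={"encoder": enc, "decoder": dec},
        specs={"encoder": enc_spec, "decoder": dec_spec},
        train_config=cfg,
        loss_history=np.asarray(history),
        input_stats=stats,
    )


def encode(model: TrainedModel, W: WeightMatrix | np.ndarray) -> np.ndarray:
    """Weight feature tensor W' of shape (m, m, p) from the trained encoder."""
    if model.name != "cae" or "encoder" not in model.networks:
        raise ValueError("encode requires a trained CAE model")
    Wm = W.W if isinstance(W, WeightMatrix) else np.asarray(W)
    Wstd, _ = standardize(Wm, model.input_stats)
    out = model.networks["encoder"].forward(Wstd[None, :, :, None], train=False)
    return out[0]


def _train_supervised(
    net: nn.Sequential,
    X: np.ndarray,
    Y: np.ndarray,
    cfg: TrainConfig,
    what: str,
) -> np.ndarray:
    N = X.shape[0]
    bs = min(cfg.batch_size, N)
    ss = np.random.SeedSequence([cfg.seed, 0x7247191])
    shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    history = []
    order = shuffle_rng.permutation(N)
    pos = 0
    for _ in range(cfg.iterations):
        if pos + bs > N:
            order = shuffle_rng.permutation(N)
            pos = 0
        idx = order[pos : pos + bs]
        pos += bs
        pred = net.forward(X[idx], train=True, rng=drop_rng)
        loss, grad = nn.mae_loss(pred, Y[idx])
        _check_finite(loss, history, what)
        history.append(loss)
        net.backward(grad)
        net._adam.step()
    return np.asarray(history)


def train_cnn(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    spec: NetworkSpec | None = None,
    scale_labels: bool = False,
) -> TrainedModel:
    """Train the reconstruction CNN on velocity features v' (N, m, p)
    against velocity labels (N, n) in m/s."""
    cfg = cfg if cfg is not None else TrainConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("feature and label sample counts differ")
    N, m, p = features.shape
    n_out = labels.shape[1]
    spec = spec if spec is not None else cnn_spec(m, p, n_out)

    Xn, stats = normalize_features(features)
    label_stats = None
    Y = labels
    if scale_labels:
        Y, label_stats = normalize_features(labels)

    init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC44]))
    net = build_network(spec, init_rng)
    _init_adam(net, cfg)
    history = _train_supervised(net, Xn[..., None], Y, cfg, "CNN")
    return TrainedModel(
        name="cnn",
        networks={"net": net},
        specs={"net": spec},
        train_config=cfg,
        loss_history=history,
        input_stats=stats,
        label_stats=label_stats,
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Velocity estimate(s) in m/s for one (m, p) feature matrix or a
    batch (N, m, p); for BP models, one (m,) voltage vector or (N, m)."""
    if "net" not in model.networks:
        raise ValueError("predict requires a trained CNN or BP model")
    X = np.asarray(features, dtype=float)
    if model.name == "cnn":
        single = X.ndim == 2
        if single:
            X = X[None]
        Xn, _ = normalize_features(X, model.input_stats)
        out = model.networks["net"].forward(Xn[..., None], train=False)
    else:
        single = X.ndim == 1
        if single:
            X = X[None]
        Xn, _ = normalize_features(X, model.input_stats)
        out = model.networks["net"].forward(Xn[:, None, :, None], train=False)
    if model.label_stats is not None:
        out = out * model.label_stats["std"] + model.label_stats["mean"]
    return out[0] if single else out


def train_bp(
    U: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    hidden: tuple[int, ...] = (512,),
    scale_labels: bool = False,
) -> TrainedModel:
    """Train the fully-connected baseline on raw voltages (N, m)."""
    cfg = cfg if cfg is not None else TrainConfig()
    U = np.asarray(U, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if U.shape[0] != labels.shape[0]:
        raise ValueError("voltage and label sample counts differ")
    spec = bp_spec(U.shape[1], labels.shape[1], hidden)
    Xn, stats = normalize_features(U)
    label_stats = None
    Y = labels
    if scale_labels:
        Y, label_stats = normalize_features(labels)
    init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB9]))
    net = build_network(spec, init_rng)
    _init_adam(net, cfg)
    history = _train_supervised(net, Xn[:, None, :, None], Y, cfg, "BP")
    return TrainedModel(
        name="bp",
        networks={"net": net},
        specs={"net": spec},
        train_config=cfg,
        loss_history=history,
        input_stats=stats,
        label_stats=label_stats,
    )


# Adam state is attached to the Sequential so the batch loop stays simple.


def _init_adam(net: nn.Sequential, cfg: TrainConfig) -> None:
    net._adam = nn.Adam(net, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint: parameter arrays + JSON metadata."""
    arrays = {}
    for net_name, net in model.networks.items():
        for key, arr in net.state_arrays().items():
            arrays[f"{net_name}/{key}"] = arr
    meta = {
        "format": "emflowtomo-model-v1",
        "name": model.name,
        "specs": {k: {"name": s.name, "input_shape": list(s.input_shape),
                      "layers": [asdict(l) for l in s.layers]} for k, s in model.specs.items()},
        "train_config": asdict(model.train_config),
        "input_stats": _stats_to_json(model.input_stats),
        "label_stats": _stats_to_json(model.label_stats) if model.label_stats else None,
    }
    np.savez(
        path,
        loss_history=model.loss_history,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **arrays,
    )


def load_model(path) -> TrainedModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        specs = {}
        networks = {}
        for key, sd in meta["specs"].items():
            spec = NetworkSpec(
                name=sd["name"],
                input_shape=tuple(sd["input_shape"]),
                layers=[LayerSpec(**ld) for ld in sd["layers"]],
            )
            specs[key] = spec
            net = build_network(spec, np.random.default_rng(0))
            state = {
                k.split("/", 1)[1]: z[k]
                for k in z.files
                if k.startswith(f"{key}/")
            }
            net.load_state_arrays(state)
            networks[key] = net
        return TrainedModel(
            name=meta["name"],
            networks=networks,
            specs=specs,
            train_config=TrainConfig(**meta["train_config"]),
            loss_history=np.array(z["loss_history"]),
            input_stats=_stats_from_json(meta["input_stats"]),
            label_stats=_stats_from_json(meta["label_stats"]) if meta["label_stats"] else None,
        )


def _stats_to_json(stats: dict | None) -> dict | None:
    if stats is None:
        return None
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in stats.items()}


def _stats_from_json(stats: dict) -> dict:
    return {k: (np.array(v) if isinstance(v, list) else v) for k, v in stats.items()}
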