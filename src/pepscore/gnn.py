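"""Graph-network regressor of normalized ligand RMSD.

Three full graph-net layers update edge, vertex and global features in
turn; each update concatenates the incident feature vectors (summing over
sets of unknown size), then applies perceptron -> batch normalization ->
ELU -> dropout.  Layer 1 consumes a constant dummy global input; later
layers consume the learned global.  A final convolution slides a kernel
across the per-layer learned global vectors and a linear map plus logistic
squash emits one scalar in [0, 1], regressing
``lrmsd_norm = 1/(1 + (LRMSD/8)^2)``.

Aggregation is summation, so the score is invariant to vertex relabeling.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, batchnorm_train, concat, linear
from .graph import ComplexGraph, EDGE_DIM, VERTEX_DIM

PARAMS_FORMAT_VERSION = "pepscore-params-1"
GLOBAL_IN_DIM = 1
BN_EPS = 1e-5
BN_MOMENTUM = 0.1


class ParamsIOError(IOError):
    """Raised when a parameter file cannot be loaded."""


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 3
    edge_dim: int = 32
    vertex_dim: int = 32
    global_dim: int = 32
    head_channels: int = 16
    head_kernel: int = 2
    dropout_rate: float = 0.40
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 1 <= self.head_kernel <= self.n_layers:
            raise ValueError("head_kernel must be in [1, n_layers]")


@dataclass
class ModelParams:
    """All weights of the network plus batch-norm running statistics."""

    config: ModelConfig
    arrays: dict[str, np.ndarray]

    def copy(self) -> "ModelParams":
        return ModelParams(self.config, {k: v.copy() for k, v in self.arrays.items()})

    def trainable_keys(self) -> list[str]:
        return [k for k in self.arrays if not k.endswith((".run_mean", ".run_var"))]


@dataclass
class ScorePrediction:
    score: float
    per_layer_globals: list[np.ndarray]


@dataclass
class GraphBatch:
    """Several graphs concatenated with ownership indices (for batching)."""

    vertices: np.ndarray
    edge_features: np.ndarray
    senders: np.ndarray
    receivers: np.ndarray
    v_graph: np.ndarray
    e_graph: np.ndarray
    globals_in: np.ndarray
    n_graphs: int
    _scatters: dict = field(default_factory=dict, repr=False)

    def scatter(self, name: str):
        """Cached sparse incidence matrix for a scatter-add, by index name."""
        if name not in self._scatters:
            from scipy.sparse import csr_matrix

            idx, n = {
                "senders": (self.senders, self.vertices.shape[0]),
                "receivers": (self.receivers, self.vertices.shape[0]),
                "e_graph": (self.e_graph, self.n_graphs),
                "v_graph": (self.v_graph, self.n_graphs),
            }[name]
            m = len(idx)
            self._scatters[name] = csr_matrix(
                (np.ones(m, dtype=np.float32), (idx, np.arange(m))), shape=(n, m)
            )
        return self._scatters[name]

    def astype(self, dtype) -> "GraphBatch":
        return GraphBatch(
            vertices=self.vertices.astype(dtype),
            edge_features=self.edge_features.astype(dtype),
            senders=self.senders,
            receivers=self.receivers,
            v_graph=self.v_graph,
            e_graph=self.e_graph,
            globals_in=self.globals_in.astype(dtype),
            n_graphs=self.n_graphs,
        )

    @classmethod
    def from_graphs(cls, graphs: list[ComplexGraph]) -> "GraphBatch":
        v_off = 0
        verts, efeats, snd, rcv, vg, eg, glob = [], [], [], [], [], [], []
        for gi, g in enumerate(graphs):
            verts.append(g.vertices)
            efeats.append(g.edge_features)
            snd.append(g.senders + v_off)
            rcv.append(g.receivers + v_off)
            vg.append(np.full(g.n_vertices, gi))
            eg.append(np.full(g.n_edges, gi))
            glob.append(g.global_in)
            v_off += g.n_vertices
        return cls(
            vertices=np.vstack(verts),
            edge_features=np.vstack(efeats),
            senders=np.concatenate(snd),
            receivers=np.concatenate(rcv),
            v_graph=np.concatenate(vg).astype(np.int64),
            e_graph=np.concatenate(eg).astype(np.int64),
            globals_in=np.vstack([g[None, :] for g in glob]),
            n_graphs=len(graphs),
        )


def _layer_dims(config: ModelConfig, layer: int) -> dict[str, tuple[int, int]]:
    e_in = EDGE_DIM if layer == 0 else config.edge_dim
    v_in = VERTEX_DIM if layer == 0 else config.vertex_dim
    g_in = GLOBAL_IN_DIM if layer == 0 else config.global_dim
    return {
        "edge": (e_in + 2 * v_in + g_in, config.edge_dim),
        "vertex": (config.edge_dim + v_in + g_in, config.vertex_dim),
        "global": (config.edge_dim + config.vertex_dim + g_in, config.global_dim),
    }


def init_params(config: ModelConfig, rng: np.random.Generator | None = None) -> ModelParams:
    """Fan-in scaled uniform initialization, seeded from the config."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arrays: dict[str, np.ndarray] = {}

    def block(prefix: str, fan_in: int, fan_out: int) -> None:
        bound = 1.0 / np.sqrt(fan_in)
        arrays[f"{prefix}.W"] = rng.uniform(-bound, bound, (fan_in, fan_out))
        arrays[f"{prefix}.b"] = rng.uniform(-bound, bound, fan_out)
        arrays[f"{prefix}.gamma"] = np.ones(fan_out)
        arrays[f"{prefix}.beta"] = np.zeros(fan_out)
        arrays[f"{prefix}.run_mean"] = np.zeros(fan_out)
        arrays[f"{prefix}.run_var"] = np.ones(fan_out)

    for layer in range(config.n_layers):
        for name, (fi, fo) in _layer_dims(config, layer).items():
            block(f"layer{layer}.{name}", fi, fo)

    n_windows = config.n_layers - config.head_kernel + 1
    conv_in = config.head_kernel * config.global_dim
    bound = 1.0 / np.sqrt(conv_in)
    arrays["head.W_conv"] = rng.uniform(-bound, bound, (conv_in, config.head_channels))
    arrays["head.b_conv"] = rng.uniform(-bound, bound, config.head_channels)
    out_in = n_windows * config.head_channels
    bound = 1.0 / np.sqrt(out_in)
    arrays["head.W_out"] = rng.uniform(-bound, bound, (out_in, 1))
    arrays["head.b_out"] = rng.uniform(-bound, bound, 1)
    return ModelParams(config=config, arrays=arrays)


def _check_shapes(params: ModelParams, batch: GraphBatch) -> None:
    cfg = params.config
    exp = _layer_dims(cfg, 0)["edge"][0]
    got = batch.edge_features.shape[1] + 2 * batch.vertices.shape[1] + batch.globals_in.shape[1]
    if exp != got:
        raise ValueError(
            f"layer 0 edge-update input width mismatch: params expect {exp}, "
            f"graph provides {got}"
        )


class _ForwardState:
    """Holds Tensor views of the parameters for one forward/backward pass."""

    def __init__(self, params: ModelParams, trainable: bool):
        self.tensors = {
            k: Tensor(v, requires_grad=trainable and not k.endswith((".run_mean", ".run_var")))
            for k, v in params.arrays.items()
        }

    def __getitem__(self, key: str) -> Tensor:
        return self.tensors[key]


def _batchnorm(
    x: Tensor,
    state: _ForwardState,
    params: ModelParams,
    prefix: str,
    training: bool,
    momentum: float = BN_MOMENTUM,
) -> Tensor:
    gamma, beta = state[f"{prefix}.gamma"], state[f"{prefix}.beta"]
    if training:
        out, mu, var = batchnorm_train(x, gamma, beta, eps=BN_EPS)
        run_mean = params.arrays[f"{prefix}.run_mean"]
        run_var = params.arrays[f"{prefix}.run_var"]
        run_mean *= 1.0 - momentum
        run_mean += momentum * mu
        run_var *= 1.0 - momentum
        run_var += momentum * var
        return out
    mean = params.arrays[f"{prefix}.run_mean"]
    var = params.arrays[f"{prefix}.run_var"]
    xhat = (x - Tensor(mean)) * Tensor(1.0 / np.sqrt(var + BN_EPS))
    return xhat * gamma + beta


def _dropout(x: Tensor, rate: float, training: bool, rng) -> Tensor:
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode forward needs an rng for dropout")
    mask = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.data.dtype)
    return x * Tensor(mask)


def _perceptron_stack(
    x: Tensor,
    state: _ForwardState,
    params: ModelParams,
    prefix: str,
    training: bool,
    rng,
    momentum: float = BN_MOMENTUM,
) -> Tensor:
    pre = linear(x, state[f"{prefix}.W"], state[f"{prefix}.b"])
    normed = _batchnorm(pre, state, params, prefix, training, momentum)
    return _dropout(normed.elu(), params.config.dropout_rate, training, rng)


def forward_batch(
    batch: GraphBatch,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    trainable: bool = False,
    bn_momentum: float = BN_MOMENTUM,
) -> tuple[Tensor, list[Tensor], _ForwardState]:
    """Run the network on a batch; returns (scores (B,1), per-layer globals)."""
    _check_shapes(params, batch)
    cfg = params.config
    state = _ForwardState(params, trainable)

    E = Tensor(batch.edge_features)
    V = Tensor(batch.vertices)
    G = Tensor(batch.globals_in)
    n_v, n_e, n_g = batch.vertices.shape[0], batch.edge_features.shape[0], batch.n_graphs

    learned_globals: list[Tensor] = []
    for layer in range(cfg.n_layers):
        p = f"layer{layer}"
        edge_in = concat(
            [E,
             V.gather_rows(batch.senders, batch.scatter("senders")),
             V.gather_rows(batch.receivers, batch.scatter("receivers")),
             G.gather_rows(batch.e_graph, batch.scatter("e_graph"))]
        )
        E = _perceptron_stack(edge_in, state, params, f"{p}.edge", training, rng, bn_momentum)

        incoming = E.segment_sum(batch.receivers, n_v, batch.scatter("receivers"))
        vertex_in = concat(
            [incoming, V, G.gather_rows(batch.v_graph, batch.scatter("v_graph"))]
        )
        V = _perceptron_stack(vertex_in, state, params, f"{p}.vertex", training, rng, bn_momentum)

        global_in = concat(
            [E.segment_sum(batch.e_graph, n_g, batch.scatter("e_graph")),
             V.segment_sum(batch.v_graph, n_g, batch.scatter("v_graph")),
             G]
        )
        G = _perceptron_stack(global_in, state, params, f"{p}.global", training, rng, bn_momentum)
        learned_globals.append(G)

    n_windows = cfg.n_layers - cfg.head_kernel + 1
    window_outs = []
    for w in range(n_windows):
        window = concat(learned_globals[w : w + cfg.head_kernel])
        act = linear(window, state["head.W_conv"], state["head.b_conv"]).elu()
        window_outs.append(act)
    stacked = concat(window_outs) if len(window_outs) > 1 else window_outs[0]
    scores = linear(stacked, state["head.W_out"], state["head.b_out"]).sigmoid()
    return scores, learned_globals, state


def recalibrate_bn(params: ModelParams, graphs: list[ComplexGraph] | GraphBatch) -> None:
    """Reset batch-norm running statistics from one full-data pass.

    Running averages accumulated over dropout-active minibatches do not
    match the activation distribution the fixed weights produce at
    evaluation time; one dropout-free pass with momentum 1 replaces them
    with the exact full-data statistics ("precise" batch norm).
    """
    batch = graphs if isinstance(graphs, GraphBatch) else GraphBatch.from_graphs(graphs)
    if batch.vertices.dtype != next(iter(params.arrays.values())).dtype:
        batch = batch.astype(next(iter(params.arrays.values())).dtype)
    no_dropout = ModelParams(
        config=replace(params.config, dropout_rate=0.0), arrays=params.arrays
    )
    forward_batch(batch, no_dropout, training=True, rng=None, bn_momentum=1.0)


def forward(
    graph: ComplexGraph,
    params: ModelParams,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> ScorePrediction:
    """Score a single complex graph; evaluation mode is deterministic."""
    batch = GraphBatch.from_graphs([graph])
    scores, globals_, _ = forward_batch(batch, params, training=training_mode, rng=rng)
    return ScorePrediction(
        score=float(scores.data[0, 0]),
        per_layer_globals=[g.data[0].copy() for g in globals_],
    )


def save_params(params: ModelParams, path) -> None:
    """Write parameters + config to a single self-describing .npz archive."""
    meta = {
        "format": PARAMS_FORMAT_VERSION,
        "config": {
            f.name: getattr(params.config, f.name)
            for f in params.config.__dataclass_fields__.values()
        },
    }
    payload = dict(params.arrays)
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    buf = io.BytesIO()
    np.savez(buf, **payload)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_params(path, expect_config: ModelConfig | None = None) -> ModelParams:
    """Load parameters; fails loudly on version or config mismatch."""
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
            meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        raise ParamsIOError(f"cannot read parameter file {path}: {exc}") from exc
    if meta.get("format") != PARAMS_FORMAT_VERSION:
        raise ParamsIOError(
            f"parameter file format {meta.get('format')!r} incompatible with "
            f"{PARAMS_FORMAT_VERSION!r}"
        )
    config = ModelConfig(**meta["config"])
    if expect_config is not None and config != expect_config:
        raise ParamsIOError(
            f"parameter file config {config} does not match expected {expect_config}"
        )
    return ModelParams(config=config, arrays=arrays)
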