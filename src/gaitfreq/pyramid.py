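"""Three-pathway frequency pyramid network with cross-domain fusion.

The classifier runs three parallel stacks of frequency-domain graph
convolution blocks at different anatomical granularities:

* **global** — the full skeleton graph (all joints connected as in the body),
* **half** — upper and lower body processed as separate components,
* **limb** — arms, legs and torso processed as separate components.

Every pathway keeps the full joint axis; a granularity is realized by
masking the skeleton's bone edges to those joining joints of the same
partition subset, so finer pathways see more, smaller connected components.
At each depth, a coarser pathway's features are injected into the next finer
one by a *cross-domain connection*: both blocks are linearly projected,
concatenated along channels, and projected back to the fine pathway's width.
Per-pathway mean pooling over frames and joints, channel concatenation and a
linear head produce the class scores.

Two ablation variants are built from the same code path: ``fgcn_only`` keeps
just the global pathway (a plain stacked frequency-GCN classifier), and
``pgcn_only`` keeps the pyramid but freezes every spectral mask at identity,
reducing each block to spatial graph aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fgcn import edge_weight_length
from .graphs import SkeletonGraph, PartitionScheme, default_partition, load_layout

__all__ = [
    "ModelConfig",
    "PathwayFeature",
    "FusionParams",
    "FPGCN",
    "TCNClassifier",
    "cross_domain_fuse",
    "pathway_graph",
    "label_smoothed_loss",
    "save_checkpoint",
    "load_checkpoint",
]

ABLATIONS = ("fpgcn", "fgcn_only", "pgcn_only")
CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters; the model is bound to a fixed frame count."""

    num_classes: int
    layout: str = "kinect25"
    in_channels: int = 3
    frames: int = 120
    depth: int = 2
    widths: tuple[int, ...] = (64, 48, 32)
    slope: float = 0.01          # LeakyReLU negative slope in F-GCN blocks
    epsilon: float = 0.1         # label-smoothing default
    ablation: str = "fpgcn"
    tcn_window: int = 9          # only used by the TCN baseline
    init_seed: int = 0
    dtype: str = "float32"       # float32 for training speed; float64 for checks

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        self.widths = tuple(int(w) for w in self.widths)


@dataclass
class PathwayFeature:
    """One pathway's feature stack output: (N, C, T, V) on the full joint set."""

    pathway_id: int
    depth: int
    values: "np.ndarray"

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class FusionParams:
    """Weights of one cross-domain connection (coarse -> fine injection)."""

    w_fine: Tensor       # (C_fine, C_fine)
    w_coarse: Tensor     # (C_coarse, C_coarse)
    w_proj: Tensor       # (C_fine, C_fine + C_coarse)
    b_proj: Tensor       # (C_fine,)

    @classmethod
    def passthrough(cls, c_fine: int, c_coarse: int, dtype="float64"):
        """Identity on the fine block, zero contribution from the coarse block."""
        proj = np.concatenate([np.eye(c_fine), np.zeros((c_fine, c_coarse))], axis=1)
        return cls(
            w_fine=Tensor(np.eye(c_fine, dtype=dtype), requires_grad=True),
            w_coarse=Tensor(np.eye(c_coarse, dtype=dtype), requires_grad=True),
            w_proj=Tensor(proj.astype(dtype), requires_grad=True),
            b_proj=Tensor(np.zeros(c_fine, dtype=dtype), requires_grad=True),
        )


def cross_domain_fuse(fine, coarse, params: FusionParams):
    """Inject a coarser pathway's features into a finer one.

    Both inputs are (N, C, T, V) with identical (T, V); the coarse features
    are already aligned joint-for-joint because every pathway indexes the
    same underlying skeleton.  Output width equals the fine input's width.
    """
    fine, coarse = ad.as_tensor(fine), ad.as_tensor(coarse)
    if fine.shape[2:] != coarse.shape[2:]:
        raise ValueError(
            f"fine {fine.shape} and coarse {coarse.shape} disagree on (T, V)"
        )
    a = ad.channel_linear(fine, params.w_fine)
    b = ad.channel_linear(coarse, params.w_coarse)
    cat = ad.concat([a, b], axis=1)
    return ad.channel_linear(cat, params.w_proj, params.b_proj)


def pathway_graph(graph: SkeletonGraph, subsets) -> SkeletonGraph:
    """The skeleton graph with bone edges masked to intra-subset pairs.

    All joints (and their self-loops) are retained, so every pathway shares
    the same joint index space; only connectivity becomes finer-grained.
    """
    groups = [frozenset(sub) for sub in subsets]
    edges = [
        (i, j)
        for (i, j) in graph.edges
        if any(i in g and j in g for g in groups)
    ]
    adj = np.eye(graph.n_joints, dtype=np.int64)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return SkeletonGraph(
        n_joints=graph.n_joints,
        joint_names=graph.joint_names,
        edges=tuple(edges),
        adjacency=adj,
        degrees=adj.sum(axis=1),
    )


def label_smoothed_loss(scores, labels, epsilon):
    """Label-smoothed cross-entropy averaged over the batch.

    Accepts a numpy array (returns a float) or a Tensor (returns a Tensor
    for backpropagation).  The smoothed target is 1 - epsilon on the true
    class and epsilon / (K - 1) elsewhere.
    """
    if isinstance(scores, Tensor):
        return ad.label_smoothed_ce(scores, labels, epsilon)
    return float(ad.label_smoothed_ce(Tensor(scores), labels, epsilon).data)


class _GraphStructure:
    """Precomputed index structures for one pathway's aggregation."""

    def __init__(self, graph: SkeletonGraph, dtype=np.float32):
        v = graph.n_joints
        self.graph = graph
        idx = np.zeros((v, v), dtype=np.intp)
        mask = np.zeros((v, v), dtype=dtype)
        for k, (i, j) in enumerate(graph.edges):
            idx[i, j] = idx[j, i] = k
            mask[i, j] = mask[j, i] = 1.0
        for i in range(v):
            idx[i, i] = len(graph.edges) + i
            mask[i, i] = 1.0
        self.idx_flat = idx.reshape(-1)
        self.support = mask
        self.inv_degree = (1.0 / graph.degrees)[:, None].astype(dtype)
        self.n_weights = edge_weight_length(graph)


class _ModelBase:
    """Shared parameter-dict plumbing for the small network classes."""

    def __init__(self, dtype="float32"):
        self.params: dict[str, Tensor] = {}
        self.dtype = np.dtype(dtype)

    def _param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=self.dtype), requires_grad=True)
        self.params[name] = t
        return t

    def trainable(self) -> dict[str, Tensor]:
        return self.params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state")
            if state[k].shape != v.data.shape:
                raise ValueError(f"parameter {k!r} shape mismatch")
            v.data = np.asarray(state[k], dtype=self.dtype).copy()

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def loss(self, x: np.ndarray, labels: np.ndarray, epsilon: float):
        return ad.label_smoothed_ce(self.forward(x), labels, epsilon)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(x).data, axis=1)


def _glorot(rng, shape):
    fan_in, fan_out = shape[-1], shape[0]
    return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)


class FPGCN(_ModelBase):
    """Frequency pyramid graph convolutional classifier (and its ablations)."""

    def __init__(self, config: ModelConfig, graph: SkeletonGraph | None = None,
                 partition: PartitionScheme | None = None):
        super().__init__(config.dtype)
        self.config = config
        layout = load_layout(config.layout)
        self.graph = graph if graph is not None else layout.graph()
        self.partition = (
            partition if partition is not None
            else default_partition(self.graph, layout)
        )
        self.spectral = config.ablation != "pgcn_only"
        self.pyramid = config.ablation != "fgcn_only"
        self.active = list(range(self.partition.n_pathways)) if self.pyramid else [0]
        self.widths = {ph: config.widths[ph] for ph in self.active}
        self.structures = {
            ph: _GraphStructure(
                pathway_graph(self.graph, self.partition.subsets(ph)), self.dtype
            )
            for ph in self.active
        }
        self._build(np.random.default_rng(config.init_seed))

    # -- parameters --------------------------------------------------------
    def _build(self, rng):
        cfg = self.config
        v = self.graph.n_joints
        f_bins = cfg.frames // 2 + 1
        for ph in self.active:
            w = self.widths[ph]
            self._param(f"lift_w_{ph}", _glorot(rng, (w, cfg.in_channels)))
            self._param(f"lift_b_{ph}", np.zeros(w))
            for i in range(cfg.depth):
                st = self.structures[ph]
                self._param(f"edge_{ph}_{i}", np.ones(st.n_weights))
                if self.spectral:
                    self._param(f"amask_{ph}_{i}", np.ones(w * v))
                    self._param(f"tmask_{ph}_{i}", np.ones(f_bins))
                self._param(f"mix_w_{ph}_{i}", np.eye(w))
                self._param(f"mix_b_{ph}_{i}", np.zeros(w))
                if self.pyramid and ph > 0:
                    cw = self.widths[ph - 1]
                    fp = FusionParams.passthrough(w, cw, self.dtype)
                    self.params[f"fuse_fine_{ph}_{i}"] = fp.w_fine
                    self.params[f"fuse_coarse_{ph}_{i}"] = fp.w_coarse
                    self.params[f"fuse_proj_{ph}_{i}"] = fp.w_proj
                    self.params[f"fuse_projb_{ph}_{i}"] = fp.b_proj
        total = sum(self.widths.values())
        self._param("head_w", _glorot(rng, (cfg.num_classes, total)))
        self._param("head_b", np.zeros(cfg.num_classes))

    def fusion_params(self, ph: int, i: int) -> FusionParams:
        return FusionParams(
            w_fine=self.params[f"fuse_fine_{ph}_{i}"],
            w_coarse=self.params[f"fuse_coarse_{ph}_{i}"],
            w_proj=self.params[f"fuse_proj_{ph}_{i}"],
            b_proj=self.params[f"fuse_projb_{ph}_{i}"],
        )

    # -- forward -----------------------------------------------------------
    def _block(self, h, ph: int, i: int):
        """One F-GCN block: aggregate -> spectral filter -> channel mix."""
        cfg = self.config
        st = self.structures[ph]
        we = self.params[f"edge_{ph}_{i}"]
        wm = ad.reshape(ad.take(we, st.idx_flat), st.support.shape)
        wm = ad.mul(ad.mul(wm, st.support), st.inv_degree)
        h = ad.joint_mix(h, wm)
        h = ad.leaky_relu(h, cfg.slope)
        if self.spectral:
            wa = self.params[f"amask_{ph}_{i}"]
            wf = self.params[f"tmask_{ph}_{i}"]
            s = wa.shape[0]
            rev = (-np.arange(s)) % s
            edge_mean = ad.mean(ad.leaky_relu(we, cfg.slope))
            a = ad.leaky_relu(ad.mul(edge_mean, wa), cfg.slope)
            a_sym = ad.mul(ad.add(a, ad.take(a, rev)), 0.5)
            b = ad.leaky_relu(wf, cfg.slope)
            h = ad.spectral_filter(h, a_sym, b)
        return ad.channel_linear(
            h, self.params[f"mix_w_{ph}_{i}"], self.params[f"mix_b_{ph}_{i}"]
        )

    def forward(self, x: np.ndarray) -> Tensor:
        """Class scores (N, K) from a (N, C, T, V) batch (time axis last inside)."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        n, c, t, v = x.shape
        cfg = self.config
        if (c, t, v) != (cfg.in_channels, cfg.frames, self.graph.n_joints):
            raise ValueError(
                f"input (C,T,V)=({c},{t},{v}) does not match model "
                f"({cfg.in_channels},{cfg.frames},{self.graph.n_joints})"
            )
        xt = Tensor(np.ascontiguousarray(x.transpose(0, 1, 3, 2), dtype=self.dtype))
        prev = {
            ph: ad.channel_linear(
                xt, self.params[f"lift_w_{ph}"], self.params[f"lift_b_{ph}"]
            )
            for ph in self.active
        }
        for i in range(cfg.depth):
            new = {}
            for ph in self.active:
                inp = prev[ph]
                if self.pyramid and ph > 0:
                    inp = cross_domain_fuse(inp, new[ph - 1], self.fusion_params(ph, i))
                new[ph] = ad.relu(self._block(inp, ph, i))
            prev = new
        pooled = [ad.mean(prev[ph], axes=(2, 3)) for ph in self.active]
        emb = pooled[0] if len(pooled) == 1 else ad.concat(pooled, axis=1)
        return ad.linear(emb, self.params["head_w"], self.params["head_b"])

    def pathway_forward(self, x: np.ndarray, ph: int) -> PathwayFeature:
        """Run a single pathway's stack (no fusion) over a (N, C, T, V) batch."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        h = ad.channel_linear(
            Tensor(np.ascontiguousarray(x.transpose(0, 1, 3, 2), dtype=self.dtype)),
            self.params[f"lift_w_{ph}"], self.params[f"lift_b_{ph}"],
        )
        for i in range(self.config.depth):
            h = ad.relu(self._block(h, ph, i))
        return PathwayFeature(
            pathway_id=ph,
            depth=self.config.depth,
            values=h.data.transpose(0, 1, 3, 2),
        )


class TCNClassifier(_ModelBase):
    """Parameter-matched baseline: fixed-window temporal convolution blocks.

    Mirrors the ``fgcn_only`` variant's topology (channel lift, per-depth
    graph neighbourhood sum + depthwise temporal window + channel mix, mean
    pooling, linear head) but extracts temporal structure with a fixed
    window instead of the frequency domain.
    """

    def __init__(self, config: ModelConfig, graph: SkeletonGraph | None = None):
        super().__init__(config.dtype)
        self.config = config
        layout = load_layout(config.layout)
        self.graph = graph if graph is not None else layout.graph()
        if not 1 <= config.tcn_window <= config.frames:
            raise ValueError("tcn_window must be in [1, frames]")
        self.adjacency = self.graph.adjacency.astype(self.dtype)
        rng = np.random.default_rng(config.init_seed)
        w = config.widths[0]
        self._param("lift_w", _glorot(rng, (w, config.in_channels)))
        self._param("lift_b", np.zeros(w))
        for i in range(config.depth):
            # moving-average init: a near-identity temporal smoother
            self._param(f"kern_{i}", np.full((w, config.tcn_window), 1.0 / config.tcn_window))
            self._param(f"mix_w_{i}", np.eye(w))
            self._param(f"mix_b_{i}", np.zeros(w))
        self._param("head_w", _glorot(rng, (config.num_classes, w)))
        self._param("head_b", np.zeros(config.num_classes))

    def forward(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        cfg = self.config
        xt = Tensor(np.ascontiguousarray(x.transpose(0, 1, 3, 2), dtype=self.dtype))
        h = ad.channel_linear(xt, self.params["lift_w"], self.params["lift_b"])
        norm = (self.adjacency / self.graph.degrees[:, None]).astype(self.dtype)
        for i in range(cfg.depth):
            h = ad.joint_mix(h, norm)
            h = ad.temporal_conv(h, self.params[f"kern_{i}"])
            h = ad.channel_linear(h, self.params[f"mix_w_{i}"], self.params[f"mix_b_{i}"])
            h = ad.relu(h)
        emb = ad.mean(h, axes=(2, 3))
        return ad.linear(emb, self.params["head_w"], self.params["head_b"])


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path, model):
    """Serialize config + parameters to an ``.npz`` array container."""
    header = {
        "version": CHECKPOINT_VERSION,
        "model_class": type(model).__name__,
        "config": asdict(model.config),
    }
    np.savez(
        path,
        __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **model.state_dict(),
    )


def load_checkpoint(path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unrecognized checkpoint version {header.get('version')}")
        cfg_raw = dict(header["config"])
        cfg_raw["widths"] = tuple(cfg_raw["widths"])
        config = ModelConfig(**cfg_raw)
        cls = {"FPGCN": FPGCN, "TCNClassifier": TCNClassifier}[header["model_class"]]
        model = cls(config)
        model.load_state_dict({k: data[k] for k in data.files if k != "__header__"})
    return model
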