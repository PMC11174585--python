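"""The frequency-domain graph convolution layer (F-GCN) and a TCN baseline.

An F-GCN layer processes a skeleton feature map (channels x frames x joints)
in four steps:

1. **Spatial graph aggregation** — each joint averages the edge-weighted
   features of its graph neighbourhood (self-loop included), normalized by
   its degree, followed by a LeakyReLU.
2. **Forward transform** — the (channel, joint) axes are flattened into one
   spatial axis of length S = C*V and an orthonormal 2D Fourier transform is
   taken over (space, time); by conjugate symmetry of a real signal only
   floor(T/2)+1 temporal bins are kept.
3. **Spectral weighting** — every coefficient is scaled by the product of a
   learnable spatial factor and a learnable temporal factor (both passed
   through LeakyReLU, the spatial one modulated by the mean activated edge
   weight).  The spatial factor is symmetrized across mirrored frequency
   bins so the filtered operator maps real signals to real signals.
4. **Inverse transform** — back to the spatio-temporal domain.

Because the masks are real, the filter rescales coefficient magnitudes and
preserves phases, which makes the layer equivariant to circular time shifts
— the property that lets it absorb walking-speed variation that defeats a
fixed-window temporal convolution (implemented here as the baseline).

The functions in this module are the plain-numpy reference path used
throughout the tests; the trainable network in :mod:`gaitfreq.pyramid`
routes the same arithmetic through the autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import SkeletonGraph

__all__ = [
    "FeatureMap",
    "SpectralTensor",
    "FGCNParams",
    "TCNBaselineParams",
    "spatial_aggregate",
    "to_frequency",
    "apply_spectral_weights",
    "from_frequency",
    "fgcn_layer_forward",
    "tcn_baseline_forward",
    "aggregation_matrix",
    "spectral_factors",
    "edge_weight_length",
]


@dataclass
class FeatureMap:
    """A (C, T, V) real tensor of per-joint features."""

    values: np.ndarray
    channel_semantics: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("FeatureMap must be (channels, frames, joints)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SpectralTensor:
    """Complex coefficients over S = C*V spatial bins x floor(T/2)+1 temporal bins."""

    coeffs: np.ndarray
    source_T: int

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.complex128)
        if self.coeffs.ndim != 2:
            raise ValueError("SpectralTensor must be 2-D (spatial bins, temporal bins)")
        if self.coeffs.shape[1] != self.source_T // 2 + 1:
            raise ValueError(
                f"temporal bins {self.coeffs.shape[1]} != floor(T/2)+1 for T={self.source_T}"
            )


def edge_weight_length(graph: SkeletonGraph) -> int:
    """One learnable weight per bone edge plus one per self-loop."""
    return len(graph.edges) + graph.n_joints


@dataclass
class FGCNParams:
    """Learnable parameters of one F-GCN layer.

    ``edge_weights`` holds one weight per bone edge followed by one per
    self-loop; ``spatial_mask`` has length S = C*V and ``temporal_mask``
    length floor(T/2)+1.  All default initializations are 1, which makes the
    untrained layer a near-identity.
    """

    edge_weights: np.ndarray
    spatial_mask: np.ndarray
    temporal_mask: np.ndarray
    slope: float = 0.01

    def __post_init__(self):
        self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64)
        self.spatial_mask = np.asarray(self.spatial_mask, dtype=np.float64)
        self.temporal_mask = np.asarray(self.temporal_mask, dtype=np.float64)
        for name in ("edge_weights", "spatial_mask", "temporal_mask"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @classmethod
    def identity(cls, graph: SkeletonGraph, channels: int, frames: int, slope: float = 0.01):
        s = channels * graph.n_joints
        f = frames // 2 + 1
        return cls(
            edge_weights=np.ones(edge_weight_length(graph)),
            spatial_mask=np.ones(s),
            temporal_mask=np.ones(f),
            slope=slope,
        )


@dataclass
class TCNBaselineParams:
    """Fixed-window temporal convolution kernel: (channels, window) plus stride s_d."""

    kernel: np.ndarray
    s_d: int = field(init=False)

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 2:
            raise ValueError("kernel must be (channels, window)")
        self.s_d = self.kernel.shape[1]
        if self.s_d < 1:
            raise ValueError("window length s_d must be >= 1")


def _leaky(x, slope):
    return np.where(x >= 0, x, slope * x)


def aggregation_matrix(graph: SkeletonGraph, edge_weights) -> np.ndarray:
    """Degree-normalized edge-weighted mixing matrix M with
    ``M[i, j] = W_E(edge ij) / d_i`` on adjacency support."""
    edge_weights = np.asarray(edge_weights, dtype=np.float64)
    v = graph.n_joints
    if edge_weights.shape != (edge_weight_length(graph),):
        raise ValueError(
            f"edge_weights length {edge_weights.shape} != bone edges + self-loops "
            f"({len(graph.edges)} + {v})"
        )
    m = np.zeros((v, v))
    for k, (i, j) in enumerate(graph.edges):
        m[i, j] = m[j, i] = edge_weights[k]
    m[np.diag_indices(v)] = edge_weights[len(graph.edges):]
    return m / graph.degrees[:, None]


def spatial_aggregate(x: FeatureMap, graph: SkeletonGraph, params: FGCNParams) -> FeatureMap:
    """Degree-normalized, edge-weighted neighbourhood average per joint,
    followed by the layer activation (LeakyReLU)."""
    if x.shape[2] != graph.n_joints:
        raise ValueError(f"feature map has {x.shape[2]} joints, graph {graph.n_joints}")
    m = aggregation_matrix(graph, params.edge_weights)
    agg = np.einsum("ij,ctj->cti", m, x.values)
    return FeatureMap(_leaky(agg, params.slope), x.channel_semantics)


def to_frequency(x: FeatureMap) -> SpectralTensor:
    """Orthonormal 2D Fourier transform of the flattened (C*V, T) features.

    Only the non-negative temporal frequencies (floor(T/2)+1 bins) are
    stored; the negative half is implied by conjugate symmetry.
    """
    c, t, v = x.shape
    xs = x.values.transpose(0, 2, 1).reshape(c * v, t)
    coeffs = np.fft.fft(np.fft.rfft(xs, axis=1, norm="ortho"), axis=0, norm="ortho")
    return SpectralTensor(coeffs, source_T=t)


def spectral_factors(params: FGCNParams, s: int, f: int):
    """Per-bin real scaling factors derived from the layer parameters.

    The spatial factor at bin s is LeakyReLU(mean(LeakyReLU(W_E)) * W_A[s]),
    symmetrized across mirrored bins (s and (S-s) mod S share a factor) so
    the filter maps real inputs to real outputs.  The temporal factor at bin
    t is LeakyReLU(W_F[t]).
    """
    if params.spatial_mask.shape != (s,):
        raise ValueError(f"spatial_mask length {params.spatial_mask.shape[0]} != S={s}")
    if params.temporal_mask.shape != (f,):
        raise ValueError(f"temporal_mask length {params.temporal_mask.shape[0]} != F={f}")
    edge_mean = _leaky(params.edge_weights, params.slope).mean()
    a = _leaky(edge_mean * params.spatial_mask, params.slope)
    rev = (-np.arange(s)) % s
    a_sym = 0.5 * (a + a[rev])
    b = _leaky(params.temporal_mask, params.slope)
    return a_sym, b


def apply_spectral_weights(
    xf: SpectralTensor, params: FGCNParams, edge_context: SkeletonGraph
) -> SpectralTensor:
    """Scale each coefficient by the spatial-bin and temporal-bin factors.

    The factors are real, so magnitudes are rescaled and phases preserved.
    """
    s, f = xf.coeffs.shape
    a_sym, b = spectral_factors(params, s, f)
    return SpectralTensor(a_sym[:, None] * b[None, :] * xf.coeffs, xf.source_T)


def from_frequency(xf: SpectralTensor, target_shape) -> FeatureMap:
    """Inverse orthonormal transform back to a real (C, T, V) feature map."""
    c, t, v = target_shape
    s, f = xf.coeffs.shape
    if s != c * v or t != xf.source_T or f != t // 2 + 1:
        raise ValueError(
            f"spectral shape {xf.coeffs.shape} (T={xf.source_T}) inconsistent with {target_shape}"
        )
    z = np.fft.ifft(xf.coeffs, axis=0, norm="ortho")
    xs = np.fft.irfft(z, n=t, axis=1, norm="ortho")
    return FeatureMap(xs.reshape(c, v, t).transpose(0, 2, 1))


def fgcn_layer_forward(x: FeatureMap, graph: SkeletonGraph, params: FGCNParams) -> FeatureMap:
    """Full F-GCN layer: aggregate -> transform -> weight -> inverse."""
    h = spatial_aggregate(x, graph, params)
    xf = to_frequency(h)
    xf = apply_spectral_weights(xf, params, graph)
    return from_frequency(xf, h.shape)


def tcn_baseline_forward(
    x: FeatureMap, graph: SkeletonGraph, params: TCNBaselineParams
) -> FeatureMap:
    """Fixed-window temporal convolution over the graph neighbourhood.

    ``y[c, t, i] = sum_{j in N(i) u {i}} sum_{tau < s_d} W[c, tau] * x[c, t+tau, j]``
    with zero padding past the end of the sequence.
    """
    c, t, v = x.shape
    if params.s_d > t:
        raise ValueError(f"window s_d={params.s_d} exceeds T={t}")
    if v != graph.n_joints:
        raise ValueError("feature map / graph joint mismatch")
    if params.kernel.shape[0] != c:
        raise ValueError("kernel channel count mismatch")
    u = np.einsum("ij,ctj->cti", graph.adjacency.astype(np.float64), x.values)
    y = np.zeros_like(u)
    for tau in range(params.s_d):
        y[:, : t - tau, :] += params.kernel[:, tau, None, None] * u[:, tau:, :]
    return FeatureMap(y, x.channel_semantics)
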