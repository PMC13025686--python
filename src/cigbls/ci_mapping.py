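"""Channel-independent mapping: isolated feature channels, per-channel
K-Means anchors and RBF enhancement nodes.

Each input variable is mapped through its own random affine map, so feature
columns of different channels never mix.  Enhancement nodes are RBF
similarities between a channel's feature block and a small set of anchors
clustered from that block alone; cross-variable coupling is recovered only
by the shared linear readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .bls_core import (
    ACTIVATIONS,
    KIND_ENHANCEMENT,
    KIND_FEATURE,
    NodeLayout,
    RandomMap,
    StateMatrix,
    _check_finite_matrix,
    _draw_map,
    subseed_int,
    subseed_rng,
)

__all__ = [
    "ChannelMaps",
    "AnchorSet",
    "init_channel_maps",
    "ci_feature_map",
    "fit_channel_anchors",
    "rbf_enhance",
    "assemble_state",
]

_SALT_CI_FEATURE = 0
_SALT_CI_KMEANS = 2


@dataclass(frozen=True)
class ChannelMaps:
    """Per-channel fixed random maps plus the input columns each consumes.

    For the channel-independent model every channel consumes exactly one
    input column; the fully connected ablation is expressed as a single
    channel spanning all columns.
    """

    per_channel_maps: tuple[RandomMap, ...]
    input_slices: tuple[slice, ...]
    nodes_per_channel: int

    def __post_init__(self) -> None:
        if len(self.per_channel_maps) != len(self.input_slices):
            raise ValueError("one input slice per channel map is required")
        for c, (m, sl) in enumerate(zip(self.per_channel_maps, self.input_slices)):
            width = sl.stop - sl.start
            if m.d_in != width:
                raise ValueError(f"channel {c} map consumes {m.d_in} columns, slice has {width}")
            if m.d_out != self.nodes_per_channel:
                raise ValueError("all channels must share nodes_per_channel")

    @property
    def channel_count(self) -> int:
        return len(self.per_channel_maps)

    @property
    def input_dim(self) -> int:
        return max(sl.stop for sl in self.input_slices) if self.input_slices else 0


def init_channel_maps(
    channel_widths: Sequence[int],
    nodes_per_channel: int,
    weight_init_range: tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
) -> ChannelMaps:
    """Draw one fixed random map per channel.

    ``channel_widths`` gives the number of consecutive input columns per
    channel (all ones for the channel-independent layout).  Channel ``c``
    draws from sub-stream ``(seed, salt, c)``, so its weights are identical
    no matter how many other channels exist.
    """
    if nodes_per_channel < 1:
        raise ValueError("nodes_per_channel must be >= 1")
    if any(w < 1 for w in channel_widths):
        raise ValueError("channel widths must be >= 1")
    maps, slices = [], []
    start = 0
    for c, width in enumerate(channel_widths):
        rng = subseed_rng(seed, _SALT_CI_FEATURE, c)
        maps.append(_draw_map(rng, width, nodes_per_channel, weight_init_range))
        slices.append(slice(start, start + width))
        start += width
    return ChannelMaps(tuple(maps), tuple(slices), nodes_per_channel)


def ci_feature_map(
    X: np.ndarray, maps: ChannelMaps, activation: str = "linear"
) -> tuple[np.ndarray, NodeLayout]:
    """Map each channel's input columns through its own random map.

    Returns the concatenated feature block ``Z_f = [Z_1 ... Z_M]`` and the
    column-to-channel layout.
    """
    X = _check_finite_matrix(X, "X")
    if X.shape[1] != maps.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns, channel maps expect {maps.input_dim}")
    phi = ACTIVATIONS[activation]
    blocks = [phi(m(X[:, sl])) for m, sl in zip(maps.per_channel_maps, maps.input_slices)]
    layout = NodeLayout.uniform(KIND_FEATURE, maps.channel_count, maps.nodes_per_channel)
    return np.hstack(blocks), layout


@dataclass(frozen=True)
class AnchorSet:
    """Frozen per-channel K-Means anchors and the shared RBF width."""

    per_channel_anchors: tuple[np.ndarray, ...]
    anchors_per_channel: int
    gamma: float
    kmeans_iters: int
    seed: int

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.anchors_per_channel < 1:
            raise ValueError("anchors_per_channel must be >= 1")

    @property
    def channel_count(self) -> int:
        return len(self.per_channel_anchors)

    @property
    def total_anchors(self) -> int:
        return sum(u.shape[0] for u in self.per_channel_anchors)


def fit_channel_anchors(
    Z_f: np.ndarray,
    layout: NodeLayout,
    anchors_per_channel: int,
    gamma: float,
    kmeans_iters: int = 100,
    seed: int = 0,
) -> AnchorSet:
    """Cluster each channel's feature block independently with K-Means.

    k-means++ initialization, a single restart and a capped iteration count,
    all driven by per-channel sub-seeds.  If a channel holds fewer distinct
    points than requested anchors, its anchor count is reduced with a
    warning.
    """
    Z_f = _check_finite_matrix(Z_f, "Z_f")
    anchors = []
    for c in range(layout.n_channels):
        block = Z_f[:, layout.columns(kind=KIND_FEATURE, channel=c)]
        n_distinct = np.unique(block, axis=0).shape[0]
        m_c = anchors_per_channel
        if n_distinct < m_c:
            warnings.warn(
                f"channel {c} has only {n_distinct} distinct points; "
                f"reducing anchors from {m_c} to {n_distinct}",
                RuntimeWarning,
                stacklevel=2,
            )
            m_c = n_distinct
        km = KMeans(
            n_clusters=m_c,
            init="k-means++",
            n_init=1,
            max_iter=kmeans_iters,
            random_state=subseed_int(seed, _SALT_CI_KMEANS, c),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn convergence chatter
            km.fit(block)
        anchors.append(km.cluster_centers_.copy())
    return AnchorSet(tuple(anchors), anchors_per_channel, gamma, kmeans_iters, seed)


def rbf_enhance(
    Z_f: np.ndarray, layout: NodeLayout, anchors: AnchorSet
) -> tuple[np.ndarray, NodeLayout]:
    """RBF similarity of each channel's features to its own anchors.

    ``H[i, (c,k)] = exp(-gamma * ||z_i^(c) - u_k^(c)||^2)``; entries lie in
    ``(0, 1]``.  Returns the concatenated enhancement block and its layout.
    """
    Z_f = _check_finite_matrix(Z_f, "Z_f")
    if anchors.channel_count != layout.n_channels:
        raise ValueError(
            f"anchor set covers {anchors.channel_count} channels, layout has {layout.n_channels}"
        )
    blocks = []
    channels = []
    for c, U in enumerate(anchors.per_channel_anchors):
        cols = layout.columns(kind=KIND_FEATURE, channel=c)
        block = Z_f[:, cols]
        if U.shape[1] != block.shape[1]:
            raise ValueError(f"channel {c} anchors have width {U.shape[1]}, features {block.shape[1]}")
        d2 = cdist(block, U, metric="sqeuclidean")
        blocks.append(np.exp(-anchors.gamma * d2))
        channels.append(np.full(U.shape[0], c, dtype=np.int64))
    H = np.hstack(blocks)
    channels = np.concatenate(channels)
    enh_layout = NodeLayout(np.full(channels.shape, KIND_ENHANCEMENT, dtype=np.int8), channels)
    return H, enh_layout


def assemble_state(
    Z_f: np.ndarray,
    feature_layout: NodeLayout,
    H: np.ndarray,
    enh_layout: NodeLayout,
    xi_scale: float,
) -> StateMatrix:
    """Concatenate ``A = [Z_f | xi * H]`` with merged layout."""
    Z_f = _check_finite_matrix(Z_f, "Z_f")
    H = _check_finite_matrix(H, "H")
    if Z_f.shape[0] != H.shape[0]:
        raise ValueError(f"row mismatch: Z_f has {Z_f.shape[0]} rows, H has {H.shape[0]}")
    values = np.hstack([Z_f, xi_scale * H])
    return StateMatrix(values, NodeLayout.concat(feature_layout, enh_layout))
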