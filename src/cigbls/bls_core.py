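"""Broad-network building blocks shared by all model variants.

A broad (flat) network maps the input into random *feature nodes*,
expands those into nonlinear *enhancement nodes*, concatenates both into a
single state matrix ``A`` and connects every node linearly to the output.
Training is one regularized linear solve — no gradient iteration.

This module hosts the fully connected baseline mapping, the node-layout
bookkeeping shared with the channel-independent variant, and the ridge
solver used by every model in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg
from scipy.special import expit

__all__ = [
    "ACTIVATIONS",
    "KIND_FEATURE",
    "KIND_ENHANCEMENT",
    "BLSConfig",
    "RandomMap",
    "NodeLayout",
    "StateMatrix",
    "OutputWeights",
    "subseed_rng",
    "subseed_int",
    "init_random_maps",
    "init_enhancement_maps",
    "map_feature_nodes",
    "map_enhancement_nodes",
    "solve_ridge",
    "predict",
]

#: Elementwise activations selectable by name.
ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda x: x,
    "tanh": np.tanh,
    "sigmoid": expit,
}

KIND_FEATURE = 0
KIND_ENHANCEMENT = 1

# Salts for the seed-splitting scheme: every consumer of randomness derives
# its generator from (master_seed, salt, index) so streams never collide and
# adding one group/channel does not shift any other group's draws.
_SALT_FEATURE = 0
_SALT_ENHANCEMENT = 1
_SALT_KMEANS = 2
_SALT_SPLIT = 3


def subseed_rng(seed: int, *path: int) -> np.random.Generator:
    """Independent generator for the sub-stream identified by ``path``."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, path))))


def subseed_int(seed: int, *path: int) -> int:
    """32-bit integer sub-seed (for libraries that take plain ints)."""
    ss = np.random.SeedSequence((int(seed), *map(int, path)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass(frozen=True)
class BLSConfig:
    """Hyperparameters of the fully connected broad baseline.

    ``n_feature_groups`` groups of ``nodes_per_group`` feature nodes and
    ``n_enh_groups`` groups of ``nodes_per_enh_group`` enhancement nodes.
    """

    n_feature_groups: int = 18
    nodes_per_group: int = 10
    n_enh_groups: int = 18
    nodes_per_enh_group: int = 10
    lambda_reg: float = 1e-3
    xi_scale: float = 0.5
    feature_activation: str = "linear"
    enh_activation: str = "tanh"
    weight_init_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_feature_groups", "nodes_per_group", "n_enh_groups", "nodes_per_enh_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.xi_scale <= 0:
            raise ValueError("xi_scale must be > 0")
        lo, hi = self.weight_init_range
        if not lo < hi:
            raise ValueError("weight_init_range must be a nonempty interval")
        if self.feature_activation not in ACTIVATIONS:
            raise ValueError(f"unknown feature_activation {self.feature_activation!r}")
        if self.enh_activation not in ACTIVATIONS:
            raise ValueError(f"unknown enh_activation {self.enh_activation!r}")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")


@dataclass(frozen=True)
class RandomMap:
    """One fixed random affine map: ``x -> x @ weights + bias``.

    Weights are drawn once at initialization and never updated.
    """

    weights: np.ndarray  # (d_in, d_out)
    bias: np.ndarray  # (d_out,)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        b = np.asarray(self.bias, dtype=float)
        if w.ndim != 2 or b.ndim != 1 or w.shape[1] != b.shape[0]:
            raise ValueError(f"non-conformable map shapes {w.shape} / {b.shape}")
        w = w.copy()
        b = b.copy()
        w.setflags(write=False)
        b.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", b)

    @property
    def d_in(self) -> int:
        return self.weights.shape[0]

    @property
    def d_out(self) -> int:
        return self.weights.shape[1]

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


@dataclass(frozen=True)
class NodeLayout:
    """Column bookkeeping for a node block: kind and channel of each column."""

    kinds: np.ndarray  # int8, KIND_FEATURE or KIND_ENHANCEMENT per column
    channels: np.ndarray  # int, channel/group index per column

    def __post_init__(self) -> None:
        kinds = np.asarray(self.kinds, dtype=np.int8)
        channels = np.asarray(self.channels, dtype=np.int64)
        if kinds.shape != channels.shape or kinds.ndim != 1:
            raise ValueError("layout arrays must be 1-D and of equal length")
        kinds.setflags(write=False)
        channels.setflags(write=False)
        object.__setattr__(self, "kinds", kinds)
        object.__setattr__(self, "channels", channels)

    @property
    def n_columns(self) -> int:
        return self.kinds.shape[0]

    @property
    def n_channels(self) -> int:
        return int(self.channels.max()) + 1 if self.n_columns else 0

    def columns(self, kind: int | None = None, channel: int | None = None) -> np.ndarray:
        """Indices of columns matching the given kind and/or channel."""
        mask = np.ones(self.n_columns, dtype=bool)
        if kind is not None:
            mask &= self.kinds == kind
        if channel is not None:
            mask &= self.channels == channel
        return np.flatnonzero(mask)

    @staticmethod
    def uniform(kind: int, n_channels: int, nodes_per_channel: int) -> "NodeLayout":
        channels = np.repeat(np.arange(n_channels), nodes_per_channel)
        return NodeLayout(np.full(channels.shape, kind, dtype=np.int8), channels)

    @staticmethod
    def concat(a: "NodeLayout", b: "NodeLayout") -> "NodeLayout":
        return NodeLayout(
            np.concatenate([a.kinds, b.kinds]),
            np.concatenate([a.channels, b.channels]),
        )


@dataclass(frozen=True)
class StateMatrix:
    """Assembled system state ``A = [feature block | scaled enhancement block]``."""

    values: np.ndarray  # (N, L_f + L_e)
    layout: NodeLayout

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("state matrix must be 2-D")
        if values.shape[1] != self.layout.n_columns:
            raise ValueError(
                f"layout covers {self.layout.n_columns} columns but values has {values.shape[1]}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("state matrix contains non-finite entries")
        object.__setattr__(self, "values", values)

    @property
    def n_feature_nodes(self) -> int:
        return int(np.count_nonzero(self.layout.kinds == KIND_FEATURE))

    @property
    def n_enh_nodes(self) -> int:
        return int(np.count_nonzero(self.layout.kinds == KIND_ENHANCEMENT))


@dataclass(frozen=True)
class OutputWeights:
    """Linear readout connecting every node to the output(s)."""

    W: np.ndarray  # (L, C)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2:
            raise ValueError("output weights must be 2-D (L x C)")
        if not np.all(np.isfinite(W)):
            raise ValueError("output weights contain non-finite entries")
        object.__setattr__(self, "W", W)

    @property
    def n_outputs(self) -> int:
        return self.W.shape[1]


def _draw_map(rng: np.random.Generator, d_in: int, d_out: int,
              init_range: tuple[float, float]) -> RandomMap:
    lo, hi = init_range
    return RandomMap(
        weights=rng.uniform(lo, hi, size=(d_in, d_out)),
        bias=rng.uniform(lo, hi, size=d_out),
    )


def init_random_maps(config: BLSConfig, input_dim: int) -> list[RandomMap]:
    """Draw the fixed input-to-feature maps, one per feature group.

    Each group gets its own sub-stream of the master seed, so the draws for
    group ``i`` do not depend on how many other groups exist.
    """
    if input_dim < 1:
        raise ValueError(f"input_dim must be >= 1, got {input_dim}")
    return [
        _draw_map(subseed_rng(config.seed, _SALT_FEATURE, i), input_dim,
                  config.nodes_per_group, config.weight_init_range)
        for i in range(config.n_feature_groups)
    ]


def init_enhancement_maps(config: BLSConfig) -> list[RandomMap]:
    """Draw the fixed feature-to-enhancement maps, one per enhancement group."""
    d_in = config.n_feature_groups * config.nodes_per_group
    return [
        _draw_map(subseed_rng(config.seed, _SALT_ENHANCEMENT, j), d_in,
                  config.nodes_per_enh_group, config.weight_init_range)
        for j in range(config.n_enh_groups)
    ]


def _check_finite_matrix(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def map_feature_nodes(X: np.ndarray, maps: Sequence[RandomMap], config: BLSConfig) -> np.ndarray:
    """Concatenate the feature-node groups ``phi(X W_i + b_i)`` column-wise."""
    X = _check_finite_matrix(X, "X")
    phi = ACTIVATIONS[config.feature_activation]
    blocks = []
    for i, m in enumerate(maps):
        if m.d_in != X.shape[1]:
            raise ValueError(f"map {i} expects {m.d_in} inputs, X has {X.shape[1]} columns")
        blocks.append(phi(m(X)))
    return np.hstack(blocks)


def map_enhancement_nodes(Z_n: np.ndarray, maps: Sequence[RandomMap], config: BLSConfig) -> np.ndarray:
    """Concatenate the enhancement groups ``psi(Z W_j + b_j)`` column-wise."""
    Z_n = _check_finite_matrix(Z_n, "Z_n")
    psi = ACTIVATIONS[config.enh_activation]
    blocks = []
    for j, m in enumerate(maps):
        if m.d_in != Z_n.shape[1]:
            raise ValueError(f"map {j} expects {m.d_in} inputs, Z has {Z_n.shape[1]} columns")
        blocks.append(psi(m(Z_n)))
    return np.hstack(blocks)


def _state_values(A: "StateMatrix | np.ndarray") -> np.ndarray:
    if isinstance(A, StateMatrix):
        return A.values
    return _check_finite_matrix(A, "A")


def _as_targets(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.ndim != 2:
        raise ValueError(f"targets must be 1-D or 2-D, got shape {Y.shape}")
    return Y


def solve_ridge(A: "StateMatrix | np.ndarray", Y: np.ndarray, lambda_reg: float) -> OutputWeights:
    """Closed-form readout: ``W = (lambda I + A^T A)^{-1} A^T Y``.

    Solved through a Cholesky factorization of the Gram matrix rather than an
    explicit inverse.  A singular system at ``lambda_reg == 0`` raises; an
    ill-conditioned system at positive ``lambda_reg`` falls back to the
    pseudo-inverse with a warning.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    values = _state_values(A)
    Y = _as_targets(Y)
    if values.shape[0] != Y.shape[0]:
        raise ValueError(f"A has {values.shape[0]} rows but Y has {Y.shape[0]}")
    G = values.T @ values
    G[np.diag_indices_from(G)] += lambda_reg
    rhs = values.T @ Y
    return OutputWeights(_solve_spd(G, rhs, lambda_reg))


def _solve_spd(G: np.ndarray, rhs: np.ndarray, lambda_reg: float) -> np.ndarray:
    """Solve a symmetric (nominally PD) system with a guarded fallback."""
    try:
        c, low = linalg.cho_factor(G, check_finite=False)
        return linalg.cho_solve((c, low), rhs, check_finite=False)
    except linalg.LinAlgError:
        if lambda_reg == 0:
            raise np.linalg.LinAlgError(
                "A^T A is numerically rank-deficient and lambda_reg is 0; "
                "set lambda_reg > 0 or provide a full-column-rank state matrix"
            ) from None
        warnings.warn(
            "Gram system is ill-conditioned; falling back to pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.linalg.pinv(G) @ rhs


def predict(A: "StateMatrix | np.ndarray", W: "OutputWeights | np.ndarray") -> np.ndarray:
    """Network output ``A @ W``."""
    values = _state_values(A)
    Wm = W.W if isinstance(W, OutputWeights) else np.asarray(W, dtype=float)
    if values.shape[1] != Wm.shape[0]:
        raise ValueError(f"A has {values.shape[1]} columns but W has {Wm.shape[0]} rows")
    return values @ Wm
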