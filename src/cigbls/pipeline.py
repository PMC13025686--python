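"""Preprocessing, metrics, model composition and experiment drivers.

Turns raw multi-rate batch records into a supervised design (assay-delay
alignment, label interpolation, sliding windows, train-only min-max
scaling), then fits/predicts the channel-independent anchor-graph model and
its ablation variants.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .bls_core import (
    KIND_ENHANCEMENT,
    KIND_FEATURE,
    NodeLayout,
    OutputWeights,
    StateMatrix,
    predict,
    solve_ridge,
    subseed_rng,
)
from .ci_mapping import (
    AnchorSet,
    ChannelMaps,
    assemble_state,
    ci_feature_map,
    fit_channel_anchors,
    init_channel_maps,
    rbf_enhance,
)
from .graph_reg import GraphRegularizer, build_anchor_regularizer, solve_manifold
from .synthetic_data import ProcessBatch, ProcessDataset

__all__ = [
    "CIGBLSConfig",
    "WindowedDesign",
    "MinMaxParams",
    "CIGBLSModel",
    "FitResult",
    "shift_target",
    "interpolate_labels",
    "make_windows",
    "stratified_batch_split",
    "minmax_fit",
    "minmax_apply",
    "compute_metrics",
    "build_designs",
    "fit_cigbls",
    "predict_cigbls",
    "grid_search",
    "run_ablation",
    "beta_sensitivity",
    "welch_ttest",
    "read_dataset_csv",
    "write_dataset_csv",
    "config_from_yaml",
]

ABLATION_VARIANTS = ("CI-GBLS", "w/o Graph", "w/o CI", "K-BLS")


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIGBLSConfig:
    """Hyperparameters of the channel-independent anchor-graph model.

    ``channel_independent=False`` collapses all inputs into one fully
    connected channel with the same total node budget (the "w/o CI"
    ablation); ``beta=0`` removes the anchor-graph constraint.
    """

    nodes_per_channel: int = 10
    anchors_per_channel: int = 10
    gamma: float = 0.1
    lambda_reg: float = 1e-3
    beta: float = 0.05
    xi_scale: float = 0.5
    feature_activation: str = "linear"
    kmeans_iters: int = 100
    channel_independent: bool = True
    weight_init_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nodes_per_channel < 1 or self.anchors_per_channel < 1:
            raise ValueError("node/anchor counts must be >= 1")
        if self.gamma < 0 or self.lambda_reg < 0 or self.beta < 0:
            raise ValueError("gamma, lambda_reg and beta must be >= 0")
        if self.xi_scale <= 0:
            raise ValueError("xi_scale must be > 0")


def config_from_yaml(path) -> CIGBLSConfig:
    """Load a :class:`CIGBLSConfig` from a YAML mapping of field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in CIGBLSConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "weight_init_range" in raw:
        raw["weight_init_range"] = tuple(raw["weight_init_range"])
    return CIGBLSConfig(**raw)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def shift_target(batch: ProcessBatch, delay_minutes: float) -> ProcessBatch:
    """Advance the quality series so inputs at t align with the assay drawn at t.

    An assay logged at time t reflects a sample drawn ``delay_minutes``
    earlier; shifting the observations back by the delay restores physical
    alignment.  Rows whose shifted target falls off the grid become NaN.
    """
    t = batch.timestamps
    dt = float(t[1] - t[0])
    shift_f = delay_minutes / dt
    shift = int(round(shift_f))
    if abs(shift_f - shift) > 1e-9:
        warnings.warn(
            f"delay {delay_minutes} min is not a multiple of the {dt} min sampling "
            f"interval; rounding to {shift} samples",
            RuntimeWarning,
            stacklevel=2,
        )
    q = batch.quality
    new_q = np.full_like(q, np.nan)
    if shift == 0:
        new_q[:] = q
    elif shift > 0:
        new_q[:-shift] = q[shift:]
    else:
        new_q[-shift:] = q[:shift]
    return replace(batch, quality=new_q)


def interpolate_labels(batch: ProcessBatch) -> np.ndarray:
    """Dense quality trend: linear between assays, held constant outside.

    With a single observation the whole series is constant-filled with a
    warning; with none, raises.
    """
    q = batch.quality
    obs = np.flatnonzero(~np.isnan(q))
    if obs.size == 0:
        raise ValueError(f"batch {batch.batch_id} has no quality observations")
    if obs.size == 1:
        warnings.warn(
            f"batch {batch.batch_id} has a single quality observation; constant fill",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full_like(q, q[obs[0]])
    t = batch.timestamps
    return np.interp(t, t[obs], q[obs])  # np.interp pads boundaries by holding


def make_windows(
    batch: ProcessBatch,
    window_len: int = 1,
    stride: int = 1,
    target: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Sliding-window design rows for one batch.

    Each row is the flattened window of all process variables ending at t
    (variable-major, oldest lag first) and the target is the dense quality
    at t.  Windows never cross batch boundaries by construction.  Returns
    ``(X, y, column_names)``.
    """
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    if target is None:
        target = interpolate_labels(batch)
    V = batch.process_vars
    T, M = V.shape
    if T < window_len:
        return (np.empty((0, M * window_len)), np.empty((0,)), _window_names(batch.var_names, window_len))
    ends = np.arange(window_len - 1, T, stride)
    rows = np.empty((ends.size, M * window_len))
    for r, t_end in enumerate(ends):
        win = V[t_end - window_len + 1 : t_end + 1]  # (window_len, M)
        rows[r] = win.T.reshape(-1)  # variable-major: var0 lags, var1 lags, ...
    return rows, np.asarray(target)[ends], _window_names(batch.var_names, window_len)


def _window_names(var_names: Sequence[str], window_len: int) -> tuple[str, ...]:
    if window_len == 1:
        return tuple(var_names)
    return tuple(
        f"{v}_lag{lag}" for v in var_names for lag in range(window_len - 1, -1, -1)
    )


def stratified_batch_split(
    batch_ids: Sequence[str],
    strata: Sequence,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Split batch ids train/test within each stratum.

    Per stratum the ids are shuffled and ``round(train_frac * n)`` go to
    train (clamped so train keeps at least one batch; a one-batch stratum
    contributes no test batch).  Deterministic under ``seed``.
    """
    if len(batch_ids) != len(strata):
        raise ValueError("every batch needs a stratum label")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = subseed_rng(seed, 3)
    train, test = [], []
    by_stratum: dict = {}
    for bid, s in zip(batch_ids, strata):
        by_stratum.setdefault(s, []).append(bid)
    for s in sorted(by_stratum, key=str):
        ids = sorted(by_stratum[s])
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


@dataclass(frozen=True)
class MinMaxParams:
    col_min: np.ndarray
    col_max: np.ndarray

    @property
    def scale(self) -> np.ndarray:
        return self.col_max - self.col_min


def minmax_fit(X: np.ndarray) -> MinMaxParams:
    """Per-column min/max on the given (training) rows only."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    if np.any(hi == lo):
        warnings.warn(
            "constant column(s) detected; they will map to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return MinMaxParams(lo, hi)


def minmax_apply(X: np.ndarray, params: MinMaxParams) -> np.ndarray:
    """Scale with frozen params; no clipping, so test rows may leave [0, 1]."""
    X = np.asarray(X, dtype=float)
    scale = np.where(params.scale == 0, 1.0, params.scale)
    return (X - params.col_min) / scale


def compute_metrics(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """RMSE, MAE and coefficient of determination."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float).reshape(y.shape)
    err = y - y_hat
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    centred = y - y.mean(axis=0)
    sst = float(np.sum(centred**2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return {"rmse": rmse, "mae": mae, "r2": r2}


# ---------------------------------------------------------------------------
# windowed design assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowedDesign:
    """Supervised design: scaled inputs, targets and batch membership."""

    X: np.ndarray  # (N, M_in), scaled
    Y: np.ndarray  # (N, C)
    groups: np.ndarray  # batch id per row
    column_names: tuple[str, ...]
    scaler_params: MinMaxParams | None = None
    Y_true: np.ndarray | None = None  # ground-truth targets, evaluation only

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def build_designs(
    dataset: ProcessDataset,
    train_ids: Iterable[str],
    test_ids: Iterable[str],
    delay_minutes: float = 240.0,
    window_len: int = 1,
    stride: int = 1,
) -> tuple[WindowedDesign, WindowedDesign]:
    """Shift -> interpolate -> window each batch, then scale on train only."""
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"batches in both splits: {sorted(overlap)}")

    def stack(ids):
        xs, ys, gs, yts = [], [], [], []
        names = None
        for bid in ids:
            batch = dataset.get(bid)
            shifted = shift_target(batch, delay_minutes)
            target = interpolate_labels(shifted)
            X, y, names = make_windows(shifted, window_len, stride, target=target)
            xs.append(X)
            ys.append(y)
            gs.append(np.full(y.shape, bid, dtype=object))
            if batch.quality_true is not None:
                ends = np.arange(window_len - 1, batch.n_steps, stride)
                yts.append(batch.quality_true[ends])
        X = np.vstack(xs)
        y = np.concatenate(ys)[:, None]
        groups = np.concatenate(gs)
        y_true = np.concatenate(yts)[:, None] if len(yts) == len(ids) and yts else None
        return X, y, groups, y_true, names

    Xtr, Ytr, gtr, Ttr, names = stack(train_ids)
    scaler = minmax_fit(Xtr)
    train = WindowedDesign(minmax_apply(Xtr, scaler), Ytr, gtr, names, scaler, Ttr)
    if test_ids:
        Xte, Yte, gte, Tte, _ = stack(test_ids)
        test = WindowedDesign(minmax_apply(Xte, scaler), Yte, gte, names, scaler, Tte)
    else:
        test = WindowedDesign(
            np.empty((0, Xtr.shape[1])), np.empty((0, 1)), np.empty(0, dtype=object),
            names, scaler, None,
        )
    return train, test


# ---------------------------------------------------------------------------
# model fit / predict
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIGBLSModel:
    """Frozen model state: maps, anchors, graph pieces and readout."""

    config: CIGBLSConfig
    maps: ChannelMaps
    feature_layout: NodeLayout
    anchors: AnchorSet
    enh_layout: NodeLayout
    regularizer: GraphRegularizer | None
    weights: OutputWeights
    scaler_params: MinMaxParams | None = None


@dataclass(frozen=True)
class FitResult:
    model: CIGBLSModel
    metrics: dict[str, float]
    train_time_s: float


def _channel_widths(n_inputs: int, config: CIGBLSConfig) -> tuple[list[int], int, int]:
    """Channel layout plus per-channel node/anchor budgets for a variant.

    The fully connected variant keeps the same *total* node and anchor
    budget as the channel-independent one so ablations are scale-matched.
    """
    if config.channel_independent:
        return [1] * n_inputs, config.nodes_per_channel, config.anchors_per_channel
    return [n_inputs], config.nodes_per_channel * n_inputs, config.anchors_per_channel * n_inputs


def _build_structure(X: np.ndarray, config: CIGBLSConfig):
    """Maps, anchors and the assembled state matrix for training rows."""
    widths, nodes, anchors_n = _channel_widths(X.shape[1], config)
    maps = init_channel_maps(widths, nodes, config.weight_init_range, config.seed)
    Z_f, f_layout = ci_feature_map(X, maps, config.feature_activation)
    anchors = fit_channel_anchors(
        Z_f, f_layout, anchors_n, config.gamma, config.kmeans_iters, config.seed
    )
    H, e_layout = rbf_enhance(Z_f, f_layout, anchors)
    A = assemble_state(Z_f, f_layout, H, e_layout, config.xi_scale)
    return maps, f_layout, anchors, e_layout, H, A


def _transform(model: CIGBLSModel, X: np.ndarray) -> StateMatrix:
    """State matrix for new rows using frozen maps and anchors."""
    Z_f, f_layout = ci_feature_map(X, model.maps, model.config.feature_activation)
    H, e_layout = rbf_enhance(Z_f, f_layout, model.anchors)
    return assemble_state(Z_f, f_layout, H, e_layout, model.config.xi_scale)


def fit_cigbls(train: WindowedDesign, config: CIGBLSConfig) -> FitResult:
    """Fit the model on a windowed design (one analytic solve, no iteration)."""
    t0 = time.perf_counter()
    maps, f_layout, anchors, e_layout, H, A = _build_structure(train.X, config)
    if config.beta > 0:
        reg = build_anchor_regularizer(H, config.beta)
        W = solve_manifold(A, train.Y, config.lambda_reg, reg)
    else:
        reg = None
        W = solve_ridge(A, train.Y, config.lambda_reg)
    elapsed = time.perf_counter() - t0
    model = CIGBLSModel(config, maps, f_layout, anchors, e_layout, reg, W, train.scaler_params)
    metrics = compute_metrics(train.Y, predict(A, W))
    return FitResult(model, metrics, elapsed)


def predict_cigbls(fitted: "FitResult | CIGBLSModel", X_new: np.ndarray) -> np.ndarray:
    """Predict on already-scaled inputs with frozen maps/anchors/weights."""
    model = fitted.model if isinstance(fitted, FitResult) else fitted
    return predict(_transform(model, X_new), model.weights)


# ---------------------------------------------------------------------------
# model selection and ablation
# ---------------------------------------------------------------------------

def default_grids() -> dict[str, tuple[float, ...]]:
    """Log grids for lambda in [1e-4, 10], gamma in [1e-4, 1], small beta set."""
    return {
        "lambda_reg": tuple(np.logspace(-4, 1, 6)),
        "gamma": tuple(np.logspace(-4, 0, 5)),
        "beta": (0.0, 0.01, 0.05),
    }


def grid_search(
    train: WindowedDesign,
    base_config: CIGBLSConfig,
    grids: dict[str, Sequence[float]] | None = None,
    val_frac: float = 0.2,
    seed: int = 0,
) -> tuple[CIGBLSConfig, pd.DataFrame]:
    """Exhaustive search minimizing validation RMSE.

    Holds out ``val_frac`` of the training *batches* as validation, caches
    the random maps/anchors (which do not depend on lambda, gamma or beta)
    and re-solves only the readout per candidate.  Ties are broken toward
    smaller beta, then larger lambda.
    """
    grids = dict(default_grids(), **(grids or {}))
    ids = sorted(set(train.groups))
    if len(ids) < 2:
        raise ValueError("grid search needs at least two training batches")
    rng = subseed_rng(seed, 4)
    perm = rng.permutation(len(ids))
    n_val = min(max(int(round(val_frac * len(ids))), 1), len(ids) - 1)
    val_ids = {ids[i] for i in perm[:n_val]}
    val_mask = np.isin(train.groups, list(val_ids))
    X_fit, Y_fit = train.X[~val_mask], train.Y[~val_mask]
    X_val, Y_val = train.X[val_mask], train.Y[val_mask]

    widths, nodes, anchors_n = _channel_widths(train.X.shape[1], base_config)
    maps = init_channel_maps(widths, nodes, base_config.weight_init_range, base_config.seed)
    Z_fit, f_layout = ci_feature_map(X_fit, maps, base_config.feature_activation)
    Z_val, _ = ci_feature_map(X_val, maps, base_config.feature_activation)
    anchors_base = fit_channel_anchors(
        Z_fit, f_layout, anchors_n, 0.0, base_config.kmeans_iters, base_config.seed
    )

    records = []
    best = None  # (rmse, beta, -lambda, config)
    for gamma in grids["gamma"]:
        anchors = replace(anchors_base, gamma=float(gamma))
        H_fit, e_layout = rbf_enhance(Z_fit, f_layout, anchors)
        H_val, _ = rbf_enhance(Z_val, f_layout, anchors)
        A_fit = assemble_state(Z_fit, f_layout, H_fit, e_layout, base_config.xi_scale)
        A_val = assemble_state(Z_val, f_layout, H_val, e_layout, base_config.xi_scale)
        reg0 = build_anchor_regularizer(H_fit, 0.0)
        for beta in grids["beta"]:
            for lam in grids["lambda_reg"]:
                if beta > 0:
                    W = solve_manifold(A_fit, Y_fit, lam, reg0.with_beta(beta))
                else:
                    W = solve_ridge(A_fit, Y_fit, lam)
                rmse = compute_metrics(Y_val, predict(A_val, W))["rmse"]
                records.append(
                    {"lambda_reg": lam, "gamma": gamma, "beta": beta, "val_rmse": rmse}
                )
                key = (rmse, beta, -lam)
                if best is None or key < best[0]:
                    cfg = replace(
                        base_config, lambda_reg=float(lam), gamma=float(gamma), beta=float(beta)
                    )
                    best = (key, cfg)
    return best[1], pd.DataFrame.from_records(records)


def run_ablation(
    train: WindowedDesign,
    test: WindowedDesign,
    config: CIGBLSConfig,
    target: str = "observed",
) -> pd.DataFrame:
    """Fit the four structural variants under identical seeds and budgets.

    Rows: full model, without the anchor-graph term, without channel
    independence, and with both removed.  ``target='true'`` scores against
    ground-truth dense quality when the design carries it.
    """
    variants = {
        "CI-GBLS": config,
        "w/o Graph": replace(config, beta=0.0),
        "w/o CI": replace(config, channel_independent=False),
        "K-BLS": replace(config, channel_independent=False, beta=0.0),
    }
    rows = []
    for name, cfg in variants.items():
        result = fit_cigbls(train, cfg)
        y_hat = predict_cigbls(result, test.X)
        y_ref = _reference_targets(test, target)
        m = compute_metrics(y_ref, y_hat)
        rows.append({"variant": name, **m, "train_time_s": result.train_time_s})
    return pd.DataFrame(rows).set_index("variant")


def _reference_targets(design: WindowedDesign, target: str) -> np.ndarray:
    if target == "true":
        if design.Y_true is None:
            raise ValueError("design carries no ground-truth targets")
        return design.Y_true
    if target != "observed":
        raise ValueError("target must be 'observed' or 'true'")
    return design.Y


def beta_sensitivity(
    train: WindowedDesign,
    test: WindowedDesign,
    config: CIGBLSConfig,
    beta_grid: Sequence[float],
    target: str = "observed",
) -> pd.DataFrame:
    """Test RMSE as a function of the manifold coefficient.

    The structure (maps, anchors, state matrices, graph factors) is built
    once; only the readout solve is repeated per beta.
    """
    maps, f_layout, anchors, e_layout, H, A = _build_structure(train.X, config)
    reg0 = build_anchor_regularizer(H, 0.0)
    model_stub = CIGBLSModel(config, maps, f_layout, anchors, e_layout, None,
                             OutputWeights(np.zeros((A.values.shape[1], train.Y.shape[1]))),
                             train.scaler_params)
    A_test = _transform(model_stub, test.X)
    y_ref = _reference_targets(test, target)
    rows = []
    for beta in beta_grid:
        W = solve_manifold(A, train.Y, config.lambda_reg, reg0.with_beta(float(beta)))
        m = compute_metrics(y_ref, predict(A_test, W))
        rows.append({"beta": float(beta), **m})
    return pd.DataFrame(rows)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Welch's unequal-variance t-test over repeated-run metric samples."""
    t, p = stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)
    return {"t": float(t), "p": float(p)}


# ---------------------------------------------------------------------------
# CSV I/O (long format: one row per time step, one file per dataset)
# ---------------------------------------------------------------------------

def dataset_to_frame(dataset: ProcessDataset) -> pd.DataFrame:
    frames = []
    for b in dataset:
        df = pd.DataFrame(b.process_vars, columns=list(b.var_names))
        df.insert(0, "batch_id", b.batch_id)
        df.insert(1, "mode", b.mode)
        df.insert(2, "time_min", b.timestamps)
        df["quality"] = b.quality
        if b.quality_true is not None:
            df["quality_true"] = b.quality_true
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_dataset_csv(dataset: ProcessDataset, path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def read_dataset_csv(path) -> ProcessDataset:
    """Read the long-format CSV dialect written by :func:`write_dataset_csv`."""
    df = pd.read_csv(path)
    meta = {"batch_id", "mode", "time_min", "quality", "quality_true"}
    var_names = tuple(c for c in df.columns if c not in meta)
    batches = []
    for bid, sub in df.groupby("batch_id", sort=True):
        sub = sub.sort_values("time_min")
        batches.append(
            ProcessBatch(
                batch_id=str(bid),
                timestamps=sub["time_min"].to_numpy(dtype=float),
                process_vars=sub[list(var_names)].to_numpy(dtype=float),
                var_names=var_names,
                quality=sub["quality"].to_numpy(dtype=float),
                mode=int(sub["mode"].iloc[0]) if "mode" in sub else 0,
                quality_true=(
                    sub["quality_true"].to_numpy(dtype=float) if "quality_true" in sub else None
                ),
            )
        )
    return ProcessDataset(tuple(batches), {"source": str(path)})
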