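"""Desk-scale experiment drivers: benchmark assembly, ablation sweeps,
manifold-coefficient sensitivity and empirical complexity trends.

These keep every study reproducible from a single integer seed and small
enough to run on one CPU in minutes; sizes are deliberately reduced from
industrial scale and documented as such.
"""

from __future__ import annotations

import time
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bls_core import subseed_rng
from .graph_reg import build_dense_lap_oracle, solve_dense_lap
from .pipeline import (
    CIGBLSConfig,
    WindowedDesign,
    beta_sensitivity,
    build_designs,
    compute_metrics,
    fit_cigbls,
    run_ablation,
    stratified_batch_split,
)
from .synthetic_data import SimConfig, simulate_dataset

__all__ = [
    "default_sim_config",
    "default_model_config",
    "make_benchmark",
    "ablation_experiment",
    "sensitivity_experiment",
    "complexity_experiment",
]


def default_sim_config(seed: int, **overrides) -> SimConfig:
    """Desk-scale generator settings for the standard experiments."""
    params = dict(
        n_batches=12,
        duration_h=100.0,
        process_dt_min=12.0,
        quality_dt_h=12.0,
        n_vars=10,
        assay_delay_h=4.0,
        noise_sd=0.05,
        assay_noise_sd=0.15,
        batch_variability_sd=0.05,
        control_modes=3,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def default_model_config(seed: int, **overrides) -> CIGBLSConfig:
    """Desk-scale model settings (node budget reduced from industrial scale)."""
    params = dict(
        nodes_per_channel=8,
        anchors_per_channel=8,
        gamma=0.1,
        lambda_reg=1e-3,
        beta=0.05,
        xi_scale=0.5,
        seed=seed,
    )
    params.update(overrides)
    return CIGBLSConfig(**params)


def make_benchmark(
    seed: int,
    sim_overrides: dict | None = None,
    train_frac: float = 0.8,
    window_len: int = 1,
    delay_minutes: float = 240.0,
    stride: int = 1,
) -> tuple[WindowedDesign, WindowedDesign]:
    """Simulate a dataset, split by stratified batches and build designs."""
    cfg = default_sim_config(seed, **(sim_overrides or {}))
    dataset = simulate_dataset(cfg)
    train_ids, test_ids = stratified_batch_split(
        dataset.batch_ids, dataset.modes, train_frac=train_frac, seed=seed
    )
    return build_designs(dataset, train_ids, test_ids,
                         delay_minutes=delay_minutes, window_len=window_len, stride=stride)


# Standard ablation regime: pronounced batch-to-batch variability, noisy
# assays and a barely-there ridge, so both structural components have work
# to do.  Scored against the observed (interpolated-assay) test labels.
ABLATION_SIM = dict(
    noise_sd=0.2, assay_noise_sd=1.0, n_vars=10, n_batches=16, batch_variability_sd=0.12
)
ABLATION_MODEL = dict(lambda_reg=1e-6, gamma=0.5, beta=0.05)


def ablation_experiment(
    seeds: Sequence[int],
    sim_overrides: dict | None = None,
    model_overrides: dict | None = None,
    stride: int = 5,
    target: str = "observed",
) -> pd.DataFrame:
    """Per-seed metrics of the four structural variants.

    The effect sizes are small relative to seed-to-seed spread, so the
    ordering claim is about medians over a few dozen seeds, never about a
    single run.
    """
    frames = []
    for seed in seeds:
        train, test = make_benchmark(seed, {**ABLATION_SIM, **(sim_overrides or {})},
                                     stride=stride)
        config = default_model_config(seed, **{**ABLATION_MODEL, **(model_overrides or {})})
        table = run_ablation(train, test, config, target=target).reset_index()
        table.insert(0, "seed", seed)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def sensitivity_experiment(
    seed: int,
    beta_grid: Sequence[float] | None = None,
    sim_overrides: dict | None = None,
    model_overrides: dict | None = None,
    target: str = "observed",
) -> pd.DataFrame:
    """Test RMSE over a wide manifold-coefficient grid on synthetic data.

    Runs in the same noisy regime as the ablation study, where the curve
    shows a flat low-RMSE plateau for small beta and sharp degradation
    (over-smoothing) beyond beta ~ 1.
    """
    if beta_grid is None:
        beta_grid = [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.5, 1.0, 10.0]
    train, test = make_benchmark(seed, {**ABLATION_SIM, **(sim_overrides or {})})
    config = default_model_config(seed, **{**ABLATION_MODEL, **(model_overrides or {})})
    return beta_sensitivity(train, test, config, beta_grid, target=target)


def _timing_data(seed: int, n: int, n_vars: int) -> tuple[np.ndarray, np.ndarray]:
    """Cheap nonlinear regression data for runtime scaling (content-free)."""
    rng = subseed_rng(seed, 7, n)
    X = rng.uniform(0.0, 1.0, size=(n, n_vars))
    y = np.tanh(X @ rng.standard_normal(n_vars)) + 0.1 * rng.standard_normal(n)
    return X, y[:, None]


def complexity_experiment(
    seed: int,
    n_grid_fast: Sequence[int] = (1000, 2000, 4000, 8000),
    n_grid_dense: Sequence[int] = (500, 1000, 2000, 4000),
    n_vars: int = 8,
    repeats: int = 3,
) -> dict:
    """Log-log runtime slope vs N for the anchor path and the dense oracle.

    The anchor path times a full fit (maps, per-channel K-Means, RBF,
    analytic solve); the oracle path times dense k-NN graph construction
    plus the dense Laplacian solve.  Returns slopes and the raw timing
    table; this is a trend check, never a wall-clock constant.
    """
    # wide enough that per-sample work dominates fixed overhead at N >= 500
    config = default_model_config(seed, nodes_per_channel=16, anchors_per_channel=16)
    rows = []

    def best_time(fn) -> float:
        times = []
        for _ in range(repeats):
            t0 = time.perf_counter()
            fn()
            times.append(time.perf_counter() - t0)
        return min(times)

    for n in n_grid_fast:
        X, y = _timing_data(seed, n, n_vars)
        design = WindowedDesign(X, y, np.zeros(n, dtype=object), tuple(f"v{i}" for i in range(n_vars)))
        rows.append({"path": "anchor", "n": n, "seconds": best_time(lambda: fit_cigbls(design, config))})

    for n in n_grid_dense:
        X, y = _timing_data(seed, n, n_vars)
        design = WindowedDesign(X, y, np.zeros(n, dtype=object), tuple(f"v{i}" for i in range(n_vars)))
        A = fit_cigbls(design, replace(config, beta=0.0))  # structure reused below
        from .pipeline import _transform  # local import to avoid cycle at module load

        state = _transform(A.model, X)

        def dense_path():
            graph = build_dense_lap_oracle(X, k_neighbors=10)
            solve_dense_lap(state, y, config.lambda_reg, config.beta, graph)

        rows.append({"path": "dense", "n": n, "seconds": best_time(dense_path)})

    table = pd.DataFrame(rows)

    def slope(path: str) -> float:
        sub = table[table["path"] == path]
        return float(np.polyfit(np.log(sub["n"]), np.log(sub["seconds"]), 1)[0])

    return {"anchor_slope": slope("anchor"), "dense_slope": slope("dense"), "timings": table}
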