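"""Seeded generator of fed-batch fermentation-like process data.

Produces multivariate batch time series with the statistical features a
multi-rate soft sensor has to cope with: high-frequency process variables,
a slowly varying quality variable assayed every few hours with an
analytical delay, nonlinear inter-variable coupling with heterogeneous
per-variable dynamics, control-mode strata and batch-to-batch variability.

The latent state follows a small Monod-type fed-batch model (logistic
biomass growth, substrate depletion against a mode-dependent feed, product
formation proportional to biomass with substrate saturation); observed
variables are lagged nonlinear mixtures of the latents plus noise.  This is
deliberately a statistical emulator, not a mechanistic simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .bls_core import subseed_rng

__all__ = ["SimConfig", "simulate_batch", "simulate_dataset", "ProcessBatch", "ProcessDataset"]


@dataclass(frozen=True)
class ProcessBatch:
    """One batch: dense process variables plus a sparse quality series.

    ``quality`` lives on the process grid with NaN at unobserved steps;
    ``quality_true`` (if present) is the dense noise-free ground truth used
    only for evaluation.
    """

    batch_id: str
    timestamps: np.ndarray  # minutes, strictly increasing
    process_vars: np.ndarray  # (T, M)
    var_names: tuple[str, ...]
    quality: np.ndarray  # (T,), NaN where unobserved
    mode: int = 0
    quality_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be 1-D and strictly increasing")
        if self.process_vars.shape != (t.shape[0], len(self.var_names)):
            raise ValueError("process_vars shape must be (T, M)")
        if self.quality.shape != t.shape:
            raise ValueError("quality must live on the process grid")

    @property
    def n_steps(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_vars(self) -> int:
        return len(self.var_names)


@dataclass(frozen=True)
class ProcessDataset:
    batches: tuple[ProcessBatch, ...]
    manifest: dict = field(default_factory=dict)

    @property
    def batch_ids(self) -> list[str]:
        return [b.batch_id for b in self.batches]

    @property
    def modes(self) -> list[int]:
        return [b.mode for b in self.batches]

    def __iter__(self):
        return iter(self.batches)

    def __len__(self) -> int:
        return len(self.batches)

    def get(self, batch_id: str) -> ProcessBatch:
        for b in self.batches:
            if b.batch_id == batch_id:
                return b
        raise KeyError(batch_id)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings (desk-scale experiments override the defaults)."""

    n_batches: int = 10
    duration_h: float = 230.0
    process_dt_min: float = 12.0
    quality_dt_h: float = 12.0
    n_vars: int = 18
    assay_delay_h: float = 4.0
    noise_sd: "float | tuple[float, ...]" = 0.02  # relative; scalar or one value per variable
    assay_noise_sd: float = 0.15  # absolute, in product units
    batch_variability_sd: float = 0.05
    control_modes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.n_vars < 1 or self.control_modes < 1:
            raise ValueError("counts must be >= 1")
        if self.duration_h / self.quality_dt_h < 1:
            raise ValueError("duration must cover at least 2 assays")
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if np.any(noise < 0) or noise.size not in (1, self.n_vars):
            raise ValueError("noise_sd must be >= 0, scalar or one value per variable")
        for name in ("assay_noise_sd", "batch_variability_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.process_dt_min <= 0 or self.quality_dt_h <= 0:
            raise ValueError("sampling intervals must be positive")


# Baseline kinetic constants; batch effects perturb them multiplicatively.
_KIN = dict(mu_max=0.12, Ks=0.1, Xmax=35.0, Yxs=0.45, ms=0.014, kp=0.02, Kp=0.08,
            X0=0.15, S0=15.0)


def _feed_profile(t_h: np.ndarray, mode: int) -> np.ndarray:
    """Mode-dependent substrate feed (g/L/h), the stratum signature."""
    m = mode % 3
    if m == 0:  # recipe: constant feed after a lag
        feed = np.where(t_h >= 24.0, 0.62, 0.0)
    elif m == 1:  # operator: stepwise escalation
        feed = np.select(
            [t_h < 20.0, t_h < 0.45 * t_h.max(), t_h >= 0.45 * t_h.max()],
            [0.0, 0.42, 0.85],
        )
    else:  # advanced control: smooth ramp plus dither
        ramp = np.clip((t_h - 20.0) / 100.0, 0.0, 1.0)
        feed = 0.9 * ramp + 0.05 * np.sin(2 * np.pi * t_h / 40.0) * (t_h > 20.0)
    # higher mode indices reuse the base shapes with a gain offset
    return feed * (1.0 + 0.1 * (mode // 3))


def _integrate_latents(t_h: np.ndarray, feed: np.ndarray, kin: dict) -> dict[str, np.ndarray]:
    """Euler integration of the Monod-type fed-batch latents."""
    n = t_h.shape[0]
    dt = float(t_h[1] - t_h[0]) if n > 1 else 0.0
    X = np.empty(n)
    S = np.empty(n)
    P = np.empty(n)
    mu = np.empty(n)
    X[0], S[0], P[0] = kin["X0"], kin["S0"], 0.0
    for i in range(n):
        mu[i] = kin["mu_max"] * S[i] / (kin["Ks"] + S[i]) * max(0.0, 1.0 - X[i] / kin["Xmax"])
        if i + 1 == n:
            break
        dX = mu[i] * X[i]
        dS = -dX / kin["Yxs"] - kin["ms"] * X[i] + feed[i]
        dP = kin["kp"] * X[i] * S[i] / (kin["Kp"] + S[i])  # >= 0: product accumulates
        X[i + 1] = max(X[i] + dt * dX, 0.0)
        S[i + 1] = max(S[i] + dt * dS, 0.0)
        P[i + 1] = P[i] + dt * dP
    return {"X": X, "S": S, "P": P, "mu": mu}


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift a series by ``lag`` steps, holding the first value at the edge."""
    if lag <= 0:
        return x
    out = np.empty_like(x)
    out[:lag] = x[0]
    out[lag:] = x[:-lag]
    return out


# Observed-variable recipes: (name, lag steps, builder(latents, feed, t_h)).
# Channels deliberately differ in lag, nonlinearity and signal content; the
# last few are near-pure distractors.
_RECIPES: list[tuple[str, int, Callable[..., np.ndarray]]] = [
    ("feed_rate", 0, lambda L, feed, t: feed),
    ("substrate_conc", 0, lambda L, feed, t: L["S"]),
    ("dO2", 1, lambda L, feed, t: 100.0 - 9.0 * L["mu"] * L["X"] - 0.6 * L["X"]),
    ("offgas_co2", 2, lambda L, feed, t: 0.5 + 1.6 * L["mu"] * L["X"] + 0.09 * L["X"]),
    ("temperature", 0, lambda L, feed, t: 25.0 + 0.9 * np.tanh(0.12 * (L["X"] - 12.0))),
    ("pH", 3, lambda L, feed, t: 6.5 - 0.015 * L["X"] + 0.003 * L["S"]),
    ("biomass_probe", 2, lambda L, feed, t: L["X"] ** 0.95),
    # saturating rheology probe: recovering P requires inverting a 1-D nonlinearity
    ("viscosity", 5, lambda L, feed, t: 1.2 * np.sqrt(L["P"] + 0.1) + 0.02 * L["X"] ** 1.2),
    ("vessel_volume", 0, lambda L, feed, t: 80.0 + 0.04 * np.cumsum(feed) * (t[1] - t[0] if t.size > 1 else 0.0)),
    ("agitator_rpm", 0, lambda L, feed, t: 90.0 + 12.0 * np.tanh(0.08 * L["X"])),
    ("aeration_rate", 1, lambda L, feed, t: 60.0 + 1.4 * L["mu"] * L["X"]),
    ("pressure", 0, lambda L, feed, t: 1.2 + 0.02 * np.sin(t / 9.0)),
    ("base_flow", 2, lambda L, feed, t: 0.02 * L["X"] + 0.01 * L["mu"] * L["X"]),
    ("paa_flow", 0, lambda L, feed, t: 0.3 * feed + 0.02),
    ("offgas_o2", 2, lambda L, feed, t: 20.9 - 1.5 * L["mu"] * L["X"] - 0.08 * L["X"]),
    ("nh3_conc", 4, lambda L, feed, t: 1.8 - 0.02 * np.log1p(L["X"] * 2.0)),
    ("cooling_duty", 1, lambda L, feed, t: 0.1 + 0.6 * L["mu"] * L["X"]),
    ("turbidity", 1, lambda L, feed, t: np.log1p(3.0 * L["X"])),
]


def simulate_batch(cfg: SimConfig, batch_seed: int, mode: int, batch_id: str | None = None) -> ProcessBatch:
    """Generate one batch under the given control mode.

    With ``noise_sd = 0`` and ``batch_variability_sd = 0`` two batches of
    the same mode are identical regardless of ``batch_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(batch_seed)))
    t_min = np.arange(0.0, cfg.duration_h * 60.0 + 1e-9, cfg.process_dt_min)
    t_h = t_min / 60.0

    # batch-level random effects on the kinetics
    kin = dict(_KIN)
    for key in ("mu_max", "kp", "Yxs", "S0"):
        kin[key] = kin[key] * np.exp(cfg.batch_variability_sd * rng.standard_normal())
    feed_gain = np.exp(cfg.batch_variability_sd * rng.standard_normal())
    feed = feed_gain * _feed_profile(t_h, mode)

    latents = _integrate_latents(t_h, feed, kin)

    cols = []
    names = []
    noise_sd = np.broadcast_to(np.atleast_1d(np.asarray(cfg.noise_sd, dtype=float)),
                               (cfg.n_vars,))
    for j in range(cfg.n_vars):
        name, lag, builder = _RECIPES[j % len(_RECIPES)]
        if j >= len(_RECIPES):
            name = f"{name}_{j // len(_RECIPES)}"
        signal = _lagged(np.asarray(builder(latents, feed, t_h), dtype=float), lag)
        scale = float(np.std(signal))
        scale = scale if scale > 0 else max(abs(float(np.mean(signal))), 1.0)
        # batch-level sensor offset + high-frequency measurement noise
        signal = signal + cfg.batch_variability_sd * scale * rng.standard_normal()
        signal = signal + noise_sd[j] * scale * rng.standard_normal(signal.shape)
        cols.append(signal)
        names.append(name)
    process_vars = np.column_stack(cols)

    # sparse assays: the value logged at grid time t is the concentration of
    # the sample drawn assay_delay_h earlier
    quality = np.full(t_min.shape, np.nan)
    delay_steps = int(round(cfg.assay_delay_h * 60.0 / cfg.process_dt_min))
    assay_t_h = np.arange(0.0, cfg.duration_h + 1e-9, cfg.quality_dt_h)
    idx = np.round(assay_t_h * 60.0 / cfg.process_dt_min).astype(int)
    idx = idx[idx < t_min.shape[0]]
    src = np.maximum(idx - delay_steps, 0)
    quality[idx] = latents["P"][src] + cfg.assay_noise_sd * rng.standard_normal(idx.shape)

    return ProcessBatch(
        batch_id=batch_id or f"batch_{batch_seed}",
        timestamps=t_min,
        process_vars=process_vars,
        var_names=tuple(names),
        quality=quality,
        mode=mode,
        quality_true=latents["P"].copy(),
    )


def simulate_dataset(cfg: SimConfig) -> ProcessDataset:
    """Generate ``cfg.n_batches`` batches spread over the control modes.

    Modes are assigned in contiguous blocks (first third mode 0, etc.), and
    every batch seed derives from ``cfg.seed`` so the dataset is fully
    reproducible; the manifest records the per-batch seeds.
    """
    batches = []
    seeds = {}
    for b in range(cfg.n_batches):
        mode = b * cfg.control_modes // cfg.n_batches
        batch_seed = int(
            np.random.SeedSequence((cfg.seed, 100, b)).generate_state(1, dtype=np.uint64)[0]
        )
        batch_id = f"B{b:03d}"
        seeds[batch_id] = batch_seed
        batches.append(simulate_batch(cfg, batch_seed, mode, batch_id=batch_id))
    manifest = {
        "seed": cfg.seed,
        "batch_seeds": seeds,
        "n_batches": cfg.n_batches,
        "control_modes": cfg.control_modes,
    }
    return ProcessDataset(tuple(batches), manifest)
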