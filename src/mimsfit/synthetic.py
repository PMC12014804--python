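"""Forward simulation of TR-MIMS traces and variable-fluorescence decays.

The generator is the stand-in for raw instrument data: it produces traces with
known ground truth plus the noise and artifact structure the analysis has to
cope with — a residual-O2 step at the moment of H2(18)O injection, optional
first-order mixing of the injected label, additive Gaussian detector noise,
per-channel gain, and a pre-injection baseline.  Everything is seeded, so a
trace is reproducible bit-for-bit from its configuration.

What it does NOT emulate: membrane-inlet gas consumption, detector drift,
flash-lamp photophysics, or Kok-cycle miss/double-hit statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .isotope_model import (
    CorrectionFactors,
    EnrichmentSpec,
    ExchangeParams,
    FlashProtocol,
    fast_fraction_a,
    interflash_b,
)

__all__ = [
    "MimsSimConfig",
    "MimsTrace",
    "FluorDecayParams",
    "FluorTrace",
    "default_mims_time_grid",
    "default_fluorescence_time_grid",
    "simulate_mims",
    "simulate_fluorescence",
]


def default_mims_time_grid(
    injection_time: float = 1.0,
    t_min: float = 2e-3,
    t_max: float = 20.0,
    n_post: int = 64,
    n_baseline: int = 10,
) -> np.ndarray:
    """Log-spaced post-injection samples plus a linear pre-injection baseline.

    The default covers 2 ms–20 s after injection, resolving both a fast phase
    near 100 s^-1 and a slow phase near 1 s^-1.
    """
    if injection_time <= 0:
        raise ValueError("injection_time must be positive to fit a baseline before it")
    baseline = np.linspace(0.0, injection_time * 0.95, n_baseline)
    post = injection_time + np.geomspace(t_min, t_max, n_post)
    return np.concatenate([baseline, post])


@dataclass(frozen=True)
class MimsTrace:
    """Time-stamped m/z 34 / m/z 36 (optionally m/z 32) signal vectors.

    Times are in seconds on the instrument clock; ``injection_time`` marks the
    H2(18)O injection trigger on that clock.  ``meta`` carries provenance
    (enrichment, protocol, seed, ground truth when synthetic).
    """

    t: np.ndarray
    y34: np.ndarray
    y36: np.ndarray
    injection_time: float
    y32: Optional[np.ndarray] = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y34 = np.asarray(self.y34, dtype=float)
        y36 = np.asarray(self.y36, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y34", y34)
        object.__setattr__(self, "y36", y36)
        if self.y32 is not None:
            y32 = np.asarray(self.y32, dtype=float)
            object.__setattr__(self, "y32", y32)
            if y32.shape != t.shape:
                raise ValueError("y32 length differs from time vector")
        if y34.shape != t.shape or y36.shape != t.shape:
            raise ValueError("signal vectors must match the time vector length")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time vector must be 1-D with at least 2 samples")
        if np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"time vector must be strictly increasing (row {i})")
        for name, v in (("t", t), ("y34", y34), ("y36", y36)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_pre(self) -> int:
        """Number of samples strictly before the injection trigger."""
        return int(np.sum(self.t < self.injection_time))


@dataclass(frozen=True)
class MimsSimConfig:
    """Everything needed to forward-simulate one TR-MIMS experiment.

    Attributes
    ----------
    truth : ExchangeParams
        Generating exchange rates (the quantities a fit should recover).
    enrichment, protocol :
        Determine the amplitude factors a and b exactly as at fit time.
    time_grid : ndarray, optional
        Sampling times, s; defaults to :func:`default_mims_time_grid`.
    injection_time : float
        H2(18)O injection trigger, s.
    mixing_tau : float
        First-order time constant of the enrichment rise at injection, s.
        0 means an instantaneous step; ~0.006 s mimics the fast syringe
        injection when enabled.
    residual_o2_step : float
        Additive step on both channels at injection (dissolved O2 carried in
        with the injected water), signal units.
    noise_sigma : float
        SD of i.i.d. Gaussian detector noise per channel, signal units.
    scale_34, scale_36 : float
        Channel gains multiplying the unit-plateau kernels.
    seed : int
        Seed for the noise generator; recorded in the trace metadata.
    """

    truth: ExchangeParams
    enrichment: EnrichmentSpec
    protocol: FlashProtocol
    time_grid: Optional[np.ndarray] = None
    injection_time: float = 1.0
    mixing_tau: float = 0.0
    residual_o2_step: float = 0.0
    noise_sigma: float = 0.0
    scale_34: float = 1.0
    scale_36: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.mixing_tau < 0:
            raise ValueError("mixing_tau must be nonnegative")
        if self.injection_time < 0:
            raise ValueError("injection_time must be nonnegative")
        if self.scale_34 <= 0 or self.scale_36 <= 0:
            raise ValueError("channel scales must be positive")
        grid = (
            default_mims_time_grid(self.injection_time)
            if self.time_grid is None
            else np.asarray(self.time_grid, dtype=float)
        )
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be 1-D and strictly increasing")
        if grid[-1] <= self.injection_time:
            raise ValueError("time_grid must extend past injection_time")
        object.__setattr__(self, "time_grid", grid)


def _rise_with_mixing(k: float, t: np.ndarray, mixing_tau: float) -> np.ndarray:
    """Exchange rise 1-e^{-kt} driven by an enrichment step filtered at mixing_tau.

    Solves x' = k (alpha(t) - x) with alpha(t) = 1 - e^{-t/tau}:
    x(t) = 1 - (k e^{-mt} - m e^{-kt})/(k - m), m = 1/tau.  Degenerate k = m
    handled by the analytic limit 1 - e^{-kt}(1 + kt).
    """
    t = np.asarray(t, dtype=float)
    if mixing_tau == 0.0:
        return -np.expm1(-np.clip(k * t, 0.0, 700.0))
    m = 1.0 / mixing_tau
    if abs(k - m) < 1e-9 * max(k, m):
        kt = np.clip(k * t, 0.0, 700.0)
        return 1.0 - np.exp(-kt) * (1.0 + kt)
    ekt = np.exp(-np.clip(k * t, 0.0, 700.0))
    emt = np.exp(-np.clip(m * t, 0.0, 700.0))
    return 1.0 - (k * emt - m * ekt) / (k - m)


def simulate_mims(config: MimsSimConfig) -> MimsTrace:
    """Forward-simulate one TR-MIMS experiment.

    The noiseless kernel is zero before injection; after injection it is the
    per-channel gain times the unit-plateau labeling model (fast fraction a
    from the enrichments, inter-flash factor b from the protocol), optionally
    filtered by first-order mixing.  The residual-O2 step and Gaussian noise
    are then added.  With all artifact knobs at zero the output equals the
    analytic models exactly on the grid.
    """
    t = config.time_grid
    dt = t - config.injection_time
    post = dt >= 0.0

    a = fast_fraction_a(config.enrichment)
    b = interflash_b(config.protocol)
    k_f, k_s = config.truth.k_f, config.truth.k_s

    y34 = np.zeros_like(t)
    y36 = np.zeros_like(t)
    tp = dt[post]
    if config.mixing_tau == 0.0:
        fast = 1.0 - b * np.exp(-np.clip(k_f * tp, 0.0, 700.0))
    else:
        # the b-reduced fast amplitude mixes like the rest of the fast phase
        fast = 1.0 - b + b * _rise_with_mixing(k_f, tp, config.mixing_tau)
    slow = _rise_with_mixing(k_s, tp, config.mixing_tau)
    y34[post] = config.scale_34 * (a * fast + (1.0 - a) * slow)
    y36[post] = config.scale_36 * slow

    if config.residual_o2_step:
        y34[post] += config.residual_o2_step
        y36[post] += config.residual_o2_step

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        y34 = y34 + rng.normal(0.0, config.noise_sigma, t.size)
        y36 = y36 + rng.normal(0.0, config.noise_sigma, t.size)

    meta = {
        "synthetic": True,
        "seed": config.seed,
        "truth_k_f": k_f,
        "truth_k_s": k_s,
        "alpha_i": config.enrichment.alpha_i,
        "alpha_f": config.enrichment.alpha_f,
        "probed_state": config.protocol.probed_state.value,
        "flash_frequency": config.protocol.flash_frequency,
        "t_s3": config.protocol.t_s3,
        "k_f_s3": config.protocol.k_f_s3,
        "mixing_tau": config.mixing_tau,
        "residual_o2_step": config.residual_o2_step,
        "noise_sigma": config.noise_sigma,
        "scale_34": config.scale_34,
        "scale_36": config.scale_36,
    }
    return MimsTrace(
        t=t, y34=y34, y36=y36, injection_time=config.injection_time, meta=meta
    )


# --------------------------------------------------------------------------
# Variable fluorescence


@dataclass(frozen=True)
class FluorDecayParams:
    """Three-component exponential decay of normalized variable fluorescence.

    F(t) = A0 + A1 e^{-t/tau1} + A2 e^{-t/tau2} + A3 e^{-t/tau3},
    with tau1 < tau2 < tau3 (fast / middle / slow recombination phases) and a
    non-decaying offset A0.
    """

    a0: float
    a1: float
    a2: float
    a3: float
    tau1: float
    tau2: float
    tau3: float

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "a2", "a3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        taus = (self.tau1, self.tau2, self.tau3)
        if any(tau <= 0 for tau in taus):
            raise ValueError("time constants must be positive")
        if not (self.tau1 < self.tau2 < self.tau3):
            raise ValueError(
                f"time constants must be strictly ordered, got {taus}"
            )

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])

    @property
    def taus(self) -> np.ndarray:
        return np.array([self.tau1, self.tau2, self.tau3])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.a0, dtype=float)
        for amp, tau in zip(self.amplitudes, self.taus):
            out += amp * np.exp(-np.clip(t / tau, 0.0, 700.0))
        return out


@dataclass(frozen=True)
class FluorTrace:
    """A (normalized) variable-fluorescence decay time series.

    ``fv`` holds the normalized variable fluorescence when ``f0``/``fmax`` are
    absent, or the raw yield to be normalized via (F - F0)/(Fmax - F0).
    """

    t: np.ndarray
    fv: np.ndarray
    f0: Optional[float] = None
    fmax: Optional[float] = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        fv = np.asarray(self.fv, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "fv", fv)
        if fv.shape != t.shape or t.ndim != 1:
            raise ValueError("fv must be 1-D and match the time vector length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(fv))):
            raise ValueError("non-finite values in fluorescence trace")
        if self.f0 is not None and self.fmax is not None and self.fmax <= self.f0:
            raise ValueError(f"fmax ({self.fmax}) must exceed f0 ({self.f0})")


def default_fluorescence_time_grid(
    t_min: float = 150e-6, t_max: float = 100.0, points_per_decade: int = 8
) -> np.ndarray:
    """Logarithmic measuring-flash grid (default 150 us – 100 s, 8 per decade)."""
    n_decades = math.log10(t_max / t_min)
    n = max(2, int(round(n_decades * points_per_decade)) + 1)
    return np.geomspace(t_min, t_max, n)


def simulate_fluorescence(
    params: FluorDecayParams,
    time_grid: Optional[np.ndarray] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> FluorTrace:
    """Simulate a normalized variable-fluorescence decay with Gaussian noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    t = (
        default_fluorescence_time_grid()
        if time_grid is None
        else np.asarray(time_grid, dtype=float)
    )
    fv = params(t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        fv = fv + rng.normal(0.0, noise_sigma, t.size)
    meta = {
        "synthetic": True,
        "seed": seed,
        "noise_sigma": noise_sigma,
        "truth": {
            "a0": params.a0,
            "a1": params.a1,
            "a2": params.a2,
            "a3": params.a3,
            "tau1": params.tau1,
            "tau2": params.tau2,
            "tau3": params.tau3,
        },
    }
    return FluorTrace(t=t, fv=fv, meta=meta)
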