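"""Preprocessing and global fitting of TR-MIMS isotope-exchange traces.

The m/z 34 and m/z 36 channels are fitted jointly: the slow rate k_s is a
single shared parameter (the m/z 36 rise is constrained by W_s exchange
alone), k_f shapes the fast phase of m/z 34, and each channel carries a free
positive gain.  The fast-phase amplitude ``a`` is computed from the isotope
enrichments and the inter-flash factor ``b`` from the flash protocol; both can
be floated or disabled for sensitivity analysis.  Parameter uncertainties come
from a delete-one jackknife over time points (the i-th sample removed from
both channels simultaneously, preserving the global-fit structure).

Rates are fitted on a log scale with the ordering k_f > k_s enforced by
parameterization: k_s = exp(x0), k_f = k_s * (1 + exp(x1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .isotope_model import (
    RATE_MAX,
    RATE_MIN,
    EnrichmentSpec,
    ExchangeParams,
    FlashProtocol,
    fast_fraction_a,
    interflash_b,
)
from .synthetic import MimsTrace, _rise_with_mixing

__all__ = ["FitConfig", "FitResult", "preprocess", "global_fit", "jackknife_errors"]

_LOG_RATE_LO, _LOG_RATE_HI = math.log(RATE_MIN), math.log(RATE_MAX)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the global biexponential exchange fit.

    ``fix_a_from_enrichment`` / ``fix_b_from_protocol`` pin the amplitude
    factors to their analytic values; with ``fix_b_from_protocol=False`` the
    fit proceeds with b = 1 (no inter-flash correction).  ``mixing_correction``
    replaces each exponential rise by its first-order-mixing-filtered form with
    time constant ``mixing_tau``.
    """

    enrichment: EnrichmentSpec
    protocol: FlashProtocol
    fix_a_from_enrichment: bool = True
    fix_b_from_protocol: bool = True
    weighting: str = "uniform"  # or "inverse_variance"
    init_strategy: str = "loglinear"  # or "grid"
    k_bounds: Tuple[float, float] = (RATE_MIN, RATE_MAX)
    mixing_correction: bool = False
    mixing_tau: float = 0.006

    def __post_init__(self) -> None:
        lo, hi = self.k_bounds
        if not (0 < lo < hi):
            raise ValueError(f"k_bounds must be positive and ordered, got {self.k_bounds}")
        if self.weighting not in ("uniform", "inverse_variance"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.init_strategy not in ("loglinear", "grid"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")
        if self.mixing_correction and self.mixing_tau <= 0:
            raise ValueError("mixing_correction requires mixing_tau > 0")


@dataclass
class FitResult:
    """Converged estimates of a global exchange fit plus diagnostics.

    ``std_errors`` is empty until :func:`jackknife_errors` fills it; every
    estimate then carries a jackknife SE.  ``jackknife_replicates`` holds the
    per-replicate parameter table for diagnostic plotting of the resampling
    distribution.
    """

    estimates: ExchangeParams
    scale_34: float
    scale_36: float
    a: float
    b: float
    a_fixed: bool
    converged: bool
    cost: float
    n_points: int
    residuals_34: np.ndarray
    residuals_36: np.ndarray
    std_errors: Dict[str, float] = field(default_factory=dict)
    se_reliable: Optional[bool] = None
    jackknife_replicates: Optional[Dict[str, np.ndarray]] = None
    warnings: List[str] = field(default_factory=list)
    degenerate: bool = False
    monophasic_alternative: Optional[Dict[str, float]] = None

    def param_dict(self) -> Dict[str, float]:
        d = {
            "k_f": self.estimates.k_f,
            "k_s": self.estimates.k_s,
            "scale_34": self.scale_34,
            "scale_36": self.scale_36,
        }
        if not self.a_fixed:
            d["a"] = self.a
        return d


def preprocess(
    raw: MimsTrace,
    residual_estimate: Union[str, Tuple[float, float], None] = "auto",
) -> MimsTrace:
    """Baseline-subtract, remove the residual-O2 injection step, re-zero time.

    The mean of the pre-injection samples is subtracted per channel.  The
    residual-O2 step (dissolved O2 carried in with the injected water) is then
    removed: in ``"auto"`` mode it is estimated per channel from the
    discontinuity between the last pre-injection and first post-injection
    samples after baseline removal.  When probing S2 the labeling kernel
    itself jumps to a(1-b) at injection; if the trace metadata carries the
    enrichments and protocol, that model discontinuity is accounted for
    (plateau estimated from the trace tail), so only the artifact is removed.
    The estimate is adequate when the first post-injection sample sits within
    a small fraction of 1/k_f of the injection; otherwise pass explicit
    per-channel amplitudes ``(step34, step36)``, or ``None`` to skip removal.
    Time is re-zeroed so the injection trigger is at t = 0 (pre-injection
    samples keep negative times).  Channels are NOT rescaled: the fit carries
    free gain parameters.
    """
    n_pre = raw.n_pre
    if residual_estimate == "auto" and n_pre < 3:
        raise ValueError(
            "auto residual-O2 estimation needs >=3 pre-injection baseline samples"
        )
    if n_pre < 1:
        raise ValueError("trace has no pre-injection baseline samples")

    t = raw.t - raw.injection_time
    pre = t < 0.0
    post = ~pre
    y34 = raw.y34 - raw.y34[pre].mean()
    y36 = raw.y36 - raw.y36[pre].mean()
    noise34 = float(np.std(raw.y34[pre], ddof=1)) if n_pre > 1 else 0.0
    noise36 = float(np.std(raw.y36[pre], ddof=1)) if n_pre > 1 else 0.0

    if residual_estimate == "auto":
        jump34 = _model_jump_at_injection(raw.meta)
        d34 = float(y34[post][0] - y34[pre][-1])
        step36 = float(y36[post][0] - y36[pre][-1])
        if jump34 > 0.0:
            tail = max(3, int(post.sum()) // 10)
            plateau34 = float(np.mean(y34[post][-tail:]))
            step34 = (d34 - jump34 * plateau34) / (1.0 - jump34)
        else:
            step34 = d34
    elif residual_estimate is None:
        step34 = step36 = 0.0
    else:
        step34, step36 = map(float, residual_estimate)
    y34 = y34 - np.where(post, step34, 0.0)
    y36 = y36 - np.where(post, step36, 0.0)

    meta = dict(raw.meta)
    meta.update(
        preprocessed=True,
        residual_step_34=step34,
        residual_step_36=step36,
        baseline_noise_34=noise34,
        baseline_noise_36=noise36,
    )
    y32 = None
    if raw.y32 is not None:
        y32 = raw.y32 - raw.y32[pre].mean()
    return MimsTrace(t=t, y34=y34, y36=y36, y32=y32, injection_time=0.0, meta=meta)


def _model_jump_at_injection(meta: Dict) -> float:
    """Unit-plateau m/z 34 kernel value at t = 0+, a(1-b), from trace metadata.

    Nonzero only when probing S2 with an inter-flash correction.  Returns 0
    when the metadata lacks enrichment/protocol provenance (the b = 1 case is
    then assumed).
    """
    try:
        alpha_i, alpha_f = meta["alpha_i"], meta["alpha_f"]
        state = meta["probed_state"]
        if alpha_i is None or alpha_f is None or state is None:
            return 0.0
        a = fast_fraction_a(EnrichmentSpec(alpha_i=alpha_i, alpha_f=alpha_f))
        b = interflash_b(
            FlashProtocol(
                probed_state=state,
                flash_frequency=meta.get("flash_frequency") or 100.0,
                t_s3=meta.get("t_s3"),
                k_f_s3=meta.get("k_f_s3"),
            )
        )
        return a * (1.0 - b)
    except (KeyError, ValueError):
        return 0.0


def _rise(k: float, t: np.ndarray, config: FitConfig) -> np.ndarray:
    if config.mixing_correction:
        return _rise_with_mixing(k, t, config.mixing_tau)
    return -np.expm1(-np.clip(k * t, 0.0, 700.0))


def _model_channels(
    theta: np.ndarray, t: np.ndarray, config: FitConfig, a_fixed: Optional[float], b: float
) -> Tuple[np.ndarray, np.ndarray]:
    k_s = math.exp(theta[0])
    k_f = k_s * (1.0 + math.exp(theta[1]))
    s34, s36 = math.exp(theta[2]), math.exp(theta[3])
    a = a_fixed if a_fixed is not None else 1.0 / (1.0 + math.exp(-theta[4]))
    fast = 1.0 - b + b * _rise(k_f, t, config)
    slow = _rise(k_s, t, config)
    return s34 * (a * fast + (1.0 - a) * slow), s36 * slow


def _unpack(theta: np.ndarray, a_fixed: Optional[float]) -> Dict[str, float]:
    k_s = math.exp(theta[0])
    out = {
        "k_s": k_s,
        "k_f": k_s * (1.0 + math.exp(theta[1])),
        "scale_34": math.exp(theta[2]),
        "scale_36": math.exp(theta[3]),
    }
    if a_fixed is None:
        out["a"] = 1.0 / (1.0 + math.exp(-theta[4]))
    return out


def _initial_guess(
    t: np.ndarray, y34: np.ndarray, y36: np.ndarray, a: float, b: float,
    config: FitConfig,
) -> List[float]:
    """Two-segment log-linear heuristic: late window -> k_s, early window -> k_f."""
    tail = max(3, t.size // 10)
    s36_0 = max(float(np.mean(y36[-tail:])), 1e-12)
    s34_0 = max(float(np.mean(y34[-tail:])), 1e-12)

    # slow rate from the half-rise time of the monophasic channel
    half = np.flatnonzero(y36 >= 0.5 * s36_0)
    k_s0 = math.log(2.0) / t[half[0]] if half.size and t[half[0]] > 0 else 1.0

    # fast rate from the half-rise of the fast component of m/z 34
    slow_part = (1.0 - a) * (-np.expm1(-k_s0 * t))
    yf = y34 / s34_0 - slow_part
    target = a * (1.0 - 0.5 * b)
    cross = np.flatnonzero(yf >= target)
    if cross.size and t[cross[0]] > 0:
        k_f0 = max(math.log(2.0) / t[cross[0]], 2.0 * k_s0)
    else:
        k_f0 = 50.0 * k_s0

    lo, hi = config.k_bounds
    k_s0 = min(max(k_s0, lo * 1.01), hi * 0.99)
    k_f0 = min(max(k_f0, k_s0 * 1.5), hi * 0.99)
    return [
        math.log(k_s0),
        math.log(k_f0 / k_s0 - 1.0),
        math.log(s34_0),
        math.log(s36_0),
    ]


def global_fit(trace: MimsTrace, config: FitConfig) -> FitResult:
    """Globally fit the m/z 34 and m/z 36 channels with a shared slow rate.

    Minimizes the (optionally inverse-variance weighted) sum of squared
    residuals of both channels against the unit-plateau labeling models times
    per-channel gains.  Non-convergence is reported via the ``converged`` flag,
    never raised.  If the fitted rate contrast k_f/k_s falls below 2 the
    result is flagged degenerate and a monophasic comparison fit (a single
    shared rate) is attached — the model choice is reported, never swapped.
    """
    t_rel = trace.t - trace.injection_time
    post = t_rel >= 0.0
    t = t_rel[post]
    y34 = trace.y34[post]
    y36 = trace.y36[post]
    if t.size < 8:
        raise ValueError(f"need >=8 post-injection samples per channel, got {t.size}")

    a_fixed: Optional[float]
    a_fixed = fast_fraction_a(config.enrichment) if config.fix_a_from_enrichment else None
    b = interflash_b(config.protocol) if config.fix_b_from_protocol else 1.0

    w34 = w36 = 1.0
    if config.weighting == "inverse_variance":
        n34 = float(trace.meta.get("baseline_noise_34", 0.0) or 0.0)
        n36 = float(trace.meta.get("baseline_noise_36", 0.0) or 0.0)
        if n34 > 0 and n36 > 0:
            w34, w36 = 1.0 / n34, 1.0 / n36

    def residuals(theta: np.ndarray) -> np.ndarray:
        m34, m36 = _model_channels(theta, t, config, a_fixed, b)
        return np.concatenate([w34 * (y34 - m34), w36 * (y36 - m36)])

    a_for_init = a_fixed if a_fixed is not None else 0.5
    x0 = _initial_guess(t, y34, y36, a_for_init, b, config)
    if a_fixed is None:
        x0 = x0 + [0.0]  # logit(a) = 0 -> a = 0.5

    lo_k, hi_k = config.k_bounds
    lower = [math.log(lo_k), -20.0, -30.0, -30.0]
    upper = [math.log(hi_k), 25.0, 30.0, 30.0]
    if a_fixed is None:
        lower.append(-12.0)
        upper.append(12.0)

    starts = [x0]
    if config.init_strategy == "grid":
        for mult in (0.1, 10.0, 100.0):
            alt = list(x0)
            alt[1] = min(max(alt[1] + math.log(mult), lower[1] + 1e-6), upper[1] - 1e-6)
            starts.append(alt)

    best = None
    for start in starts:
        start = np.clip(start, np.array(lower) + 1e-9, np.array(upper) - 1e-9)
        try:
            sol = least_squares(
                residuals, start, bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        est = _unpack(np.asarray(x0), a_fixed)
        return FitResult(
            estimates=ExchangeParams(est["k_f"], est["k_s"]),
            scale_34=est["scale_34"], scale_36=est["scale_36"],
            a=est.get("a", a_for_init), b=b, a_fixed=a_fixed is not None,
            converged=False, cost=math.inf, n_points=t.size,
            residuals_34=np.full_like(t, np.nan), residuals_36=np.full_like(t, np.nan),
            warnings=["optimizer failed to evaluate"],
        )

    est = _unpack(best.x, a_fixed)
    k_f, k_s = est["k_f"], est["k_s"]
    m34, m36 = _model_channels(best.x, t, config, a_fixed, b)
    warn: List[str] = []
    if k_f > 0.98 * hi_k or k_s < 1.02 * lo_k:
        warn.append("a rate estimate sits at its bound; result unreliable")
    converged = bool(best.success) and not math.isinf(best.cost)

    degenerate = k_f / k_s < 2.0
    mono = None
    if degenerate:
        warn.append(
            f"rate contrast k_f/k_s = {k_f / k_s:.2f} < 2: biphasic model weakly "
            "identified; monophasic comparison fit attached"
        )
        mono = _monophasic_fit(t, y34, y36, (w34, w36), config)

    result = FitResult(
        estimates=ExchangeParams(k_f=k_f, k_s=k_s),
        scale_34=est["scale_34"], scale_36=est["scale_36"],
        a=est.get("a", a_for_init), b=b, a_fixed=a_fixed is not None,
        converged=converged, cost=float(best.cost), n_points=int(t.size),
        residuals_34=y34 - m34, residuals_36=y36 - m36,
        warnings=warn, degenerate=degenerate, monophasic_alternative=mono,
    )
    result._theta = best.x  # warm start for jackknife replicates
    return result


def _monophasic_fit(
    t: np.ndarray, y34: np.ndarray, y36: np.ndarray,
    weights: Tuple[float, float], config: FitConfig,
) -> Dict[str, float]:
    """Single shared-rate comparison model: y_ch = s_ch (1 - e^{-k t})."""
    w34, w36 = weights

    def res(theta: np.ndarray) -> np.ndarray:
        k = math.exp(theta[0])
        rise = _rise(k, t, config)
        return np.concatenate(
            [w34 * (y34 - math.exp(theta[1]) * rise), w36 * (y36 - math.exp(theta[2]) * rise)]
        )

    tail = max(3, t.size // 10)
    x0 = [0.0, math.log(max(np.mean(y34[-tail:]), 1e-12)),
          math.log(max(np.mean(y36[-tail:]), 1e-12))]
    sol = least_squares(res, x0, method="lm", max_nfev=2000)
    return {
        "k": math.exp(sol.x[0]),
        "scale_34": math.exp(sol.x[1]),
        "scale_36": math.exp(sol.x[2]),
        "cost": float(sol.cost),
        "converged": bool(sol.success),
    }


def jackknife_errors(
    trace: MimsTrace, config: FitConfig, base: FitResult
) -> FitResult:
    """Delete-one jackknife standard errors for the global-fit parameters.

    Each replicate removes the i-th post-injection time point from both
    channels simultaneously and refits starting from the base estimates.  The
    SE of each parameter is sqrt[(n-1)/n * sum_i (theta_(i) - theta_bar)^2].
    If more than 20% of replicates fail to converge the SEs are flagged
    unreliable.  The replicate parameter table is attached for diagnostic
    plots of the resampling distribution.
    """
    if not base.converged:
        raise ValueError("jackknife requires a converged base fit")
    t_rel = trace.t - trace.injection_time
    post = t_rel >= 0.0
    t = t_rel[post]
    y34 = trace.y34[post]
    y36 = trace.y36[post]
    n = t.size
    if n < 10:
        raise ValueError(f"jackknife needs >=10 post-injection points, got {n}")

    a_fixed = fast_fraction_a(config.enrichment) if config.fix_a_from_enrichment else None
    b = base.b
    w34 = w36 = 1.0
    if config.weighting == "inverse_variance":
        n34 = float(trace.meta.get("baseline_noise_34", 0.0) or 0.0)
        n36 = float(trace.meta.get("baseline_noise_36", 0.0) or 0.0)
        if n34 > 0 and n36 > 0:
            w34, w36 = 1.0 / n34, 1.0 / n36

    theta0 = getattr(base, "_theta", None)
    if theta0 is None:
        raise ValueError("base fit does not carry optimizer state; rerun global_fit")

    lo_k, hi_k = config.k_bounds
    lower = [math.log(lo_k), -20.0, -30.0, -30.0]
    upper = [math.log(hi_k), 25.0, 30.0, 30.0]
    if a_fixed is None:
        lower.append(-12.0)
        upper.append(12.0)

    names = list(base.param_dict().keys())
    reps: Dict[str, List[float]] = {k: [] for k in names}
    failures = 0
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[:] = True
        keep[i] = False
        ti, y34i, y36i = t[keep], y34[keep], y36[keep]

        def res(theta: np.ndarray) -> np.ndarray:
            m34, m36 = _model_channels(theta, ti, config, a_fixed, b)
            return np.concatenate([w34 * (y34i - m34), w36 * (y36i - m36)])

        sol = least_squares(
            res, np.clip(theta0, np.array(lower) + 1e-9, np.array(upper) - 1e-9),
            bounds=(lower, upper), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=500,
        )
        if not sol.success:
            failures += 1
            continue
        est = _unpack(sol.x, a_fixed)
        for k in names:
            reps[k].append(est[k])

    n_ok = n - failures
    se: Dict[str, float] = {}
    replicates = {k: np.asarray(v) for k, v in reps.items()}
    if n_ok >= 2:
        for k, vals in replicates.items():
            mean = vals.mean()
            se[k] = math.sqrt((n_ok - 1) / n_ok * float(np.sum((vals - mean) ** 2)))
    reliable = failures <= 0.2 * n and n_ok >= 2

    out = replace(base)
    out.std_errors = se
    out.se_reliable = reliable
    out.jackknife_replicates = replicates
    if not reliable:
        out.warnings = base.warnings + [
            f"jackknife: {failures}/{n} replicates failed to converge; SEs unreliable"
        ]
    out._theta = theta0
    return out
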