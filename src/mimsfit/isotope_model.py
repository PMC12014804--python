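"""Closed-form forward model of flash-induced O2 isotopologue labeling kinetics.

After a rapid jump of the H2(18)O enrichment of the medium, the O2 evolved by
Photosystem II on a turnover flash reports how far the two bound substrate
waters (the fast-exchanging W_f and the slow-exchanging W_s) have isotopically
equilibrated with the bulk.  The single-labeled product ((18)O(16)O, m/z 34)
rises biphasically with rate constants k_f and k_s; the double-labeled product
((18)O(18)O, m/z 36) rises monophasically with k_s alone, because a doubly
labeled O2 requires the slow site to have exchanged.

Two amplitude factors enter the m/z 34 kinetics:

``a``
    the fraction of the m/z 34 plateau carried by the fast phase.  It follows
    from isotopologue statistics: each O2 draws one oxygen from each substrate
    site, so the single-label probability with one site equilibrated at the
    final enrichment alpha_f and the other still at the initial alpha_i,
    normalized by the fully equilibrated single-label probability
    2*alpha_f*(1-alpha_f).

``b``
    an inter-flash correction used when probing the S2 state: during the dwell
    in S3 between turnover flashes (10 ms at 100 Hz) the fast site already
    exchanges with rate k_f^S3, which removes part of the unexchanged fast-phase
    amplitude.  b = exp(-k_f^S3 * t_S3); for measurements probing S3 itself,
    b = 1.

All model functions are normalized to a unit plateau; instrument gain is a
separate scale parameter handled at fit time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "SState",
    "ExchangeParams",
    "EnrichmentSpec",
    "FlashProtocol",
    "CorrectionFactors",
    "isotopologue_fractions",
    "fast_fraction_a",
    "interflash_b",
    "mz34_model",
    "mz36_model",
    "RATE_MIN",
    "RATE_MAX",
]

# Rate bounds used in fitting contexts (s^-1); generous but keeps the
# optimizer away from overflow in exp().
RATE_MIN = 1e-6
RATE_MAX = 1e6


class SState(str, Enum):
    """Kok-cycle state probed by the flash protocol (only S2 and S3 resolve W_f)."""

    S2 = "S2"
    S3 = "S3"


@dataclass(frozen=True)
class ExchangeParams:
    """Substrate water exchange rate constants.

    Attributes
    ----------
    k_f : float
        Fast-exchanging substrate water (W_f) rate constant, s^-1.
    k_s : float
        Slow-exchanging substrate water (W_s) rate constant, s^-1.
    """

    k_f: float
    k_s: float

    def __post_init__(self) -> None:
        if not (self.k_f > 0 and math.isfinite(self.k_f)):
            raise ValueError(f"k_f must be positive and finite, got {self.k_f}")
        if not (self.k_s > 0 and math.isfinite(self.k_s)):
            raise ValueError(f"k_s must be positive and finite, got {self.k_s}")


@dataclass(frozen=True)
class EnrichmentSpec:
    """Initial and final (18)O enrichment of the water pool, as fractions.

    alpha_i is the enrichment before injection (natural abundance or a
    measured baseline, ~0.0007); alpha_f the enrichment after the H2(18)O
    injection (~0.13 in the typical protocol).
    """

    alpha_i: float
    alpha_f: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_i < 1.0):
            raise ValueError(f"alpha_i must lie in [0, 1), got {self.alpha_i}")
        if not (0.0 < self.alpha_f < 1.0):
            raise ValueError(f"alpha_f must lie in (0, 1), got {self.alpha_f}")
        if self.alpha_i > self.alpha_f:
            raise ValueError(
                f"alpha_i ({self.alpha_i}) must not exceed alpha_f ({self.alpha_f})"
            )


@dataclass(frozen=True)
class FlashProtocol:
    """Flash-sequence metadata needed to evaluate the inter-flash correction.

    Attributes
    ----------
    probed_state : SState
        S-state whose substrate exchange the measurement probes.
    flash_frequency : float
        Turnover flash frequency, Hz.
    t_s3 : float, optional
        Dwell time spent in S3 per turnover cycle, s.  Defaults to one flash
        period (10 ms at 100 Hz).
    k_f_s3 : float, optional
        Fast exchange rate in S3 (s^-1) used for the b-correction; required
        only when probing S2.
    """

    probed_state: SState
    flash_frequency: float = 100.0
    t_s3: Optional[float] = None
    k_f_s3: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "probed_state", SState(self.probed_state))
        if not self.flash_frequency > 0:
            raise ValueError(
                f"flash_frequency must be positive, got {self.flash_frequency}"
            )
        if self.t_s3 is None:
            object.__setattr__(self, "t_s3", 1.0 / self.flash_frequency)
        if self.t_s3 < 0:
            raise ValueError(f"t_s3 must be nonnegative, got {self.t_s3}")
        if self.k_f_s3 is not None and not self.k_f_s3 > 0:
            raise ValueError(f"k_f_s3 must be positive, got {self.k_f_s3}")


@dataclass(frozen=True)
class CorrectionFactors:
    """Amplitude factors of the m/z 34 model: fast fraction a, inter-flash b."""

    a: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.a <= 1.0):
            raise ValueError(f"a must lie in (0, 1], got {self.a}")
        if not (0.0 < self.b <= 1.0):
            raise ValueError(f"b must lie in (0, 1], got {self.b}")


def isotopologue_fractions(
    alpha_site1: float, alpha_site2: float
) -> Tuple[float, float, float]:
    """O2 isotopologue probabilities when each oxygen comes from one substrate site.

    Site ``i`` contributes an (18)O with probability ``alpha_site_i``,
    independently.  Returns ``(f32, f34, f36)``; the three fractions sum to 1
    exactly.  This enumeration is the combinatorial basis of the fast-phase
    amplitude factor ``a``.
    """
    for name, alpha in (("alpha_site1", alpha_site1), ("alpha_site2", alpha_site2)):
        if not (0.0 <= alpha <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {alpha}")
    f36 = alpha_site1 * alpha_site2
    f32 = (1.0 - alpha_site1) * (1.0 - alpha_site2)
    f34 = alpha_site1 * (1.0 - alpha_site2) + (1.0 - alpha_site1) * alpha_site2
    return f32, f34, f36


def fast_fraction_a(enrichment: EnrichmentSpec) -> float:
    """Fast-phase fractional amplitude of the m/z 34 rise.

    a = [alpha_f(1-alpha_i) + (1-alpha_f)alpha_i] / [2 alpha_f (1-alpha_f)]

    i.e. the single-label probability with the fast site equilibrated at
    alpha_f and the slow site still at alpha_i, normalized by the single-label
    probability with both sites at alpha_f.  Lies in (0, 1] for
    alpha_i < alpha_f <= 0.5.
    """
    a_i, a_f = enrichment.alpha_i, enrichment.alpha_f
    denom = 2.0 * a_f * (1.0 - a_f)
    if denom == 0.0:  # unreachable through EnrichmentSpec, kept for raw floats
        raise ValueError(f"alpha_f = {a_f} makes the single-label plateau vanish")
    return (a_f * (1.0 - a_i) + (1.0 - a_f) * a_i) / denom


def interflash_b(protocol: FlashProtocol) -> float:
    """Inter-flash fast-exchange correction factor b.

    Probing S3: no correction is needed, b = 1 exactly.  Probing S2: the fast
    site exchanges with rate k_f^S3 during the dwell t_S3 spent in S3 between
    turnover flashes, so the surviving unexchanged fast amplitude is
    b = exp(-k_f^S3 * t_S3).
    """
    if protocol.probed_state is SState.S3:
        return 1.0
    if protocol.t_s3 == 0.0:
        return 1.0
    if protocol.k_f_s3 is None:
        raise ValueError(
            "probing S2 requires k_f_s3 (fast exchange rate in S3) "
            "to evaluate the inter-flash correction"
        )
    return math.exp(-protocol.k_f_s3 * protocol.t_s3)


def _stable_rise(k: float, t: np.ndarray) -> np.ndarray:
    """1 - exp(-k t) evaluated without overflow for large k*t."""
    kt = np.clip(k * np.asarray(t, dtype=float), 0.0, 700.0)
    return -np.expm1(-kt)


def mz34_model(
    t: np.ndarray, params: ExchangeParams, corrections: CorrectionFactors
) -> np.ndarray:
    """Unit-plateau m/z 34 ((18)O(16)O) labeling kinetics.

    y(t) = a (1 - b e^{-k_f t}) + (1-a)(1 - e^{-k_s t})

    Biphasic rise; y(0) = a(1-b), y(inf) = 1, nondecreasing in t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time values must be nonnegative")
    a, b = corrections.a, corrections.b
    fast = 1.0 - b * np.exp(-np.clip(params.k_f * t, 0.0, 700.0))
    slow = _stable_rise(params.k_s, t)
    return a * fast + (1.0 - a) * slow


def mz36_model(
    t: np.ndarray, params: ExchangeParams, gated_by_fast: bool = False
) -> np.ndarray:
    """Unit-plateau m/z 36 ((18)O(18)O) labeling kinetics.

    The double-labeled product requires the slow site to have exchanged, so the
    standard model is the monophasic rise 1 - e^{-k_s t}.  With
    ``gated_by_fast=True`` the alternative product form
    (1 - e^{-k_f t})(1 - e^{-k_s t}) — both sites must have exchanged — is
    returned for sensitivity analysis; it is nearly indistinguishable whenever
    k_f >> k_s.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time values must be nonnegative")
    slow = _stable_rise(params.k_s, t)
    if gated_by_fast:
        return _stable_rise(params.k_f, t) * slow
    return slow
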