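"""Closed-form two-compartment disposition kinetics under piecewise-constant infusion.

The drug amount in the central (A1) and peripheral (A2) compartments obeys

    dA1/dt = rate_in(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2

with k10 = CL/V1, k12 = Q/V1, k21 = Q/V2.  The plasma concentration C = A1/V1
is a sum of two exponentials with hybrid rate constants lambda_fast/lambda_slow
(the classical alpha/beta).  Because the system is linear and time-invariant,
an arbitrary regimen of constant-rate infusion segments is handled exactly by
superposition: each segment contributes its own analytic rise/decay term, and
switching an infusion off is equivalent to superposing a negative-rate infusion.

Units are fixed package-wide: amounts mg, rates mg/h, times h, volumes L,
clearances L/h.  Concentrations are returned in ng/mL; the single mg/L -> ng/mL
scale factor (x1000) lives in :func:`concentration` and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PKParameters",
    "HybridConstants",
    "DoseEvent",
    "Regimen",
    "micro_constants",
    "concentration",
    "time_to_css_fraction",
]

#: Relative gap below which the two hybrid roots are treated as degenerate.
_DEGENERATE_GAP = 1e-8


@dataclass(frozen=True)
class PKParameters:
    """Disposition parameters of one individual (or the population typical value).

    Attributes
    ----------
    cl : float
        Elimination clearance from the central compartment, L/h.
    v1 : float
        Central volume of distribution, L.
    q : float
        Inter-compartmental (distributional) clearance, L/h.
    v2 : float
        Peripheral volume of distribution, L.
    """

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0.0):
                raise ValueError(
                    f"PK parameter {name!r} must be finite and > 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.cl, self.v1, self.q, self.v2], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PKParameters":
        cl, v1, q, v2 = (float(x) for x in arr)
        return cls(cl, v1, q, v2)


@dataclass(frozen=True)
class HybridConstants:
    """Micro rate constants and hybrid (distribution/terminal) exponents, 1/h.

    ``lambda_fast``/``lambda_slow`` are the classical alpha/beta exponents,
    renamed to avoid collision with the statistical significance level.
    """

    k10: float
    k12: float
    k21: float
    lambda_fast: float
    lambda_slow: float
    t_half_fast: float
    t_half_slow: float


@dataclass(frozen=True)
class DoseEvent:
    """One constant-rate infusion segment.

    A bolus-style loading dose is represented as a 1-minute infusion
    (rate = amount * 60 mg/h), not as an instantaneous input.
    """

    start: float
    rate: float
    duration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.start) or self.start < 0.0:
            raise ValueError(f"DoseEvent start must be >= 0, got {self.start!r}")
        if not math.isfinite(self.rate) or self.rate < 0.0:
            raise ValueError(f"DoseEvent rate must be >= 0, got {self.rate!r}")
        if not math.isfinite(self.duration) or self.duration <= 0.0:
            raise ValueError(f"DoseEvent duration must be > 0, got {self.duration!r}")

    @property
    def amount(self) -> float:
        """Total dose delivered by the segment, mg."""
        return self.rate * self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered collection of infusion segments; overlapping rates add."""

    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "events", events)

    @classmethod
    def constant_infusion(cls, rate: float, duration: float, start: float = 0.0) -> "Regimen":
        return cls((DoseEvent(start=start, rate=rate, duration=duration),))

    @classmethod
    def loading_plus_maintenance(
        cls, loading_mg: float, maintenance_rate: float, maintenance_duration: float
    ) -> "Regimen":
        """Loading dose as a 1-min infusion followed immediately by maintenance."""
        load = DoseEvent(start=0.0, rate=loading_mg * 60.0, duration=1.0 / 60.0)
        maint = DoseEvent(start=1.0 / 60.0, rate=maintenance_rate, duration=maintenance_duration)
        return cls((load, maint))

    @property
    def end_time(self) -> float:
        """Time at which the last segment switches off, h (0 for empty regimen)."""
        return max((e.end for e in self.events), default=0.0)

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


def _hybrid_arrays(cl, v1, q, v2):
    """Hybrid exponents and bolus coefficients, vectorised over parameter arrays.

    Returns ``(lam_fast, lam_slow, a_fast, a_slow)`` where the unit-bolus
    concentration response is ``a_fast*exp(-lam_fast t) + a_slow*exp(-lam_slow t)``
    (mg/L per mg).  Near-coincident roots are separated by a tiny relative clamp
    so that every downstream expression stays finite; the clamp perturbs the
    profile by O(1e-8) relative, below every tolerance used in this package.
    """
    cl = np.asarray(cl, dtype=float)
    k10 = cl / v1
    k12 = np.asarray(q, dtype=float) / v1
    k21 = np.asarray(q, dtype=float) / v2
    ksum = k10 + k12 + k21
    disc = np.sqrt(np.maximum(ksum * ksum - 4.0 * k10 * k21, 0.0))
    lam_fast = 0.5 * (ksum + disc)
    lam_slow = 0.5 * (ksum - disc)
    # degenerate-root guard: enforce a minimal relative gap
    min_gap = _DEGENERATE_GAP * lam_fast
    lam_slow = np.where(lam_fast - lam_slow < min_gap, lam_fast - min_gap, lam_slow)
    denom = v1 * (lam_fast - lam_slow)
    a_fast = (lam_fast - k21) / denom
    a_slow = (k21 - lam_slow) / denom
    return lam_fast, lam_slow, a_fast, a_slow


def _segment_concentration(cl, v1, q, v2, seg_start, seg_rate, seg_dur, t):
    """Concentration contribution (mg/L) of infusion segments at times ``t``.

    All arguments broadcast elementwise; this is the workhorse shared by the
    public API and the batched mixed-effects engine.
    """
    lam_fast, lam_slow, a_fast, a_slow = _hybrid_arrays(cl, v1, q, v2)
    tau = np.asarray(t, dtype=float) - seg_start
    on = np.clip(tau, 0.0, seg_dur)          # time spent infusing
    off = np.maximum(tau - seg_dur, 0.0)     # time since the segment stopped
    term_fast = a_fast / lam_fast * (-np.expm1(-lam_fast * on)) * np.exp(-lam_fast * off)
    term_slow = a_slow / lam_slow * (-np.expm1(-lam_slow * on)) * np.exp(-lam_slow * off)
    return seg_rate * (term_fast + term_slow)


def micro_constants(params: PKParameters) -> HybridConstants:
    """Reparameterize (CL, V1, Q, V2) into micro and hybrid rate constants.

    The hybrid exponents are the roots of
    ``lambda^2 - (k10+k12+k21) lambda + k10 k21 = 0``; half-lives are ln2/lambda.
    """
    lam_fast, lam_slow, _, _ = _hybrid_arrays(params.cl, params.v1, params.q, params.v2)
    lam_fast = float(lam_fast)
    lam_slow = float(lam_slow)
    return HybridConstants(
        k10=params.cl / params.v1,
        k12=params.q / params.v1,
        k21=params.q / params.v2,
        lambda_fast=lam_fast,
        lambda_slow=lam_slow,
        t_half_fast=math.log(2.0) / lam_fast,
        t_half_slow=math.log(2.0) / lam_slow,
    )


def concentration(params: PKParameters, regimen: Regimen, times) -> np.ndarray:
    """Plasma concentration (ng/mL) at the requested times under a regimen.

    Exact closed-form superposition of the analytic response of each
    constant-rate segment; continuous in t, zero before the first dose.

    Parameters
    ----------
    params : PKParameters
    regimen : Regimen
        Piecewise-constant infusion history (mg/h).  An empty regimen yields
        zeros.
    times : array-like of float
        Times in hours, all >= 0.

    Returns
    -------
    numpy.ndarray
        Concentrations in ng/mL, same shape as ``times``.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("times must be >= 0")
    out = np.zeros_like(t)
    for ev in regimen.events:
        if ev.rate == 0.0:
            continue
        out = out + _segment_concentration(
            params.cl, params.v1, params.q, params.v2,
            ev.start, ev.rate, ev.duration, t,
        )
    return out * 1000.0  # mg/L -> ng/mL


def steady_state_concentration(params: PKParameters, rate: float) -> float:
    """Plateau concentration rate/CL under an indefinite infusion, ng/mL."""
    return rate / params.cl * 1000.0


def accumulation_fraction(params: PKParameters, times) -> np.ndarray:
    """C(t)/C_ss under a constant infusion started at t=0 (rate-independent)."""
    lam_fast, lam_slow, a_fast, a_slow = _hybrid_arrays(
        params.cl, params.v1, params.q, params.v2
    )
    t = np.asarray(times, dtype=float)
    frac = params.cl * (
        a_fast / lam_fast * (-np.expm1(-lam_fast * t))
        + a_slow / lam_slow * (-np.expm1(-lam_slow * t))
    )
    return frac


def time_to_css_fraction(params: PKParameters, rate: float, fraction: float) -> float:
    """Smallest t (h) at which C(t) reaches ``fraction`` of the steady-state plateau.

    Linear kinetics make the answer independent of the infusion rate; ``rate``
    is accepted for interface symmetry and sanity-checked only.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction!r}")
    if rate <= 0.0:
        raise ValueError(f"rate must be > 0, got {rate!r}")

    def gap(t: float) -> float:
        return float(accumulation_fraction(params, t)) - fraction

    hi = 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - defensive
            raise RuntimeError("failed to bracket time to steady-state fraction")
    return float(brentq(gap, 0.0, hi, xtol=1e-10, rtol=1e-12))
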