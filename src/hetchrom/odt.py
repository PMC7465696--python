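"""Order–disorder transition of a diblock from RPA correlation functions.

The random-phase approximation gives the diblock structure factor
S(q)⁻¹ ∝ F(x, f)/N − 2χ, with x = q²R_g² the dimensionless squared
wavevector and F a quotient of Debye-type correlation functions. The
spinodal is where S first diverges: χN_s(f) = min_x F(x, f)/2. At
symmetric composition this is the classic ≈ 10.5 threshold for a flexible
diblock.

Composition profiles ϕ_A(r_⊥) across lamellae are generated in two
regimes. Just above the ODT the profile is a weak sinusoid (wavy,
liquid-like interfaces); far above it, a square wave with narrow
tanh-smoothed interfaces of width w = 2b/√(6χ) (the standard
strong-segregation interface form), where b is the repeat (clutch) length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .clutch import (
    CHI_N_ODT_FLEXIBLE,
    STRONG_RATIO_DEFAULT,
    DiblockSpec,
    classify_segregation,
)

#: below this f·x the exact expression for g loses precision to
#: cancellation; a 3-term series takes over (seam tested against the exact
#: branch)
_SERIES_THRESHOLD = 1e-4


def debye_g(f: float, x) -> np.ndarray | float:
    """Debye-type correlation function g(f, x) = 2(fx + e^(−fx) − 1)/x².

    Continuous at x = 0 with limit f². Accepts scalar or array x.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError("require 0 < f ≤ 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be ≥ 0")
    fx = f * x
    out = np.empty_like(x)
    small = fx < _SERIES_THRESHOLD
    # series: g = f²(1 − fx/3 + (fx)²/12 − ...)
    fxs = fx[small]
    out[small] = f * f * (1.0 - fxs / 3.0 + fxs * fxs / 12.0)
    xl = x[~small]
    out[~small] = 2.0 * (fx[~small] + np.expm1(-fx[~small])) / (xl * xl)
    return out if out.ndim else float(out)


def rpa_F(f: float, x) -> np.ndarray | float:
    """Leibler correlation quotient F(x, f); spinodal is min_x F/2.

    F = g(1,x) / [g(f,x)·g(1−f,x) − ¼(g(1,x) − g(f,x) − g(1−f,x))²].
    Symmetric under f ↔ 1−f. Diverges as x → 0 (the homogeneous mode is
    suppressed by chain connectivity).
    """
    if not (0.0 < f < 1.0):
        raise ValueError("require 0 < f < 1")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    g1 = debye_g(1.0, x)
    gf = debye_g(f, x)
    gc = debye_g(1.0 - f, x)
    denom = np.asarray(gf) * gc - 0.25 * (np.asarray(g1) - gf - gc) ** 2
    if np.any(denom <= 0):
        raise FloatingPointError(
            "RPA denominator non-positive: outside the formula's domain"
        )
    out = np.asarray(g1) / denom
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SpinodalResult:
    """Spinodal χN and the wavevector that first goes unstable."""

    f: float
    chiN_s: float
    x_star: float

    def __post_init__(self):
        if self.chiN_s <= 0 or self.x_star <= 0:
            raise ValueError("chiN_s and x_star must be positive")


def spinodal(
    f: float,
    x_range: tuple[float, float] = (1e-3, 1e3),
    tol: float = 1e-8,
    n_grid: int = 1024,
) -> SpinodalResult:
    """Locate the spinodal: χN_s = min over x of F(x, f)/2.

    A log-spaced grid scan (handles the x → 0 divergence) brackets the
    minimum; golden-section/Brent refinement polishes it. For f = 0.5 this
    yields χN_s ≈ 10.495, i.e. the familiar "around 10.5".
    """
    if not (0.0 < f < 1.0):
        raise ValueError("require 0 < f < 1")
    xs = np.geomspace(x_range[0], x_range[1], n_grid)
    vals = rpa_F(f, xs) / 2.0
    i = int(np.argmin(vals))
    if i == 0 or i == len(xs) - 1:
        raise RuntimeError(
            f"spinodal minimum at grid edge (x = {xs[i]:.3g}, F/2 = "
            f"{vals[i]:.6g}); widen x_range"
        )
    res = minimize_scalar(
        lambda x: rpa_F(f, float(x)) / 2.0,
        bracket=(xs[i - 1], xs[i], xs[i + 1]),
        method="brent",
        options={"xtol": tol},
    )
    if not res.success:
        raise RuntimeError(f"spinodal refinement failed: {res.message}")
    return SpinodalResult(f=f, chiN_s=float(res.fun), x_star=float(res.x))


@dataclass(frozen=True)
class CompositionProfile:
    """ϕ_A across lamellae: positions in units of the repeat length b."""

    positions: np.ndarray
    phi_A: np.ndarray
    regime: str
    interface_width: float  # NaN in the weak regime (no sharp interface)

    def __post_init__(self):
        if np.any(self.phi_A < 0) or np.any(self.phi_A > 1):
            raise ValueError("ϕ_A must lie in [0, 1]")

    def sharpness(self) -> float:
        """Max |dϕ_A/dr|: the wavy → sharp progression is monotone in χN."""
        return float(np.max(np.abs(np.gradient(self.phi_A, self.positions))))


def interface_width(chi: float, b: float = 1.0) -> float:
    """Strong-segregation interface width w = 2b/√(6χ)."""
    if chi <= 0:
        raise ValueError("χ must be positive in the strong-segregation limit")
    return 2.0 * b / np.sqrt(6.0 * chi)


def lamellar_profile(
    spec: DiblockSpec,
    chiN_ODT: float = CHI_N_ODT_FLEXIBLE,
    n_periods: int = 4,
    n_points: int = 2048,
    b: float = 1.0,
    strong_ratio: float = STRONG_RATIO_DEFAULT,
) -> CompositionProfile:
    """Lamellar composition profile ϕ_A(r_⊥) for an ordered diblock.

    Weak regime (χN between the ODT and ``strong_ratio``·ODT):
    ϕ_A = f + A·cos(q*r) with amplitude A = min(f, 1−f)·√(1 − χN_ODT/χN) —
    zero exactly at the ODT, saturating well above it. Strong regime:
    a square wave (A-block fraction f of each period) smoothed at each
    interface by ½[1 + tanh(2(r − r_edge)/w)] with w = 2b/√(6χ). The
    lamellar period is 2π/q* with q* = √(x*)/R_g from the spinodal and
    R_g = b√(N/6).

    Raises on disordered input (χN below the ODT): classify first.
    """
    chiN = spec.chi * spec.N
    regime = classify_segregation(chiN, chiN_ODT, strong_ratio)
    if regime == "disordered":
        raise ValueError(
            f"χN = {chiN:.3g} < χN_ODT = {chiN_ODT:.3g}: disordered melt has "
            "no lamellar profile (use classify_segregation first)"
        )
    sp = spinodal(spec.f)
    Rg = b * np.sqrt(spec.N / 6.0)
    q = np.sqrt(sp.x_star) / Rg
    period = 2.0 * np.pi / q
    r = np.linspace(0.0, n_periods * period, n_points, endpoint=False)
    if regime == "weak_wavy":
        A = min(spec.f, 1.0 - spec.f) * np.sqrt(1.0 - chiN_ODT / chiN)
        phi = spec.f + A * np.cos(q * r)
        w = float("nan")
    else:
        w = interface_width(spec.chi, b)
        phi = np.zeros_like(r)
        # tanh-smoothed square wave; neighbour periods included so the
        # window edges carry full tails
        for k in range(-2, n_periods + 2):
            r0 = k * period
            r1 = r0 + spec.f * period
            phi += 0.5 * (
                np.tanh(2.0 * (r - r0) / w) - np.tanh(2.0 * (r - r1) / w)
            )
        phi = np.clip(phi, 0.0, 1.0)
    return CompositionProfile(
        positions=r, phi_A=phi, regime=regime, interface_width=w
    )
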