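"""Flory–Huggins χ for chromatin treated as a block copolymer of "clutches".

The unit of incompatibility here is not the nucleosome but the
oligo-nucleosomal clutch (2–10 nucleosomes, modelled at six): a
heterochromatin-like clutch is a clutch of H3K9me3-marked nucleosomes
bridged and compacted by HP1 dimers, a euchromatic clutch the same
nucleosomes unbridged. Absent HP1 the two are thermodynamically
equivalent, so χ is built entirely from the free-energy consequences of
HP1 bridging.

Unit conventions
----------------
All enthalpic terms (``H_*``) are carried as energy divided by the
Boltzmann constant, i.e. in kelvin; the compaction entropy ``S_COMP`` is in
units of k_B (dimensionless); temperatures in kelvin. Dividing H-terms by T
then yields a dimensionless χ directly. Favorable binding contributions
(``H_CD``, ``H_CSD``) are entered as **positive magnitudes** — they appear
with positive sign in χ — while the compaction and terminal-linker
penalties are subtracted. Thermodynamic sign conventions vary; this one
makes "stronger binding ⇒ larger χ ⇒ stronger demixing" literal.

The classical lattice and dispersive formulas for monomer-level χ are
provided alongside for comparison and for the analytic limits they supply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

#: RPA order–disorder threshold for a flexible symmetric diblock (see the
#: companion ``odt`` module, which recomputes it from first principles).
CHI_N_ODT_FLEXIBLE = 10.495

#: Multiplier of the ODT separating weak ("wavy", liquid-like) from strong
#: ("sharp") segregation. The distinction is qualitative (χN >> χN_ODT);
#: 5 is the package default and is exposed everywhere it is used.
STRONG_RATIO_DEFAULT = 5.0


@dataclass(frozen=True)
class LatticeParams:
    """Mean-field lattice description of monomer contacts.

    ``z`` is the lattice coordination number, ``kBT`` the thermal energy,
    and ``eps_*`` the A–B / A–A / B–B contact energies per repeat unit (all
    in the same energy units).
    """

    z: int
    kBT: float
    eps_AB: float
    eps_AA: float
    eps_BB: float

    def __post_init__(self):
        if self.z < 1:
            raise ValueError("coordination number z must be ≥ 1")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")


@dataclass(frozen=True)
class DispersiveSegment:
    """A segment interacting by London dispersion: polarizability α (volume
    units) and first ionization potential I (energy units)."""

    alpha: float
    ionization_potential: float

    def __post_init__(self):
        if self.alpha <= 0 or self.ionization_potential <= 0:
            raise ValueError("α and I must be positive")


@dataclass(frozen=True)
class EmpiricalChiCoefficients:
    """χ(T) = alpha_enthalpic / T + beta_entropic; either sign allowed."""

    alpha_enthalpic: float
    beta_entropic: float


@dataclass(frozen=True)
class ClutchEnergyTerms:
    """Free-energy bookkeeping for one heterochromatin-like vs euchromatic
    clutch pair.

    ``H_CD``: chromodomain–H3K9me3 binding, summed over the bridges in the
    clutch; ``H_CSD``: chromoshadow-domain dimerization, summed over
    bridging dimers; ``H_COMP``: potential energy of compaction (linker
    elasticity + steric exclusion); ``H_TL``: elastic energy of the
    terminal linker joining the clutch to flanking euchromatin; ``S_COMP``:
    excess entropy given up on compaction (sign is the caller's choice).
    H-terms in kelvin (energy / k_B), S_COMP in k_B, T in kelvin.
    ``flanked_both_sides``: a domain/complex embedded in euchromatin pays
    the terminal-linker penalty twice.
    """

    H_CD: float
    H_CSD: float
    H_COMP: float
    H_TL: float
    S_COMP: float
    T: float
    flanked_both_sides: bool = False

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        for name in ("H_CD", "H_CSD", "H_COMP", "H_TL", "S_COMP"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class DiblockSpec:
    """Composition f, repeat-unit (clutch) count N, and χ of one diblock."""

    f: float
    N: int
    chi: float

    def __post_init__(self):
        if not (0.0 < self.f < 1.0):
            raise ValueError("composition f must lie in (0, 1)")
        if self.N < 1:
            raise ValueError("N must be ≥ 1")


def chi_lattice(p: LatticeParams) -> float:
    """Mean-field lattice χ: (z/kBT)·[ε_AB − ½(ε_AA + ε_BB)].

    Zero when the A–B contact energy is the mean of the like contacts
    (mixing-neutral); positive when unlike contacts are costlier.
    """
    return (p.z / p.kBT) * (p.eps_AB - 0.5 * (p.eps_AA + p.eps_BB))


def dispersive_contact_energy(
    i: DispersiveSegment, j: DispersiveSegment, r: float
) -> float:
    """London dispersion contact energy for a single segment pair.

    ε_ij = −(3/4)·(I_i I_j / (I_i + I_j))·(α_i α_j / r⁶). The sum over
    pairs is left to the caller, keeping this referentially transparent.
    """
    if r <= 0:
        raise ValueError("separation r must be positive")
    Ii, Ij = i.ionization_potential, j.ionization_potential
    return -0.75 * (Ii * Ij / (Ii + Ij)) * (i.alpha * j.alpha) / r**6


def chi_dispersive(
    A: DispersiveSegment,
    B: DispersiveSegment,
    z: int,
    kBT: float,
    V: float,
) -> float:
    """Dispersive χ on a cubic lattice: (3/8)·(I/kBT)·(z/V²)·(α_A − α_B)².

    Assumes a shared ionization potential I ≈ I_A ≈ I_B (a warning is
    issued when they differ by more than 10%) and lattice-site volume
    V = r³. Non-negative by construction: purely dispersive diblocks always
    have some tendency to demix.
    """
    if V <= 0:
        raise ValueError("lattice volume V must be positive")
    if kBT <= 0:
        raise ValueError("kBT must be positive")
    IA, IB = A.ionization_potential, B.ionization_potential
    I = 0.5 * (IA + IB)
    if abs(IA - IB) / I > 0.10:
        warnings.warn(
            "ionization potentials differ by more than 10%; the shared-I "
            "approximation behind the dispersive χ formula is strained",
            stacklevel=2,
        )
    return 0.375 * (I / kBT) * (z / V**2) * (A.alpha - B.alpha) ** 2


def chi_empirical(c: EmpiricalChiCoefficients, T: float) -> float:
    """Empirical two-coefficient χ(T) = α/T + β (enthalpic + excess-entropic)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return c.alpha_enthalpic / T + c.beta_entropic


def chi_clutch(t: ClutchEnergyTerms) -> float:
    """Clutch-level χ for a heterochromatin-like vs euchromatic clutch.

    χ_HC = (H_CD + H_CSD − H_COMP − m·H_TL)/T + S_COMP, with m = 2 when the
    domain/complex is flanked by euchromatin on both sides (it pays the
    terminal-linker penalty at each junction), else m = 1. With all terms
    zero — no HP1 — χ_HC = 0: the marked clutch is thermodynamically
    equivalent to the euchromatic one. The terminal-linker term opposes
    phase separation; severing the linker (as in chromatin-fragmentation
    experiments) removes it and can only increase χ_HC.
    """
    m = 2.0 if t.flanked_both_sides else 1.0
    return (t.H_CD + t.H_CSD - t.H_COMP - m * t.H_TL) / t.T + t.S_COMP


def segregation_product(spec: DiblockSpec) -> float:
    """χN: the degree of phase separation of the block from its surround."""
    return spec.chi * spec.N


def classify_segregation(
    chiN: float,
    chiN_ODT: float = CHI_N_ODT_FLEXIBLE,
    strong_ratio: float = STRONG_RATIO_DEFAULT,
) -> str:
    """Regime of a diblock given its segregation product.

    ``disordered`` below the ODT; ``weak_wavy`` (liquid-like, wavy
    interfaces) between the ODT and ``strong_ratio``·ODT; ``strong_sharp``
    (discrete, sharp interfaces) beyond.
    """
    if chiN_ODT <= 0:
        raise ValueError("chiN_ODT must be positive")
    if chiN < chiN_ODT:
        return "disordered"
    if chiN < strong_ratio * chiN_ODT:
        return "weak_wavy"
    return "strong_sharp"


def extrusion_mixing(
    calls: Sequence[tuple[float, int]],
    E: float,
    chiN_ODT: float = CHI_N_ODT_FLEXIBLE,
    effective_chiN: Callable[[float, float], float] | None = None,
) -> list[str]:
    """Loop-extrusion mixing: which domains/complexes survive extrusion.

    Loop extrusion converts ATP hydrolysis into heat through friction of
    the extruded domain/complex with the nucleoplasm, disrupting HP1
    bridging; here that is modelled as an activity ``E ≥ 0`` subtracted
    from the segregation product: χN_eff = χN − E. A call stays
    ``separated`` iff χN_eff ≥ χN_ODT, else it is ``mixed``. Small-N
    complexes therefore mix first as E rises: no extrusion reconstitutes
    even small complexes, moderate activity mixes only the small ones, and
    unrestrained extrusion mixes large domains too.

    ``effective_chiN(chiN, E)`` may replace the default subtraction with
    any monotone alternative (non-increasing in E).
    """
    if E < 0:
        raise ValueError("extrusion activity E must be ≥ 0")
    eff = effective_chiN or (lambda chiN, e: chiN - e)
    out = []
    for chi, N in calls:
        chiN_eff = eff(chi * N, E)
        out.append("separated" if chiN_eff >= chiN_ODT else "mixed")
    return out
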