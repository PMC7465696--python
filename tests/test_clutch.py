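"""Flory–Huggins χ formulas, segregation regimes, and loop-extrusion mixing."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetchrom import (
    ClutchEnergyTerms,
    DiblockSpec,
    DispersiveSegment,
    EmpiricalChiCoefficients,
    LatticeParams,
    chi_clutch,
    chi_dispersive,
    chi_empirical,
    chi_lattice,
    classify_segregation,
    dispersive_contact_energy,
    extrusion_mixing,
    segregation_product,
)

ODT = 10.495


class TestChiLattice:
    def test_mixing_neutral_is_zero(self):
        p = LatticeParams(z=6, kBT=1.0, eps_AB=0.3, eps_AA=0.2, eps_BB=0.4)
        assert chi_lattice(p) == pytest.approx(0.0, abs=1e-12)

    def test_direct_substitution(self):
        p = LatticeParams(z=6, kBT=1.0, eps_AB=0.5, eps_AA=0.2, eps_BB=0.2)
        assert chi_lattice(p) == pytest.approx(1.8)

    def test_label_swap_invariant(self):
        p = LatticeParams(z=4, kBT=2.0, eps_AB=0.7, eps_AA=0.1, eps_BB=0.5)
        q = dataclasses.replace(p, eps_AA=p.eps_BB, eps_BB=p.eps_AA)
        assert chi_lattice(p) == chi_lattice(q)

    def test_invalid_kbt(self):
        with pytest.raises(ValueError, match="kBT"):
            LatticeParams(z=6, kBT=0.0, eps_AB=0, eps_AA=0, eps_BB=0)


class TestDispersiveContact:
    def test_substitution(self):
        s = DispersiveSegment(alpha=1.0, ionization_potential=2.0)
        assert dispersive_contact_energy(s, s, r=1.0) == pytest.approx(-0.75)

    def test_symmetric_in_segments(self):
        a = DispersiveSegment(1.5, 2.0)
        b = DispersiveSegment(0.8, 2.2)
        assert dispersive_contact_energy(a, b, 1.3) == dispersive_contact_energy(b, a, 1.3)

    def test_r6_scaling(self):
        a = DispersiveSegment(1.0, 2.0)
        e1 = dispersive_contact_energy(a, a, 1.0)
        e2 = dispersive_contact_energy(a, a, 2.0)
        assert e1 / e2 == pytest.approx(64.0)

    def test_invalid_separation(self):
        a = DispersiveSegment(1.0, 1.0)
        with pytest.raises(ValueError, match="separation"):
            dispersive_contact_energy(a, a, 0.0)


class TestChiDispersive:
    def test_identical_segments_zero(self):
        a = DispersiveSegment(1.0, 2.0)
        assert chi_dispersive(a, a, z=6, kBT=1.0, V=1.0) == 0.0

    def test_substitution(self):
        a = DispersiveSegment(2.0, 1.0)
        b = DispersiveSegment(1.0, 1.0)
        assert chi_dispersive(a, b, z=6, kBT=1.0, V=1.0) == pytest.approx(2.25)

    def test_symmetry(self):
        a, b = DispersiveSegment(1.7, 2.0), DispersiveSegment(0.9, 2.1)
        assert chi_dispersive(a, b, 6, 1.0, 1.0) == chi_dispersive(b, a, 6, 1.0, 1.0)

    @given(
        aa=st.floats(0.1, 10), ab=st.floats(0.1, 10),
        i=st.floats(0.5, 5), v=st.floats(0.5, 5), kbt=st.floats(0.5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_nonnegative(self, aa, ab, i, v, kbt):
        # purely dispersive diblocks always tend to demix
        A, B = DispersiveSegment(aa, i), DispersiveSegment(ab, i)
        assert chi_dispersive(A, B, z=6, kBT=kbt, V=v) >= 0.0

    def test_mismatched_ionization_warns(self):
        a = DispersiveSegment(1.0, 1.0)
        b = DispersiveSegment(1.0, 2.0)
        with pytest.warns(UserWarning, match="10%"):
            chi_dispersive(a, b, 6, 1.0, 1.0)


class TestChiEmpirical:
    def test_substitution(self):
        c = EmpiricalChiCoefficients(alpha_enthalpic=30.0, beta_entropic=-0.05)
        assert chi_empirical(c, T=300.0) == pytest.approx(0.05)

    def test_athermal_when_alpha_zero(self):
        c = EmpiricalChiCoefficients(0.0, 0.1)
        assert chi_empirical(c, 100.0) == chi_empirical(c, 1000.0) == 0.1

    def test_linear_in_inverse_temperature(self):
        c = EmpiricalChiCoefficients(50.0, 0.02)
        ts = np.array([200.0, 300.0, 400.0, 600.0])
        chis = np.array([chi_empirical(c, t) for t in ts])
        slope, intercept = np.polyfit(1.0 / ts, chis, 1)
        assert slope == pytest.approx(50.0)
        assert intercept == pytest.approx(0.02)
        assert (np.diff(chis) < 0).all()  # decreasing in T when alpha > 0


def terms(**kw):
    base = dict(H_CD=900.0, H_CSD=0.0, H_COMP=200.0, H_TL=100.0,
                S_COMP=0.0, T=300.0, flanked_both_sides=False)
    base.update(kw)
    return ClutchEnergyTerms(**base)


class TestChiClutch:
    def test_no_hp1_no_incompatibility(self):
        t = terms(H_CD=0, H_CSD=0, H_COMP=0, H_TL=0)
        assert chi_clutch(t) == 0.0

    def test_one_sided_substitution(self):
        # (900 - 200 - 100)/300 = 2.0
        assert chi_clutch(terms()) == pytest.approx(2.0)

    def test_both_sides_pays_terminal_linker_twice(self):
        both = terms(flanked_both_sides=True)
        # (900 - 200 - 2*100)/300 = 5/3, strictly below the one-sided value
        assert chi_clutch(both) == pytest.approx(5 / 3)
        assert chi_clutch(both) < chi_clutch(terms())

    def test_severed_linker_never_decreases_chi(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = terms(
                H_CD=rng.uniform(0, 2000), H_CSD=rng.uniform(0, 2000),
                H_COMP=rng.uniform(0, 1000), H_TL=rng.uniform(0, 500),
                S_COMP=rng.uniform(-2, 2), T=rng.uniform(270, 330),
                flanked_both_sides=bool(rng.integers(2)),
            )
            severed = dataclasses.replace(t, H_TL=0.0)
            assert chi_clutch(severed) >= chi_clutch(t)

    def test_monotone_in_each_term(self):
        # finite differences: chi rises with binding, falls with penalties
        rng = np.random.default_rng(1)
        h = 1.0
        for _ in range(200):
            t = terms(
                H_CD=rng.uniform(0, 2000), H_CSD=rng.uniform(0, 2000),
                H_COMP=rng.uniform(0, 1000), H_TL=rng.uniform(0, 500),
                S_COMP=rng.uniform(-2, 2), T=rng.uniform(270, 330),
            )
            c0 = chi_clutch(t)
            assert chi_clutch(dataclasses.replace(t, H_CD=t.H_CD + h)) > c0
            assert chi_clutch(dataclasses.replace(t, H_CSD=t.H_CSD + h)) > c0
            assert chi_clutch(dataclasses.replace(t, H_COMP=t.H_COMP + h)) < c0
            assert chi_clutch(dataclasses.replace(t, H_TL=t.H_TL + h)) < c0

    def test_decreasing_in_temperature_for_positive_enthalpy(self):
        t = terms()
        warm = dataclasses.replace(t, T=t.T + 10)
        assert chi_clutch(warm) < chi_clutch(t)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError, match="temperature"):
            terms(T=0.0)


class TestSegregation:
    def test_product(self):
        assert segregation_product(DiblockSpec(0.5, 30, 0.5)) == 15.0

    def test_nonpositive_chi_never_ordered(self):
        assert segregation_product(DiblockSpec(0.5, 100, -0.1)) <= 0
        assert classify_segregation(-10.0) == "disordered"

    @pytest.mark.parametrize(
        "chiN,expected",
        [
            (5.0, "disordered"),
            (11.0, "weak_wavy"),
            (100.0, "strong_sharp"),
            (ODT, "weak_wavy"),  # threshold inclusive on the ordered side
        ],
    )
    def test_regimes(self, chiN, expected):
        assert classify_segregation(chiN, ODT) == expected

    def test_monotone_in_chiN(self):
        order = {"disordered": 0, "weak_wavy": 1, "strong_sharp": 2}
        grid = np.linspace(0.1, 200, 400)
        ranks = [order[classify_segregation(c, ODT)] for c in grid]
        assert ranks == sorted(ranks)


class TestExtrusionMixing:
    def test_no_extrusion_keeps_separation(self):
        assert extrusion_mixing([(0.5, 30)], E=0.0, chiN_ODT=ODT) == ["separated"]

    def test_strong_extrusion_mixes(self):
        assert extrusion_mixing([(0.5, 30)], E=20.0, chiN_ODT=ODT) == ["mixed"]

    def test_small_complexes_mix_first(self):
        # same chi per clutch; the small-N complex dissolves, the large survives
        calls = [(0.5, 100), (0.5, 25)]
        assert extrusion_mixing(calls, E=5.0, chiN_ODT=ODT) == [
            "separated", "mixed",
        ]

    def test_mixed_set_monotone_in_E(self):
        rng = np.random.default_rng(3)
        calls = [(float(rng.uniform(0.1, 1.0)), int(rng.integers(5, 200)))
                 for _ in range(30)]
        prev = set()
        for E in (0.0, 2.0, 5.0, 10.0, 50.0, 200.0):
            mixed = {
                i for i, s in enumerate(extrusion_mixing(calls, E, ODT))
                if s == "mixed"
            }
            assert prev <= mixed
            prev = mixed

    def test_no_separated_call_smaller_than_a_mixed_one(self):
        chi = 0.4
        calls = [(chi, n) for n in (5, 20, 26, 27, 50, 150)]
        status = extrusion_mixing(calls, E=0.5, chiN_ODT=ODT)
        ns = [n for _, n in calls]
        sep_ns = [n for n, s in zip(ns, status) if s == "separated"]
        mix_ns = [n for n, s in zip(ns, status) if s == "mixed"]
        if sep_ns and mix_ns:
            assert min(sep_ns) > max(mix_ns)

    def test_negative_E_rejected(self):
        with pytest.raises(ValueError, match="E"):
            extrusion_mixing([(0.5, 10)], E=-1.0)
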