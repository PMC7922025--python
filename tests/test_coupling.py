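"""Point-dipole couplings: kernel vs an independent SI-units oracle,
screening behaviour, matrix assembly, chain extents."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scipy.constants as codata

from chlorosim import (
    CouplingModel,
    LatticeSpec,
    build_aggregate,
    coupling_matrix,
    dipole_coupling,
    make_toy_monomer,
    neighbor_extent,
    screening_factor,
)
from chlorosim.errors import DegenerateGeometryError, UsageError


def si_oracle(mu_m, mu_l, r_vec, f=1.0):
    """Brute-force SI evaluation of the dipole-dipole coupling, in eV.

    Works entirely in SI units (C·m, m, J) and converts to eV at the end;
    shares no code or unit constants with the implementation under test.
    """
    debye = 3.33564095198152e-30  # C·m (1e-21/c)
    mu_m = np.asarray(mu_m) * debye
    mu_l = np.asarray(mu_l) * debye
    r = np.asarray(r_vec) * 1e-10  # Å -> m
    R = np.linalg.norm(r)
    term = mu_m @ mu_l / R**3 - 3.0 * (mu_m @ r) * (mu_l @ r) / R**5
    joules = f * term / (4.0 * math.pi * codata.epsilon_0)
    return joules / codata.elementary_charge


def monomer_with_dipole(mu, zn=(0, 0, 0), site_energy=1.973, mid=1):
    m = make_toy_monomer(2.0, 2.0, 180.0, monomer_id=mid, site_energy=site_energy)
    m = m.translated(np.asarray(zn, dtype=float))
    m.dipole = np.asarray(mu, dtype=float)
    return m


class TestScreeningFactor:
    def test_off_is_unity(self):
        model = CouplingModel(screening_mode="off")
        for R in (0.1, 5.0, 500.0):
            assert screening_factor(R, model) == 1.0

    def test_additive_long_range_limit_is_f0(self, solvent_model):
        assert screening_factor(1e6, solvent_model) == pytest.approx(0.54, abs=1e-12)

    def test_additive_hand_value(self, solvent_model):
        expected = 2.68 * math.exp(-0.27 * 10.0) + 0.54
        assert screening_factor(10.0, solvent_model) == pytest.approx(expected, rel=1e-12)

    def test_literal_form(self):
        model = CouplingModel(screening_mode="literal")
        expected = 2.68 * math.exp(-0.27 * 10.0 + 0.54)
        assert screening_factor(10.0, model) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_distance_rejected(self, solvent_model):
        with pytest.raises(DegenerateGeometryError):
            screening_factor(0.0, solvent_model)

    @settings(derandomize=True, max_examples=40)
    @given(R=st.floats(0.5, 100.0))
    def test_screened_coupling_bounded_by_f0_and_A_plus_f0(self, R):
        solvent = CouplingModel(screening_mode="additive")
        f = screening_factor(R, solvent)
        assert 0.54 <= f <= 2.68 + 0.54


class TestDipoleCoupling:
    def test_perpendicular_orientation_vanishes(self, vacuum_model):
        m = monomer_with_dipole((5.0, 0, 0))
        l = monomer_with_dipole((0, 5.0, 0), zn=(0, 0, 6.0), mid=2)
        assert dipole_coupling(m, l, vacuum_model) == 0.0

    def test_side_by_side_matches_si_oracle(self, vacuum_model):
        m = monomer_with_dipole((0, 5.0, 0))
        l = monomer_with_dipole((0, 5.0, 0), zn=(0, 0, 6.0), mid=2)
        value = dipole_coupling(m, l, vacuum_model)
        assert value > 0  # H-type arrangement
        assert value == pytest.approx(si_oracle((0, 5, 0), (0, 5, 0), (0, 0, 6)), rel=1e-9)
        assert value == pytest.approx(0.6241509 * 25.0 / 216.0, rel=1e-6)

    def test_head_to_tail_is_minus_two_side_by_side(self, vacuum_model):
        side = dipole_coupling(
            monomer_with_dipole((0, 5.0, 0)),
            monomer_with_dipole((0, 5.0, 0), zn=(0, 0, 6.0), mid=2),
            vacuum_model,
        )
        head = dipole_coupling(
            monomer_with_dipole((0, 0, 5.0)),
            monomer_with_dipole((0, 0, 5.0), zn=(0, 0, 6.0), mid=2),
            vacuum_model,
        )
        assert head == pytest.approx(-2.0 * side, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_random_pairs_match_si_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mu1, mu2 = rng.uniform(-7, 7, (2, 3))
        r = rng.uniform(-15, 15, 3)
        if np.linalg.norm(r) < 1.0:
            r = r + 5.0
        m = monomer_with_dipole(mu1)
        l = monomer_with_dipole(mu2, zn=r, mid=2)
        model = CouplingModel(screening_mode="additive")
        f = screening_factor(np.linalg.norm(r), model)
        assert dipole_coupling(m, l, model) == pytest.approx(
            si_oracle(mu1, mu2, r, f=f), rel=1e-9
        )

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_translation_invariance(self, seed):
        model = CouplingModel(screening_mode="off")
        rng = np.random.default_rng(seed)
        mu1, mu2 = rng.uniform(-7, 7, (2, 3))
        r = rng.uniform(2, 15, 3)
        t = rng.uniform(-30, 30, 3)
        m = monomer_with_dipole(mu1)
        l = monomer_with_dipole(mu2, zn=r, mid=2)
        h = dipole_coupling(m, l, model)
        assert dipole_coupling(l, m, model) == h
        assert dipole_coupling(
            m.translated(t), l.translated(t), model
        ) == pytest.approx(h, abs=1e-12)

    def test_coincident_sites_rejected(self, vacuum_model):
        m = monomer_with_dipole((0, 5, 0))
        l = monomer_with_dipole((0, 5, 0), mid=2)
        with pytest.raises(DegenerateGeometryError):
            dipole_coupling(m, l, vacuum_model)


def chain_spec(n, step=(0.0, 0.0, 6.0)):
    return LatticeSpec(counts=(1, 1, n), t_x=(1, 0, 0), t_y=(0, 1, 0), t_z=step)


class TestCouplingMatrix:
    def test_single_site_zero_matrix(self, planar_monomer, vacuum_model):
        agg = build_aggregate(planar_monomer, chain_spec(1))
        cm = coupling_matrix(agg, vacuum_model)
        assert cm.values.shape == (1, 1)
        assert cm.values[0, 0] == 0.0

    def test_pair_equals_kernel(self, planar_monomer, vacuum_model):
        agg = build_aggregate(planar_monomer, chain_spec(2))
        cm = coupling_matrix(agg, vacuum_model)
        expected = dipole_coupling(agg.monomers[0], agg.monomers[1], vacuum_model)
        assert cm.values[0, 1] == expected == cm.values[1, 0]

    def test_chain_matrix_matches_brute_force(self, planar_monomer, solvent_model):
        agg = build_aggregate(planar_monomer, chain_spec(24))
        cm = coupling_matrix(agg, solvent_model)
        ms = agg.monomers
        for i, j in itertools.combinations(range(24), 2):
            r = ms[j].zn - ms[i].zn
            f = screening_factor(np.linalg.norm(r), solvent_model)
            assert cm.values[i, j] == pytest.approx(
                si_oracle(ms[i].dipole, ms[j].dipole, r, f=f), rel=1e-9
            )
        np.testing.assert_array_equal(cm.values, cm.values.T)
        np.testing.assert_array_equal(np.diag(cm.values), np.zeros(24))

    def test_inverse_cube_decay_along_chain(self, planar_monomer, vacuum_model):
        agg = build_aggregate(planar_monomer, chain_spec(10))
        cm = coupling_matrix(agg, vacuum_model)
        scaled = [abs(cm.values[0, j]) * j**3 for j in range(1, 10)]
        np.testing.assert_allclose(scaled, scaled[0], rtol=1e-9)


class TestNeighborExtent:
    def test_threshold_above_nearest_gives_zero(self, planar_monomer, vacuum_model):
        agg = build_aggregate(planar_monomer, chain_spec(6))
        nearest = abs(
            dipole_coupling(agg.monomers[0], agg.monomers[1], vacuum_model)
        )
        assert neighbor_extent(agg, vacuum_model, nearest * 1.01) == 0

    @pytest.mark.parametrize("threshold_mev", [0.14, 0.5, 2.0, 10.0])
    def test_matches_enumeration_oracle(self, planar_monomer, vacuum_model, threshold_mev):
        agg = build_aggregate(planar_monomer, chain_spec(24))
        threshold = threshold_mev * 1e-3
        cm = coupling_matrix(agg, vacuum_model).values
        oracle = max(
            (j for j in range(1, 24) if abs(cm[0, j]) >= threshold), default=0
        )
        # |H| ~ 1/(jd)^3 for the unslipped chain, so the extent also has
        # a closed form
        nearest = abs(cm[0, 1])
        closed = min(23, math.floor((nearest / threshold) ** (1.0 / 3.0)))
        assert neighbor_extent(agg, vacuum_model, threshold) == oracle == closed

    def test_monotone_in_threshold(self, planar_monomer, vacuum_model):
        agg = build_aggregate(planar_monomer, chain_spec(24))
        thresholds = [1e-5, 1e-4, 1e-3, 1e-2]
        extents = [neighbor_extent(agg, vacuum_model, t) for t in thresholds]
        assert extents == sorted(extents, reverse=True)

    def test_non_chain_rejected(self, planar_monomer, vacuum_model):
        spec = LatticeSpec(
            counts=(2, 2, 1), t_x=(14, 0, 0), t_y=(0, 13, 0), t_z=(0, 0, 1)
        )
        agg = build_aggregate(planar_monomer, spec)
        with pytest.raises(UsageError, match="chain"):
            neighbor_extent(agg, vacuum_model, 1e-4)
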