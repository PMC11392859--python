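"""Unit tests for the 24-state regulatory-unit model and its rate law."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from thinfil import (
    MutationSpec,
    ParameterSet,
    RegulatoryUnitState,
    TpmPos,
    apply_mutation,
    enumerate_states,
    load_parameter_set,
    save_parameter_set,
    transition_rate,
)


def S(ca=0, sp=0, ip=0, tpm=TpmPos.B):
    return RegulatoryUnitState(bool(ca), bool(sp), bool(ip), TpmPos(tpm))


class TestEnumeration:
    def test_exactly_24_states(self):
        states = enumerate_states()
        assert len(states) == 24
        assert len(set(states)) == 24

    @pytest.mark.parametrize("tpm", list(TpmPos))
    def test_eight_states_per_tpm_position(self, tpm):
        assert sum(s.tpm_pos == tpm for s in enumerate_states()) == 8

    def test_order_is_frozen_lexicographic(self):
        states = enumerate_states()
        keys = [
            (s.ca_bound, s.sp_bound, s.ip_bound, int(s.tpm_pos)) for s in states
        ]
        assert keys == sorted(keys)
        assert [s.index for s in states] == list(range(24))
        # stable across calls
        assert enumerate_states() == states


class TestTransitionRate:
    def test_b_to_c_unpinned_no_neighbors_matches_rate_decomposition(self, set1):
        # 675 * 2.3**0.48 for a fully switched unit at the chain interior
        frm, to = S(1, 1, 0, TpmPos.B), S(1, 1, 0, TpmPos.C)
        rate = transition_rate(frm, to, None, None, set1, 1.0)
        assert rate == pytest.approx(675 * 2.3**0.48, rel=1e-12)
        assert rate == pytest.approx(1006.6, abs=0.2)

    def test_bc_ratio_equals_kbc_with_symmetric_neighbors(self, set1):
        # one neighbor blocked, one closed: coupling terms cancel exactly
        frm, to = S(1, 1, 0, TpmPos.B), S(1, 1, 0, TpmPos.C)
        fwd = transition_rate(frm, to, TpmPos.B, TpmPos.C, set1, 1.0)
        bwd = transition_rate(to, frm, TpmPos.B, TpmPos.C, set1, 1.0)
        assert fwd / bwd == pytest.approx(set1.K_BC, rel=1e-12)

    def test_bc_ratio_is_kbc_times_boltzmann_for_any_neighbors(self, set1):
        # crossbridge recruitment switched off to isolate the elastic law
        p = set1.with_(fxy_on_bc=False)
        frm, to = S(1, 1, 0, TpmPos.B), S(1, 1, 0, TpmPos.C)
        nbrs = [None, TpmPos.B, TpmPos.C, TpmPos.M]
        for ln, rn in itertools.product(nbrs, nbrs):
            fwd = transition_rate(frm, to, ln, rn, p, 1.0)
            bwd = transition_rate(to, frm, ln, rn, p, 1.0)
            de = sum(
                (abs(1 - int(n)) - abs(0 - int(n)))
                for n in (ln, rn)
                if n is not None
            ) * set1.coupling_energy
            assert fwd / bwd == pytest.approx(
                set1.K_BC * math.exp(-de), rel=1e-12
            )

    def test_multi_component_transitions_are_forbidden(self, set1):
        frm = S(0, 0, 0, TpmPos.B)
        to = S(1, 0, 0, TpmPos.C)  # ca and tpm both change
        assert transition_rate(frm, to, None, None, set1, 1.0) == 0.0

    def test_direct_b_to_m_jump_is_forbidden(self, set1):
        assert (
            transition_rate(S(1, 1, 0, TpmPos.B), S(1, 1, 0, TpmPos.M),
                            None, None, set1, 1.0) == 0.0
        )

    def test_negative_ca_rejected(self, set1):
        with pytest.raises(ValueError):
            transition_rate(S(), S(ca=1), None, None, set1, -0.1)

    def test_identical_states_rejected(self, set1):
        with pytest.raises(ValueError):
            transition_rate(S(), S(), None, None, set1, 1.0)

    def test_unit_weight_gamma_decouples_neighbors(self, set1):
        p = set1.with_(gamma=1.0)
        frm, to = S(1, 1, 0, TpmPos.B), S(1, 1, 0, TpmPos.C)
        alone = transition_rate(frm, to, None, None, p, 1.0)
        for ln, rn in itertools.product([TpmPos.B, TpmPos.C, TpmPos.M], repeat=2):
            if ln == TpmPos.M or rn == TpmPos.M:
                continue  # M neighbors still act through crossbridge recruitment
            assert transition_rate(frm, to, ln, rn, p, 1.0) == pytest.approx(
                alone, rel=1e-12
            )


class TestDetailedBalance:
    """Clockwise and counter-clockwise rate products agree at machine
    precision around every troponin coupling square (Ca-SP and SP-IP),
    in every context of the remaining components and tropomyosin
    position — including the states where the active-tropomyosin lock
    applies."""

    @staticmethod
    def _cycle_product(states, params, ca):
        prod = 1.0
        for a, b in zip(states, states[1:] + states[:1]):
            r = transition_rate(a, b, TpmPos.C, TpmPos.B, params, ca)
            assert r > 0, f"cycle edge {a} -> {b} has zero rate"
            prod *= r
        return prod

    @pytest.mark.parametrize("setname", ["set1", "set2"])
    @pytest.mark.parametrize("tpm", list(TpmPos))
    def test_ca_sp_square(self, setname, tpm):
        p = load_parameter_set(setname)
        for ip in (0, 1):
            cyc = [S(0, 0, ip, tpm), S(1, 0, ip, tpm), S(1, 1, ip, tpm), S(0, 1, ip, tpm)]
            cw = self._cycle_product(cyc, p, 0.7)
            ccw = self._cycle_product(list(reversed(cyc)), p, 0.7)
            assert cw == pytest.approx(ccw, rel=1e-12)

    @pytest.mark.parametrize("setname", ["set1", "set2"])
    @pytest.mark.parametrize("tpm", list(TpmPos))
    def test_sp_ip_square(self, setname, tpm):
        p = load_parameter_set(setname)
        for ca in (0, 1):
            cyc = [S(ca, 0, 0, tpm), S(ca, 1, 0, tpm), S(ca, 1, 1, tpm), S(ca, 0, 1, tpm)]
            cw = self._cycle_product(cyc, p, 0.7)
            ccw = self._cycle_product(list(reversed(cyc)), p, 0.7)
            assert cw == pytest.approx(ccw, rel=1e-12)


class TestMutation:
    def test_zero_expression_is_identity(self, set1):
        assert apply_mutation(set1, MutationSpec(0.5, 0.74, 0.0)) == set1

    def test_full_expression_kbc(self, set1):
        m = apply_mutation(set1, MutationSpec(0.5, 0.74, 1.0))
        assert m.K_BC == pytest.approx(1.702, abs=1e-9)
        assert m.K_BC == pytest.approx(1.70, abs=0.005)  # the printed value

    def test_half_expression_gamma_midpoint(self, set1):
        m = apply_mutation(set1, MutationSpec(gamma_scale=0.5, expression=0.5))
        assert m.gamma == pytest.approx(0.75 * set1.gamma, rel=1e-12)

    def test_only_gamma_and_kbc_change(self, set1):
        m = apply_mutation(set1, MutationSpec(0.5, 0.74, 1.0))
        assert m.with_(gamma=set1.gamma, K_BC=set1.K_BC) == set1

    @given(
        e1=st.floats(0.0, 1.0),
        e2=st.floats(0.0, 1.0),
        gs=st.floats(0.1, 1.0),
        ks=st.floats(0.5, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_interpolation_monotone_in_expression(self, set1, e1, e2, gs, ks):
        lo, hi = sorted((e1, e2))
        m_lo = apply_mutation(set1, MutationSpec(gs, ks, lo))
        m_hi = apply_mutation(set1, MutationSpec(gs, ks, hi))
        assert m_hi.gamma <= m_lo.gamma + 1e-12
        assert m_hi.K_BC <= m_lo.K_BC + 1e-12

    def test_out_of_range_expression_rejected(self):
        with pytest.raises(ValueError):
            MutationSpec(expression=1.5)
        with pytest.raises(ValueError):
            MutationSpec(gamma_scale=0.0)


class TestParameterSets:
    def test_set1_matches_published_values(self, set1):
        assert (set1.kCa_plus, set1.kCa_minus) == (350, 1000)
        assert (set1.kSP_plus, set1.kSP_minus) == (180, 292)
        assert (set1.kIP_plus, set1.kIP_minus) == (700, 225)
        assert (set1.kMD_plus, set1.kMD_minus) == (590, 225)
        assert set1.kref_BC == 675
        assert set1.K_BC == 2.3
        assert set1.f_XY == 225
        assert (set1.delta, set1.lam) == (0.48, 0.008)
        assert (set1.eta, set1.mu) == (9, 9)
        assert set1.gamma == 70  # dimensionless chain-stiffness weight
        assert set1.n_units == 26

    def test_set2_matches_published_values(self, set2):
        assert (set2.kCa_plus, set2.kCa_minus) == (310, 1800)
        assert set2.kref_BC == 875
        assert set2.K_BC == 2.0
        assert set2.f_XY == 25
        assert (set2.delta, set2.lam) == (0.4, 0.0001)
        assert (set2.eta, set2.mu) == (18, 18)
        assert set2.gamma == 50

    def test_round_trip_io(self, set1, tmp_path):
        path = tmp_path / "params.json"
        save_parameter_set(set1, path)
        assert load_parameter_set(path) == set1

    @pytest.mark.parametrize(
        "field,value",
        [
            ("K_BC", -1.0),
            ("delta", 1.5),
            ("lam", 0.0),
            ("eta", 0.5),
            ("n_units", 0),
            ("gamma", 0.0),
            ("kCa_plus", -5.0),
        ],
    )
    def test_invalid_parameters_rejected(self, set1, field, value):
        with pytest.raises(ValueError):
            set1.with_(**{field: value})
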