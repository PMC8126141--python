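"""Unit and property tests for the domain types and rate equations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptlkin import (
    SCENARIOS,
    STATE_NAMES,
    CellPhenotype,
    InvalidParameterError,
    ModelConstants,
    NumericInputError,
    SystemState,
    TreatmentScenario,
    derivative,
    initial_state,
    k4_from_pka,
    steady_state_h2o2,
)
from ptlkin.model_core import _params, jacobian, rhs

conc = st.floats(min_value=0.0, max_value=1e-3, allow_nan=False)


class TestK4FromPKa:
    @pytest.mark.parametrize(
        "pka, km4, expected",
        [
            (6.8, 1e10, 1.5849e3),   # 10**(-6.8) * 1e10
            (0.0, 1.0, 1.0),
            (6.5, 1e10, 3.1623e3),
        ],
    )
    def test_values(self, pka, km4, expected):
        assert k4_from_pka(pka, km4) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("pka, km4", [(6.8, 0.0), (6.8, -1.0), (-1.0, 1e10), (15.0, 1e10)])
    def test_invalid(self, pka, km4):
        with pytest.raises(InvalidParameterError):
            k4_from_pka(pka, km4)


class TestModelConstants:
    def test_defaults_are_literature_values(self, constants):
        assert constants.to_dict() == {
            "k1": 1.7e7, "k2": 2.6e7, "k3": 1.1e3, "pKa": 6.8,
            "k_minus4": 1e10, "k5": 1.7e6, "k6": 5.8e4, "kP": 1e-7,
            "kD4": 320.0, "kD5": 320.0, "kD7": 320.0,
        }

    def test_k4_derived_from_pka(self, constants):
        assert constants.k4 == pytest.approx(
            10 ** (-constants.pKa) * constants.k_minus4, rel=1e-12)

    @pytest.mark.parametrize("override", [{"k1": 0.0}, {"kP": -1e-7}, {"pKa": 20.0}])
    def test_invalid_fields_rejected(self, override):
        with pytest.raises(InvalidParameterError):
            ModelConstants(**override)

    def test_roundtrip(self, constants):
        assert ModelConstants.from_dict(constants.to_dict()) == constants


class TestPhenotypeAndScenario:
    def test_positivity_enforced(self):
        with pytest.raises(InvalidParameterError):
            CellPhenotype(kD1=0.0, CAT0=1e-8)
        with pytest.raises(InvalidParameterError):
            CellPhenotype(kD1=920.0, CAT0=-1e-8)

    def test_canonical_regimes(self):
        assert SCENARIOS["non_selective_synergistic"].h2o2_ec0 == 1e-3
        assert SCENARIOS["non_selective_synergistic"].no2_ec0 == 1e-3
        assert SCENARIOS["non_selective_non_synergistic"].no2_ec0 == 0.0
        assert SCENARIOS["selective_synergistic"].h2o2_ec0 == 1e-6
        assert SCENARIOS["selective_non_synergistic"].h2o2_ec0 == 1e-6
        assert SCENARIOS["selective_non_synergistic"].no2_ec0 == 0.0

    def test_from_label(self):
        sc = TreatmentScenario.from_label("selective_synergistic")
        assert sc.no2_ec0 == 1e-3
        with pytest.raises(InvalidParameterError):
            TreatmentScenario.from_label("no_such_regime")

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            TreatmentScenario(-1e-6, 0.0, "bad")


class TestSteadyStateH2O2:
    def test_reference_decades(self, constants):
        # kP / (k1*CAT0 + k3*c5*c6), computed independently
        assert steady_state_h2o2(constants, 1e-8) == pytest.approx(
            1e-7 / (1.7e7 * 1e-8 + 1.1e3 * 1e-4 * 1e-7), rel=1e-12)
        assert steady_state_h2o2(constants, 1e-8) == pytest.approx(5.882e-7, rel=1e-3)
        assert steady_state_h2o2(constants, 1e-5) == pytest.approx(5.882e-10, rel=1e-3)

    def test_no_nitrite_limit_is_exact(self, constants):
        assert steady_state_h2o2(constants, 1e-6, c5_ic=0.0) == \
            constants.kP / (constants.k1 * 1e-6)

    def test_invalid_cat0(self, constants):
        with pytest.raises(InvalidParameterError):
            steady_state_h2o2(constants, 0.0)

    @given(cat0=st.floats(1e-9, 1e-4), factor=st.floats(1.01, 100.0))
    def test_strictly_decreasing_in_cat0(self, cat0, factor):
        c = ModelConstants()
        assert steady_state_h2o2(c, cat0 * factor) < steady_state_h2o2(c, cat0)

    @given(cat0=st.floats(1e-9, 1e-4), factor=st.floats(1.01, 100.0))
    def test_strictly_increasing_in_kp(self, cat0, factor):
        lo = ModelConstants()
        hi = dataclasses.replace(lo, kP=lo.kP * factor)
        assert steady_state_h2o2(hi, cat0) > steady_state_h2o2(lo, cat0)


class TestInitialState:
    def test_selective_non_synergistic_ec(self, constants):
        s = initial_state(CellPhenotype(), SCENARIOS["selective_non_synergistic"], constants)
        assert s.c1_ec == 1e-6 and s.c5_ec == 0.0

    def test_assigned_zeros_and_shared_species(self, constants):
        for sc in SCENARIOS.values():
            s = initial_state(CellPhenotype(), sc, constants)
            assert s.c3 == s.c4_ec == s.c4_ic == s.c7_ec == s.c7_ic == 0.0
            assert s.sink_ec == s.sink_ic == 0.0
            assert s.c6_ec == s.c6_ic == 1e-7
            assert s.c8_ec == s.c8_ic == 1e-3
            assert s.c5_ic == 1e-4

    def test_ic_h2o2_is_steady_state(self, constants):
        ph = CellPhenotype(kD1=920.0, CAT0=1e-8)
        s = initial_state(ph, SCENARIOS["selective_non_synergistic"], constants)
        assert s.c1_ic == pytest.approx(5.882e-7, rel=1e-3)
        assert s.c2 == ph.CAT0 and s.catalase_total == ph.CAT0


class TestDerivative:
    def test_initial_ec_h2o2_rate(self, constants):
        ph = CellPhenotype(kD1=920.0, CAT0=1e-8)
        s = initial_state(ph, SCENARIOS["selective_non_synergistic"], constants)
        d = derivative(s, ph, constants)
        # pure diffusion at t=0: -kD1 * (c1_ec - c1_ic), no EC nitrite
        assert d.c1_ec == pytest.approx(-920.0 * (1e-6 - s.c1_ic), rel=1e-12)
        assert d.c1_ec == pytest.approx(-3.789e-4, rel=1e-3)

    def test_mitochondrial_production_only(self, constants):
        # all concentrations zero: the only nonzero channel is kP into the IC
        d = derivative(SystemState(), CellPhenotype(), constants)
        vec = d.to_vector()
        assert d.c1_ic == constants.kP == 1e-7
        assert np.count_nonzero(vec) == 1

    @given(y=st.lists(conc, min_size=16, max_size=16))
    def test_catalase_two_state_cycle(self, y):
        d = rhs(0.0, np.array(y), _params(CellPhenotype(), ModelConstants()))
        assert d[STATE_NAMES.index("c2")] == -d[STATE_NAMES.index("c3")]

    @given(y=st.lists(conc, min_size=16, max_size=16))
    def test_diffusion_antisymmetry(self, y):
        """EC+IC derivative sums contain no diffusion terms for species 1/4/5/7."""
        c = ModelConstants()
        ph = CellPhenotype(kD1=920.0, CAT0=1e-8)
        y = np.array(y)
        d = rhs(0.0, y, _params(ph, c))
        i = {n: j for j, n in enumerate(STATE_NAMES)}
        c1e, c4e, c5e, c6e, c7e, c8e = y[0:6]
        c1i, c5i, c6i = y[i["c1_ic"]], y[i["c5_ic"]], y[i["c6_ic"]]
        c2, c3, c4i, c7i, c8i = y[i["c2"]], y[i["c3"]], y[i["c4_ic"]], y[i["c7_ic"]], y[i["c8_ic"]]
        # reaction-only sums computed independently
        r3e, r3i = c.k3 * c1e * c5e * c6e, c.k3 * c1i * c5i * c6i
        pairs = {
            ("c1_ec", "c1_ic"): -r3e - c.k1 * c1i * c2 - c.k2 * c1i * c3 - r3i + c.kP,
            ("c4_ec", "c4_ic"): (c.k4 * (c7e + c7i) - c.k_minus4 * (c4e * c6e + c4i * c6i)
                                 - c.k6 * (c4e * c8e + c4i * c8i) - c.k5 * c2 * c4i),
            ("c5_ec", "c5_ic"): -r3e - r3i + c.k5 * c2 * c4i,
            ("c7_ec", "c7_ic"): (r3e + r3i - c.k4 * (c7e + c7i)
                                 + c.k_minus4 * (c4e * c6e + c4i * c6i)),
        }
        scale = max(1e-20, np.max(np.abs(d)))
        for (ec, ic), expected in pairs.items():
            assert d[i[ec]] + d[i[ic]] == pytest.approx(expected, abs=1e-10 * scale)

    def test_co2_inert_without_peroxynitrite(self, constants):
        s = SystemState(c1_ec=1e-3, c5_ec=1e-3, c6_ec=1e-7, c8_ec=1e-3,
                        c2=1e-7, c8_ic=1e-3)
        d = derivative(s, CellPhenotype(), constants)
        assert d.c8_ec == 0.0 and d.c8_ic == 0.0

    def test_nonfinite_state_rejected(self, constants):
        s = SystemState(c1_ec=float("nan"))
        with pytest.raises(NumericInputError):
            derivative(s, CellPhenotype(), constants)

    @given(y=st.lists(st.floats(1e-12, 1e-3), min_size=16, max_size=16))
    def test_jacobian_matches_finite_differences(self, y):
        y = np.array(y)
        p = _params(CellPhenotype(kD1=920.0, CAT0=1e-8), ModelConstants())
        J = jacobian(0.0, y, p)
        for j in range(16):
            # every rate term is multilinear, so the central difference is
            # exact in real arithmetic for any h; a large h beats roundoff
            h = 1e-3
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            col = (rhs(0.0, yp, p) - rhs(0.0, ym, p)) / (2 * h)
            scale = max(np.max(np.abs(col)), np.max(np.abs(J[:, j])), 1e-6)
            assert np.allclose(J[:, j], col, atol=1e-5 * scale)


class TestSystemState:
    def test_vector_roundtrip(self):
        s = SystemState(**{n: float(i + 1) for i, n in enumerate(STATE_NAMES)})
        assert SystemState.from_vector(s.to_vector()) == s

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            SystemState.from_vector(np.zeros(5))

    def test_nitrogen_total_counts_sinks(self):
        s = SystemState(c4_ec=1.0, c5_ec=2.0, c7_ec=3.0, c4_ic=4.0,
                        c5_ic=5.0, c7_ic=6.0, sink_ec=7.0, sink_ic=8.0)
        assert s.nitrogen_total == 36.0
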