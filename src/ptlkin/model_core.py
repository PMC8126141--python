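"""Core chemistry of the two-compartment cell/plasma-treated-liquid model.

The model tracks eight species — H2O2 (c1), native catalase CATFeIII (c2),
compound I CATFeIVO·+ (c3), peroxynitrite ONOO- (c4), nitrite NO2- (c5),
H+ (c6), peroxynitrous acid ONOOH (c7) and CO2 (c8) — in an extracellular
(EC) and an intracellular (IC) compartment coupled only by first-order
membrane diffusion of species 1, 4, 5 and 7.  All concentrations are molar,
all times in seconds.

Reactions:

* catalase cycle (IC only):
  CATFeIII + H2O2 --k1--> compound I + H2O,
  compound I + H2O2 --k2--> CATFeIII + O2 + H2O
* peroxynitrous acid formation (both compartments):
  NO2- + H2O2 + H+ --k3--> ONOOH + H2O
* acid-base equilibrium (both): ONOOH <--k4/k-4--> ONOO- + H+
* catalase-mediated peroxynitrite decomposition (IC only):
  2 ONOO- --k5 (CATFeIII)--> O2 + 2 NO2-
* CO2-catalysed peroxynitrite consumption (both):
  ONOO- + CO2 --k6--> ONOOCOO-
* constant mitochondrial H2O2 production kP (IC only)

ONOOCOO- is inert in the model; its cumulative production per compartment is
tracked in the ``sink_ec``/``sink_ic`` bookkeeping fields so that nitrogen
mass balance can be checked on any trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "InvalidParameterError",
    "NumericInputError",
    "ModelConstants",
    "CellPhenotype",
    "TreatmentScenario",
    "SystemState",
    "SCENARIOS",
    "STATE_NAMES",
    "IC_NO2_0",
    "H_PLUS_0",
    "CO2_0",
    "k4_from_pka",
    "steady_state_h2o2",
    "initial_state",
    "derivative",
    "rhs",
    "jacobian",
]


class InvalidParameterError(ValueError):
    """A model parameter is outside its physically admissible range."""


class NumericInputError(ValueError):
    """A numeric input (state or rate) is non-finite."""


# Shared initial concentrations (M): H+ and CO2 are assigned equal values in
# both compartments; intracellular nitrite reflects a physiological resting
# level.
IC_NO2_0 = 1e-4
H_PLUS_0 = 1e-7
CO2_0 = 1e-3


def k4_from_pka(pka: float, k_minus4: float) -> float:
    """Forward rate of ONOOH -> ONOO- + H+ from the acid pKa.

    Detailed balance of the acid-base equilibrium gives
    ``k4 = Ka * k_minus4 = 10**(-pKa) * k_minus4`` (units s-1 when k_minus4
    is in M-1 s-1).

    Parameters
    ----------
    pka : acid dissociation pKa of ONOOH (dimensionless, 0-14).
    k_minus4 : recombination rate constant ONOO- + H+ -> ONOOH, M-1 s-1.
    """
    if not (0.0 <= pka <= 14.0):
        raise InvalidParameterError(f"pKa must be within [0, 14], got {pka}")
    if not (k_minus4 > 0):
        raise InvalidParameterError(f"k_minus4 must be positive, got {k_minus4}")
    return 10.0 ** (-pka) * k_minus4


@dataclass(frozen=True)
class ModelConstants:
    """Rate, diffusion and production constants.

    Defaults are the literature values used throughout: mammalian catalase
    kinetics (k1, k2), peroxynitrous acid formation (k3), the ONOOH/ONOO-
    equilibrium (pKa, k_minus4), catalase-mediated (k5) and CO2-catalysed
    (k6) peroxynitrite removal, mitochondrial H2O2 production kP, and the
    lipid-bilayer diffusion rate constants of ONOO-, NO2- and ONOOH.

    ``k4`` is derived from ``pKa`` and ``k_minus4`` and exposed as a
    read-only property.
    """

    k1: float = 1.7e7       # M-1 s-1, CATFeIII + H2O2
    k2: float = 2.6e7       # M-1 s-1, compound I + H2O2
    k3: float = 1.1e3       # M-2 s-1, NO2- + H2O2 + H+
    pKa: float = 6.8        # ONOOH acid dissociation (range 6.5-6.8 at 25 C)
    k_minus4: float = 1e10  # M-1 s-1, ONOO- + H+
    k5: float = 1.7e6       # M-1 s-1, catalase-mediated ONOO- decomposition
    k6: float = 5.8e4       # M-1 s-1, ONOO- + CO2
    kP: float = 1e-7        # M s-1, mitochondrial H2O2 production
    kD4: float = 320.0      # s-1, membrane diffusion of ONOO-
    kD5: float = 320.0      # s-1, membrane diffusion of NO2-
    kD7: float = 320.0      # s-1, membrane diffusion of ONOOH

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "pKa":
                if not (0.0 <= v <= 14.0):
                    raise InvalidParameterError(f"pKa must be in [0, 14], got {v}")
            elif not (v > 0):
                raise InvalidParameterError(f"{f.name} must be positive, got {v}")

    @property
    def k4(self) -> float:
        """Forward ONOOH dissociation rate, s-1 (derived from pKa)."""
        return k4_from_pka(self.pKa, self.k_minus4)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelConstants":
        return cls(**d)


@dataclass(frozen=True)
class CellPhenotype:
    """The two cell-specific independent variables.

    kD1
        H2O2 membrane diffusion rate constant, s-1.  Stands in for aquaporin
        expression; the sweep range 100-2000 s-1 brackets the 920 s-1
        lipid-bilayer reference value for water.
    CAT0
        Initial intracellular native-catalase concentration [CATFeIII]0, M.
        Swept over 1e-8 to 1e-5 M (cancer-like cells sit at the high-kD1 /
        low-CAT0 corner, normal-like cells at the opposite corner).
    """

    kD1: float = 920.0
    CAT0: float = 1e-8

    def __post_init__(self) -> None:
        if not (self.kD1 > 0):
            raise InvalidParameterError(f"kD1 must be positive, got {self.kD1}")
        if not (self.CAT0 > 0):
            raise InvalidParameterError(f"CAT0 must be positive, got {self.CAT0}")


@dataclass(frozen=True)
class TreatmentScenario:
    """Initial extracellular H2O2/NO2- supplied by the plasma-treated liquid."""

    h2o2_ec0: float
    no2_ec0: float
    regime_label: str

    def __post_init__(self) -> None:
        if self.h2o2_ec0 < 0 or self.no2_ec0 < 0:
            raise InvalidParameterError("scenario concentrations must be non-negative")

    @classmethod
    def from_label(cls, label: str) -> "TreatmentScenario":
        try:
            return SCENARIOS[label]
        except KeyError:
            raise InvalidParameterError(
                f"unknown scenario label {label!r}; known: {sorted(SCENARIOS)}"
            ) from None


#: The four canonical treatment regimes: selectivity is associated with the
#: 1 uM extracellular H2O2 regime, synergy with co-supplied 1 mM nitrite.
SCENARIOS: dict[str, TreatmentScenario] = {
    "non_selective_synergistic": TreatmentScenario(1e-3, 1e-3, "non_selective_synergistic"),
    "non_selective_non_synergistic": TreatmentScenario(1e-3, 0.0, "non_selective_non_synergistic"),
    "selective_synergistic": TreatmentScenario(1e-6, 1e-3, "selective_synergistic"),
    "selective_non_synergistic": TreatmentScenario(1e-6, 0.0, "selective_non_synergistic"),
}


#: State-vector ordering used everywhere (trajectory columns, RHS, Jacobian).
STATE_NAMES: tuple[str, ...] = (
    "c1_ec", "c4_ec", "c5_ec", "c6_ec", "c7_ec", "c8_ec",
    "c1_ic", "c2", "c3", "c4_ic", "c5_ic", "c6_ic", "c7_ic", "c8_ic",
    "sink_ec", "sink_ic",
)

N_STATE = len(STATE_NAMES)


@dataclass(frozen=True)
class SystemState:
    """Concentrations (M) of both compartments plus ONOOCOO- sink bookkeeping."""

    c1_ec: float = 0.0
    c4_ec: float = 0.0
    c5_ec: float = 0.0
    c6_ec: float = 0.0
    c7_ec: float = 0.0
    c8_ec: float = 0.0
    c1_ic: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4_ic: float = 0.0
    c5_ic: float = 0.0
    c6_ic: float = 0.0
    c7_ic: float = 0.0
    c8_ic: float = 0.0
    sink_ec: float = 0.0
    sink_ic: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATE,):
            raise InvalidParameterError(f"state vector must have length {N_STATE}")
        return cls(**dict(zip(STATE_NAMES, y.tolist())))

    @property
    def catalase_total(self) -> float:
        """c2 + c3; conserved along any trajectory (equals CAT0)."""
        return self.c2 + self.c3

    @property
    def nitrogen_total(self) -> float:
        """Total nitrogen over both compartments including the ONOOCOO- sinks."""
        return (self.c4_ec + self.c5_ec + self.c7_ec
                + self.c4_ic + self.c5_ic + self.c7_ic
                + self.sink_ec + self.sink_ic)


def steady_state_h2o2(
    constants: ModelConstants,
    cat0: float,
    c5_ic: float = IC_NO2_0,
    c6_ic: float = H_PLUS_0,
) -> float:
    """Pre-treatment steady-state intracellular H2O2 concentration, M.

    Balancing constant mitochondrial production against first-pass removal,
    with all catalase native (c3 = 0) at t = 0:

        c1_ss = kP / (k1 * CAT0 + k3 * c5_ic * c6_ic)

    Strictly positive, strictly decreasing in ``cat0`` and strictly
    increasing in ``kP``.
    """
    if not (cat0 > 0):
        raise InvalidParameterError(f"CAT0 must be positive, got {cat0}")
    return constants.kP / (constants.k1 * cat0 + constants.k3 * c5_ic * c6_ic)


def initial_state(
    phenotype: CellPhenotype,
    scenario: TreatmentScenario,
    constants: ModelConstants,
) -> SystemState:
    """State at t = 0: treated medium outside, resting cell inside.

    EC holds the scenario's H2O2 and nitrite plus assigned H+ and CO2; the IC
    starts at its pre-treatment H2O2 steady state with all catalase in the
    native CATFeIII form and no peroxynitrite species anywhere.
    """
    return SystemState(
        c1_ec=scenario.h2o2_ec0,
        c4_ec=0.0,
        c5_ec=scenario.no2_ec0,
        c6_ec=H_PLUS_0,
        c7_ec=0.0,
        c8_ec=CO2_0,
        c1_ic=steady_state_h2o2(constants, phenotype.CAT0),
        c2=phenotype.CAT0,
        c3=0.0,
        c4_ic=0.0,
        c5_ic=IC_NO2_0,
        c6_ic=H_PLUS_0,
        c7_ic=0.0,
        c8_ic=CO2_0,
        sink_ec=0.0,
        sink_ic=0.0,
    )


def _params(phenotype: CellPhenotype, constants: ModelConstants) -> tuple:
    c = constants
    return (c.k1, c.k2, c.k3, c.k4, c.k_minus4, c.k5, c.k6, c.kP,
            phenotype.kD1, c.kD4, c.kD5, c.kD7)


def rhs(t: float, y: np.ndarray, p: tuple) -> np.ndarray:
    """Right-hand side of the 14-species + 2-sink ODE system.

    ``p`` is the flat parameter tuple (k1, k2, k3, k4, k_minus4, k5, k6, kP,
    kD1, kD4, kD5, kD7); ``y`` follows :data:`STATE_NAMES`.  Diffusion fluxes
    enter the EC and IC equations with equal magnitude and opposite sign.
    """
    k1, k2, k3, k4, km4, k5, k6, kP, kD1, kD4, kD5, kD7 = p
    (c1e, c4e, c5e, c6e, c7e, c8e,
     c1i, c2, c3, c4i, c5i, c6i, c7i, c8i, _, _) = y

    r3e = k3 * c1e * c5e * c6e
    q4e = k4 * c7e
    qm4e = km4 * c4e * c6e
    r6e = k6 * c4e * c8e
    d1 = kD1 * (c1e - c1i)
    d4 = kD4 * (c4e - c4i)
    d5 = kD5 * (c5e - c5i)
    d7 = kD7 * (c7e - c7i)

    r1 = k1 * c1i * c2
    r2 = k2 * c1i * c3
    r3i = k3 * c1i * c5i * c6i
    q4i = k4 * c7i
    qm4i = km4 * c4i * c6i
    r5 = k5 * c2 * c4i
    r6i = k6 * c4i * c8i

    return np.array([
        -r3e - d1,                     # c1_ec
        q4e - qm4e - r6e - d4,         # c4_ec
        -r3e - d5,                     # c5_ec
        -r3e + q4e - qm4e,             # c6_ec
        r3e - q4e + qm4e - d7,         # c7_ec
        -r6e,                          # c8_ec
        -r1 - r2 - r3i + d1 + kP,      # c1_ic
        -r1 + r2,                      # c2
        r1 - r2,                       # c3
        q4i - qm4i - r5 - r6i + d4,    # c4_ic
        -r3i + r5 + d5,                # c5_ic
        -r3i + q4i - qm4i,             # c6_ic
        r3i - q4i + qm4i + d7,         # c7_ic
        -r6i,                          # c8_ic
        r6e,                           # sink_ec
        r6i,                           # sink_ic
    ])


def jacobian(t: float, y: np.ndarray, p: tuple) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` (verified against finite differences)."""
    k1, k2, k3, k4, km4, k5, k6, kP, kD1, kD4, kD5, kD7 = p
    (c1e, c4e, c5e, c6e, c7e, c8e,
     c1i, c2, c3, c4i, c5i, c6i, c7i, c8i, _, _) = y

    J = np.zeros((N_STATE, N_STATE))

    # EC trimolecular term partials
    a1 = k3 * c5e * c6e
    a5 = k3 * c1e * c6e
    a6 = k3 * c1e * c5e

    # c1_ec
    J[0, 0] = -a1 - kD1
    J[0, 2] = -a5
    J[0, 3] = -a6
    J[0, 6] = kD1
    # c4_ec
    J[1, 1] = -km4 * c6e - k6 * c8e - kD4
    J[1, 3] = -km4 * c4e
    J[1, 4] = k4
    J[1, 5] = -k6 * c4e
    J[1, 9] = kD4
    # c5_ec
    J[2, 0] = -a1
    J[2, 2] = -a5 - kD5
    J[2, 3] = -a6
    J[2, 10] = kD5
    # c6_ec
    J[3, 0] = -a1
    J[3, 1] = -km4 * c6e
    J[3, 2] = -a5
    J[3, 3] = -a6 - km4 * c4e
    J[3, 4] = k4
    # c7_ec
    J[4, 0] = a1
    J[4, 1] = km4 * c6e
    J[4, 2] = a5
    J[4, 3] = a6 + km4 * c4e
    J[4, 4] = -k4 - kD7
    J[4, 12] = kD7
    # c8_ec
    J[5, 1] = -k6 * c8e
    J[5, 5] = -k6 * c4e

    # IC trimolecular term partials
    b1 = k3 * c5i * c6i
    b5 = k3 * c1i * c6i
    b6 = k3 * c1i * c5i

    # c1_ic
    J[6, 0] = kD1
    J[6, 6] = -k1 * c2 - k2 * c3 - b1 - kD1
    J[6, 7] = -k1 * c1i
    J[6, 8] = -k2 * c1i
    J[6, 10] = -b5
    J[6, 11] = -b6
    # c2
    J[7, 6] = -k1 * c2 + k2 * c3
    J[7, 7] = -k1 * c1i
    J[7, 8] = k2 * c1i
    # c3 = -d(c2)/dt
    J[8, 6] = k1 * c2 - k2 * c3
    J[8, 7] = k1 * c1i
    J[8, 8] = -k2 * c1i
    # c4_ic
    J[9, 1] = kD4
    J[9, 7] = -k5 * c4i
    J[9, 9] = -km4 * c6i - k5 * c2 - k6 * c8i - kD4
    J[9, 11] = -km4 * c4i
    J[9, 12] = k4
    J[9, 13] = -k6 * c4i
    # c5_ic
    J[10, 2] = kD5
    J[10, 6] = -b1
    J[10, 7] = k5 * c4i
    J[10, 9] = k5 * c2
    J[10, 10] = -b5 - kD5
    J[10, 11] = -b6
    # c6_ic
    J[11, 6] = -b1
    J[11, 9] = -km4 * c6i
    J[11, 10] = -b5
    J[11, 11] = -b6 - km4 * c4i
    J[11, 12] = k4
    # c7_ic
    J[12, 4] = kD7
    J[12, 6] = b1
    J[12, 9] = km4 * c6i
    J[12, 10] = b5
    J[12, 11] = b6 + km4 * c4i
    J[12, 12] = -k4 - kD7
    # c8_ic
    J[13, 9] = -k6 * c8i
    J[13, 13] = -k6 * c4i
    # sinks
    J[14, 1] = k6 * c8e
    J[14, 5] = k6 * c4e
    J[15, 9] = k6 * c8i
    J[15, 13] = k6 * c4i

    return J


def derivative(
    state: SystemState,
    phenotype: CellPhenotype,
    constants: ModelConstants,
) -> SystemState:
    """Rate of change of every field, M s-1, packaged as a SystemState."""
    y = state.to_vector()
    if not np.all(np.isfinite(y)):
        raise NumericInputError("state contains non-finite values")
    dy = rhs(0.0, y, _params(phenotype, constants))
    if not np.all(np.isfinite(dy)):
        raise NumericInputError("derivative is non-finite")
    return SystemState.from_vector(dy)
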