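# Methods

## Model

`ptlkin` integrates a mass-action reaction network for eight species —
H2O2 (c1), native catalase CATFe(III) (c2), compound I CATFe(IV)O·⁺ (c3),
peroxynitrite ONOO⁻ (c4), nitrite NO2⁻ (c5), H⁺ (c6), peroxynitrous acid
ONOOH (c7) and CO2 (c8) — in two well-mixed compartments, extracellular
(EC) and intracellular (IC), coupled only by first-order membrane diffusion
of species 1, 4, 5 and 7 with rate constants k_D,i. The diffusion flux
enters the EC and IC equations with identical magnitude and opposite sign;
no compartment volume ratio is modeled, so the two compartments have equal
effective volumes. The catalase two-step cycle (k1, k2), the
catalase-mediated peroxynitrite decomposition (k5) and the constant
mitochondrial H2O2 source k_P act only in the IC; ONOOH formation (k3), the
ONOOH/ONOO⁻ acid-base pair (k4, k−4) and the CO2-catalysed peroxynitrite
sink (k6) act in both compartments.

Assumptions worth keeping in view:

* H⁺ and CO2 are ordinary dynamic state variables starting at 10⁻⁷ M and
  10⁻³ M in both compartments; no buffering or clamping is applied, and
  non-negativity is monitored rather than enforced by projection. In
  practice both species barely move on the simulated horizon.
* ONOOCOO⁻ is treated as inert. Its cumulative production per compartment
  is tracked in two bookkeeping fields (`sink_ec`, `sink_ic`) so nitrogen
  mass balance is checkable; the radical chemistry it seeds (CO3·⁻, ·NO2)
  is deliberately outside this model.
* k_D,1 is static — no aquaporin gating, no treatment-induced
  permeabilisation — and k_P is constant in time.
* Rate constants are literature in-vitro values at their reported
  temperatures/pH; no temperature or pH corrections are applied.

## Initialisation

At t = 0 the medium carries the treatment dose (H2O2 at 1 µM or 1 mM,
NO2⁻ at 0 or 1 mM — four canonical regimes) and the cell is at rest: all
catalase native (c3 = 0), no peroxynitrite species, IC nitrite 10⁻⁴ M, and
IC H2O2 at the pre-treatment steady state

    c1_ss = kP / (k1·CAT0 + k3·c5_ic·c6_ic).

This closed form balances production against first-pass consumption under
the same c3 = 0 assumption used for the initial condition. It is *not* the
steady state of the full two-state catalase cycle (where part of the enzyme
sits as compound I); we use the closed form as the model's initial
condition and verify in tests that the full right-hand side vanishes on it
at t = 0, where the c3-dependent term drops out. With default constants
the k1 term dominates by ~7 orders of magnitude, so c1_ss ≈ kP/(k1·CAT0):
≈5.9×10⁻⁷ M at CAT0 = 10⁻⁸ M and ≈5.9×10⁻¹⁰ M at 10⁻⁵ M.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| k1, k2 | 1.7×10⁷, 2.6×10⁷ | M⁻¹s⁻¹ | mammalian catalase cycle |
| k3 | 1.1×10³ | M⁻²s⁻¹ | NO2⁻ + H2O2 + H⁺ → ONOOH |
| pKa | 6.8 | — | ONOOH acid dissociation |
| k₋₄ | 10¹⁰ | M⁻¹s⁻¹ | ONOO⁻ + H⁺ recombination |
| k5 | 1.7×10⁶ | M⁻¹s⁻¹ | catalase-mediated ONOO⁻ decay |
| k6 | 5.8×10⁴ | M⁻¹s⁻¹ | ONOO⁻ + CO2 |
| k_P | 10⁻⁷ | M s⁻¹ | mitochondrial H2O2 production |
| k_D,4 = k_D,5 = k_D,7 | 320 | s⁻¹ | membrane diffusion, ONOO⁻/NO2⁻/ONOOH |
| k_D,1 | 100–2000 (ref. 920) | s⁻¹ | H2O2 membrane diffusion (phenotype axis) |
| CAT0 | 10⁻⁸–10⁻⁵ | M | intracellular catalase (phenotype axis) |

The ONOOH pKa is quoted in the literature as 6.5–6.8 at 25 °C; the package
defaults to 6.8 and exposes it as a configuration parameter (k4 is always
derived as 10^(−pKa)·k₋₄, never set directly). k₋₄ is an order-of-magnitude
literature value, also configurable.

## Numerics

* **Solver.** `scipy.integrate.solve_ivp` with the BDF method and an
  analytic Jacobian (validated against central finite differences, which
  are exact here because every rate term is multilinear). Default
  tolerances rtol = 10⁻⁸, atol = 10⁻¹⁴ M — atol sits well below the
  smallest concentration of interest (~10⁻¹⁰ M). The governing contract is
  not a particular solver but stability: every measure must move < 0.5%
  under output-grid halving plus 10-fold tighter tolerances, which the
  test suite checks.
* **Output grid.** Three phases (10⁻⁷ s to 10 ms, 10⁻⁵ s to 1 s, 10⁻³ s to
  100 s; ~3×10⁵ points) filled by the solver's dense interpolant; internal
  steps are adaptive and independent of the grid. Sweeps use a 10×
  thinned grid (~3×10⁴ points) whose measures match the full grid well
  within the 0.5% stability budget — measures, not samples, are the
  product.
* **Measures.** Temporal maxima are refined by the parabola through the
  three samples bracketing the discrete argmax (earliest sample on ties);
  integrals use the trapezoidal rule on the non-uniform grid. The response
  time τ is the *last* time intracellular H2O2 crosses (1 + 0.1)·baseline
  from above (linear interpolation between samples), 0 if the band is
  never left, tf if never re-entered: a return-to-tolerance time. An
  alternative "literal" convention with the threshold at baseline/1.1 is
  available by configuration. The load-over-baseline integral is signed
  (no clipping of values below baseline). r̄ is the magnitude of
  |Δ[H2O2]_EC|/tf; r_max the maximal adjacent-sample difference quotient,
  cross-checked in tests against the vectorised instantaneous rate law;
  their inverses s̄, s_max are reported as missing (not infinite) when the
  rate is zero. Susceptibilities are defined on magnitudes since EC H2O2
  is consumed (the signed average rate is negative).
* **Oracle.** A fixed-step classical RK4 integrator (dt = 10⁻⁹ s) verifies
  the stiff solution on [0, 10⁻⁴ s]. The discrepancy is normalised per
  species by the species' maximal |value| over the window, floored at
  atol: species whose entire trajectory sits below the solver's absolute
  tolerance (e.g. EC ONOO⁻ peaks near 10⁻²¹ M on that window) carry no
  signal either integrator resolves.
* **Degenerate inputs.** Empty trajectories, non-positive tolerances,
  non-finite states and mis-ordered grids raise typed errors; failed sweep
  points are recorded with a `status` flag, never dropped.

## Sweeps

The default grid is 100×100 points, linear on both axes, over
k_D,1 ∈ [100, 2000] s⁻¹ and CAT0 ∈ [10⁻⁸, 10⁻⁵] M (log spacing available
per axis). The selectivity ratio compares c1_max at the cancer-like corner
(max k_D,1, min CAT0) with the normal-like corner (min k_D,1, max CAT0);
at low CAT0 the k_D,1-dependence is negligible, so the susceptible corner's
k_D,1 choice barely matters. Synergy is quantified as the per-point fold
change of a measure between sweeps with and without 1 mM extracellular
nitrite. Sweeps iterate in a fixed order, are resumable from their partial
TSV, and every record is independent of execution order.

Tests and the acceptance script use scaled-down grids — 10×10 for the
regime bounds and the corner ratio, 5×5 for the synergy folds — chosen
because the corner points are grid-size-invariant by construction and the
surfaces are smooth and monotone in between, which the monotonicity and
spread tests verify on the 10×10 grid.

## What the defaults do and do not show

All inputs are model constants and printed treatment regimes; there is no
synthetic data generator and no randomness anywhere — identical inputs
give bit-identical trajectories. Passing tests therefore demonstrate the
internal consistency and numerical convergence of *this* parameterisation,
not agreement with any particular cell line: real cells differ in far more
than two phenotype parameters, membrane permeability is dynamic under
oxidative stress, mitochondrial production is not constant, and the
ONOO⁻/CO2 radical chemistry is unmodeled. Known limitations: the
closed-form initial steady state ignores the compound-I fraction (see
above); the EC/IC equal-volume convention means extracellular depletion is
faster than for a cell in a large medium volume; and the k3 value is an
acidic-pH literature measurement applied at pH 7.
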