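# Methods

## The model

`qsmemory` studies phenotypic memory in the LuxR-LuxI quorum-sensing (QS)
circuit of *Aliivibrio fischeri*: history dependence of gene expression that
arises purely from carry-over of biomolecules across a dilution, not from
any genetic change.

The mechanistic core is a deterministic mass-action model of eight state
variables — LuxI synthase `I`, unbound LuxR `R`, signal-bound monomer `RA`,
transcription-activating dimer `C`, intracellular and extracellular
autoinducer `A`/`A_ex`, a QS target-gene product `G`, and the cell density
`N`:

```
dI/dt   = k5 + k3 C/(kdI + C) − (k7 + k11) I
dR/dt   = k6 + k4 C/(kdR + C) + k_m1 RA − k1 R A − (k8 + k11) R
dRA/dt  = 2 k_m2 C − 2 k2 RA² − k_m1 RA + k1 R A − k11 RA     [see below]
dC/dt   = k2 RA² − (k_m2 + k11) C
dA/dt   = b I − k1 R A + k_m1 RA − D (A − A_ex) − (k9 + k11) A
dA_ex/dt = r D N (A − A_ex) − k9 A_ex
dG/dt   = k10 + k4 C/(kdI + C) − (k7 + k11) G
dN/dt   = k11 N (1 − N/N_max)
```

Dimerisation consumes two bound monomers per complex; intra- and
extracellular signal exchange through the membrane at rate `D`, with the
medium coupled to the cells through the volume fraction `r·N`; growth is
logistic, and `k11` appears in every molecular equation as dilution by cell
division. `G` is a pure readout — it feeds nothing back. The default
parameter set (`qsmemory.circuit_defaults()`) is the published *V. fischeri*-inspired
set; production rates `k3–k6, k10` are in nM/min (the only dimensionally
consistent reading of the equations).

Because of the positive feedback (the dimer upregulates both LuxI and LuxR)
the circuit is bistable over a window of densities, roughly 10^8.8–10^9.5
cell/ml under the default parameters: both an activated (ON) and a basal
(OFF) molecular state are stable there.

### The monomer-degradation term

The one place where this implementation takes a documented stance is the
degradation of the signal-bound monomer `RA`. Applying the fast unbound-LuxR
degradation rate `k8 = 0.15/min` to `RA` as well drains the dimer reservoir
so quickly after dilution that the circuit retains **no** phenotypic memory
anywhere: initially-ON and initially-OFF populations produce identical
activation curves to 0.01 log10 resolution, and the re-activation transient
misses the switching threshold by ~40% in external signal. With `k8` acting
on unbound LuxR only (the default, `monomer_degradation=False`), the model
exhibits the full phenomenology this package exists to analyse: a wide
memory zone when diluting to 10^8.5 cell/ml, its collapse under
over-dilution, the LuxI fold change of ~10.6, the ~5-generation LuxI
carry-over and the ~1.6-generation unbound-LuxR peak. The reading is also
quantitatively consistent with the reduced theory's total-LuxR decay rate
`γ_R = 0.018/min`: the effective intrinsic degradation of the total pool is
`k8` times the unbound fraction at the ON state (0.15 × 0.0064 ≈ 0.001/min,
i.e. `γ_R = γ + 0.001`), whereas degrading `RA` too would give `γ_R ≈
0.026/min`. Setting `monomer_degradation=True` restores the alternative
form. A second switch, `g_activated_by_k3`, selects which activated rate
constant drives the target gene; the default uses `k4`, and the choice only
rescales the readout.

## Numerics

* **Integrator**: LSODA (automatic stiff/non-stiff switching) via
  `scipy.integrate.solve_ivp`; default tolerances rtol = 1e-8,
  atol = 1e-10 nM, both configurable. Final states are insensitive (<0.1%
  in `G`) to halving both tolerances; solver output is clipped at zero only
  when packaged into states, and the clip is a no-op at these tolerances.
* **Steady state** is operationalised as max |d/dt| < 1e-6 nM/min over the
  seven molecular species, integrating in 2×10^4-min chunks with a hard cap
  of 10^6 min. Near the saddle-node this is the conservative choice:
  activation just above the critical density can take arbitrarily long, so
  fixed-horizon protocols systematically overestimate the critical density
  (by ~0.2–0.3 decades at a 2000-min horizon).
* **Activity classification**: a state is ON iff
  `(G − G_OFF)/(G_ON − G_OFF) ≥ 0.5`, with the ON/OFF anchors grown from
  1 cell/ml (all molecular species zero) at carrying capacities 10^11 and
  10^7 cell/ml. Ties classify ON; the boundary case has measure zero.
* **Critical densities** are located by bisection over log10 `N_max` to
  0.01-decade resolution; memory-zone boundaries from a coarse activation
  sweep (default 41 grid points over 10^8.5–10^10.5) are refined the same
  way. Bisection assumes monotone activation along the curve, which holds
  for every tested parameter set.
* **Dilution** replaces `N` and resets `A_ex` to zero, leaving per-cell
  concentrations bit-exact — the defining perturbation of every protocol
  here.

## Decay analysis

Deactivation traces come from diluting the ON culture 10^11 → 10^6 cell/ml.
Each species is fitted to `C(t) = C_on e^{−γt} + C_off` by nonlinear least
squares; with anchors supplied (the ON/OFF reference concentrations) only
`γ` is free. Two conventions matter:

* **Fit windows.** The single-exponential model class is only valid for the
  activated species (LuxI, `G`) once activated production has collapsed;
  the window therefore starts when the dimer falls below `kdI/50`
  (~127 min post-dilution at the default parameters). For species with a
  transient peak (unbound LuxR) the window starts at the post-dilution
  maximum. So fitted, LuxI decays at 0.0227/min ≈ `k7 + k11`, and the
  fitted time to 1% residual is ln(100)/γ ≈ 5.0 generations. The raw
  trajectory crossing of the 1% level takes ~7 generations because of the
  production tail; both estimators are exposed
  (`fit_decay` / `generations_to_off`) and both are reported by
  `analysis/02_deactivation_decay.py`.
* **Maximum decay rates** (the per-species ranking) are computed from
  instantaneous slopes: central differences of the 5-point-smoothed
  log-excess over the OFF level, after the trace maximum. Ranking at the
  default parameters: internal AHL (≈3/min, membrane export) > dimer
  (≈0.14/min) > unbound LuxR (≈0.11/min) > LuxI (≈0.023/min, dilution by
  division only). A species already at its OFF level returns
  not-applicable.
* **Total LuxR** is `R + RA + 2C` (two protein units per dimer), with
  `R + RA + C` available as an option. The unbound-LuxR persistence
  statistic is the full width at half maximum of the `R(t) − R_OFF`
  excursion in doubling-time units (~1.6 generations at default
  parameters).

## Memory-zone mapping

Two populations with identical kinetics but different pasts (molecular
concentrations of the ON and the OFF reference) are diluted to a common
starting density and grown to a grid of carrying capacities; the memory
zone is the contiguous interval where their steady-state classifications
differ. Under the defaults, starting from 10^8.5 cell/ml the zone spans
10^8.83–10^9.51 cell/ml; from 10^7 cell/ml it is empty — carried LuxI
(~43-min lifetime) and dimers decay long before the culture re-enters the
bistable window. Component swaps replace individual species of one
initial state with the other's values; swapping either the dimer pool or
LuxI to OFF values collapses the zone to zero width, while swapping
unbound LuxR, the monomer or internal AHL leaves it essentially unchanged,
and OFF cells activate early only when given both ON LuxI and ON dimers.
The instant-dissociation transformation (bound pools disassembled into
unbound LuxR and free signal, two LuxR and two AHL units per dimer — the
AHL stoichiometry is configurable since one unit per dimer is equally
defensible) leaves the activation curve unchanged at 0.1-decade grid
resolution, which justifies the reduced theory's first assumption.

## The closed-form theory

After dilution to density `N_0`, per-cell LuxI and total LuxR relax as
single exponentials, `I(t) = I_OFF (1 + (FC−1) e^{−γt})` and
`R(t) = R_OFF (1 + (FC−1) e^{−γ_R t})`, sharing the fold change `FC`;
extracellular signal accumulates without degradation from exponentially
growing producers. The LuxI memory term
`ξ(t) = γ(FC−1)t/(e^{γt}−1)` (continuously extended to `FC−1` at `t = 0`)
is the ratio of carry-over-driven to basal signal accumulation, and the
overall memory term `Θ(t) = ξ + (FC−1)e^{−γ_R t}(1+ξ)` adds the receptor
surplus (note `Θ(0) = FC²−1`). Activation occurs when the binding rate
`v_cell b R_OFF I_OFF (N(t)−N_0)/γ (1+Θ)` crosses `R_OFF A_thresh` (the
binding-rate constant is 1 by convention and only ratios matter). This
gives `N_C = γA_thresh/(v_cell b I_OFF) + N_0` for naive cells, the
implicit `N_C′ = γA_thresh/(v_cell b I_OFF (1+Θ(t*))) + N_0` for
previously-ON cells, and the zone width
`N_C − N_C′ = γA_thresh/(v_cell b I_OFF) · Θ(t*)/(1+Θ(t*))`, always between
0 and the saturation width `γA_thresh/(v_cell b I_OFF)`.

Numerical choices:

* `t*` (the initially-ON activation time) is found by scanning for the
  **first** threshold crossing and polishing with Brent's method to
  10^-3 min. The scan matters: the binding rate is *not* monotone in
  general — at high `FC` the memory hump can cross the threshold early,
  dip, and cross again. The implicit-density route
  (`critical_density_on_implicit`) agrees with the time-root route to
  better than 0.1% and serves as a consistency check.
* The default parameter set (`qsmemory.analytical_defaults()`) is the published
  phase-diagram set: γ = 0.017/min (40-min doubling), γ_R = 0.018/min,
  FC = 10, b = 0.04/min, I_OFF = 1000 nM, A_thresh = 20 nM,
  v_cell = 10^-12 ml, N_0 = 10^8 cell/ml, 700-min growth window. Production
  rates β_I, β_R are the primary fields, so sweeps over the growth rate
  correctly carry the second-order `I_OFF = β_I/γ` dependence. R_OFF
  cancels from every activation condition; β_R = 18 nM/min fixes it at
  1000 nM for readability.
* **Phase diagrams** label, per axis value, region I (both histories OFF),
  II (memory) and III (both ON) over log10 density. A memory region is
  drawn only when the two boundaries are separated by at least the map
  resolution (0.01 log10 units) — the continuous width is never exactly
  zero for finite activation times, but at e.g. N_0 = 10^6 it is 0.0045
  decades, invisible at any plotting resolution. Columns where naive cells
  never activate within the horizon extend region II upward; columns where
  nobody activates stay region I.
* Monotonicity of the zone holds in log-density width: widening with `FC`
  and `b`, contracting with `A_thresh`, widening with doubling time up to
  ~65 min (beyond which the lower boundary saturates at the `N_0` floor).
  The *linear* width (cell/ml) is not monotone in `b` or `A_thresh`
  because the saturation prefactor moves opposite to `Θ`.
* Signal degradation is deliberately neglected here (unlike the ODE
  module's `k9`), following the reduced model's assumptions.

## Synthetic data

The decay fitter is exercised on traces drawn from its own model class with
multiplicative log-normal noise (`value = ideal · e^{σZ}`, σ = 0.02 by
default): concentrations are positive and fluorescence-like readout error
scales with signal. At σ = 0.02 and 200 samples the rate is recovered
within 5% in ≥95 of 100 seeds with <1% bias. Perturbed kinetic-parameter
sets are drawn log-uniformly (preserving the binding-constant identities
`k1 = k_m1/kd1`, `k2 = k_m2/kd2`) for robustness sweeps. Everything is
seeded and regeneration is byte-identical. What the generator does *not*
emulate: single-cell heterogeneity, graded population-level responses,
growth-phase-dependent rates, or any real instrument's measurement model —
passing the recovery study says the fitter is correct on its model class,
not that real deactivation curves are single exponentials.

## Known limitations

* Deterministic, well-mixed, two-compartment description only; no spatial
  signal gradients, no stochastic single-cell switching.
* The steady-state critical density from growth at 1 cell/ml is 10^9.51
  under the default reading (10^9.63 with `monomer_degradation=True`);
  horizon-truncated protocols report higher values, and the package always
  reports the converged number.
* The memory zone's boundaries are defined through the deterministic
  half-maximum classification; in a stochastic description they would
  blur into probabilistic switching regions.
* mRNA dynamics are folded into effective production rates; degradation
  rates are growth-phase independent by construction.

## Problem sizes

Default test and analysis runs use 11–41-point activation grids,
0.01–0.05-decade bisection resolutions, 100-seed recovery studies and
2000-point deactivation traces; the full test suite and all five analysis
drivers complete in well under a minute on one CPU.
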