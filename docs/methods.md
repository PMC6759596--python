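# Methods

`rootflux` simulates coupled ion (Na⁺, K⁺, Cl⁻, H⁺) and water transport in a
discretized *Arabidopsis* root under salt stress, and uses the model to ask
where plasma-membrane Na⁺/H⁺ antiporters (SOS1) act and what they do. This
note documents the model, its assumptions, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## The model

### Geometry

The root is a cylinder of `n_axial` single-cell-high layers (default 30,
layer 0 at the tip) and five concentric tissue rings — epidermis, cortex,
endodermis, xylem parenchyma, xylem — with default radii spanning a
110 µm root. The bottom `apex_layers` layers (default 5) form the
developmental apex; the rest are the mature zone. Each living cell ring in
a layer contributes three well-mixed compartments (apoplast 8%, cytosol 12%,
vacuole 80% of the annulus volume). In the mature zone the xylem ring is a
single apoplastic conduit carrying the transpiration stream to the shoot
boundary; in the apex it is a living cell (the "non-functional xylem").
Apex cells are much shorter than mature cells (default 30 µm vs 100 µm),
which is what gives the apex its characteristically larger membrane area
per gram fresh weight. Fresh weight is total compartment volume ×
1000 kg m⁻³ unless overridden.

Pathways: radial and axial apoplastic edges (wall continuum), plasmodesmata
between every pair of adjacent cytosols, one plasma membrane and one
tonoplast per cell, an external-medium boundary at the epidermal wall of
every layer, and the xylem-top boundary held at −0.3 MPa. Mature-zone
barriers: the Casparian strip blocks the radial apoplastic path across the
outer face of the endodermal wall (the inner face stays continuous with the
stelar apoplast), and suberin lamellae block endodermal plasma membranes
except in passage-cell layers (deterministically spaced; default fraction
0.1).

### Transport laws

* **Channels** (NSCC, inward/outward K⁺ rectifiers, HKT1;1, anion and H⁺
  leaks, tonoplast leaks): Goldman–Hodgkin–Katz constant-field flux, with
  two-state Boltzmann gating for the K⁺ rectifiers. The outward rectifier's
  midpoint tracks the apoplastic K⁺ Nernst potential; NSCC permeability is
  blocked hyperbolically by external Ca²⁺ (half-block 0.3 mM). HKT1;1 is a
  Na⁺-selective uniporter on mature xylem-parenchyma membranes; at the
  resting potential it retrieves Na⁺ from the stelar apoplast.
* **Pumps and symporters** (plasma-membrane and tonoplast H⁺ pumps, K⁺/H⁺
  and Cl⁻/2H⁺ symporters): four-state carrier cycles solved in closed form
  (King–Altman). Binding steps are pseudo-first-order in the substrate
  concentrations; the charge-translocating step carries symmetric Eyring
  voltage factors exp(±z_t F V / 2RT). The pump rate products encode an
  ATP-scale bias (~6×10⁷ per H⁺ for the plasma membrane; ~8×10³ per H⁺ for
  the tonoplast V-ATPase, which moves ~2 H⁺ per ATP); the symporters
  satisfy detailed balance exactly — they are passive, secondary-active
  carriers. The plasma-membrane pump binds cytosolic H⁺ with a rate that
  limits the cycle near pH 7, so pumping self-regulates cytosolic pH; in
  steady state the pumped H⁺ recirculates through the H⁺-coupled nutrient
  carriers and the H⁺ leak. Stelar membranes carry proportionally more
  pump (default 2×): the stelar apoplast has no contact with the buffered
  medium, so everything H⁺-coupled there — including SOS1 xylem loading —
  runs on locally pumped H⁺.
* **Antiporters** (SOS1 on plasma membranes, NHX-type Na⁺/H⁺ — mature zone
  only — and K⁺/H⁺ on tonoplasts): mass action, J = k_ap (c_in H_out −
  c_out H_in); 1:1 exchange carries no net charge. Wild-type SOS1 defaults:
  2×10⁻⁷ (outer tissues) and 3×10⁻⁷ m⁴ mol⁻¹ s⁻¹ (stele); the sos1 mutant
  retains a low residual activity (default 10%), because zero activity
  cannot reproduce mutant-like root contents.
* **Water**: Kedem–Katchalsky volume flux across plasma membranes and
  plasmodesmata (hydraulic + osmotic terms), osmotic-only across the
  tonoplast, hydraulic-only through walls and the conduit. Osmotic
  pressure is ideal van 't Hoff over all mobile species plus the fixed
  apoplastic charges and the proton buffer.
* **Wall/symplast solute transport**: electrodiffusion plus convection with
  species diffusivities scaled by pathway tortuosities.

### Electroneutrality, pressure, buffering

Local electroneutrality is imposed through a capacitive regularization:
each compartment carries a small electric capacitance (default
5×10⁻² F m⁻² of incident membrane area), so its potential is an explicit
function of the accumulated net charge, φ = F·V·ρ/C. Conductive pathways
drain any imbalance within milliseconds, keeping the net charge density
below the documented bound (`RootModel.electroneutrality_tolerance`,
≈0.1–0.3 mol m⁻³, i.e. relative to the ~10² mol m⁻³ ionic background a
residual of order 10⁻³) at every accepted step. This is the regularized
form of the index-1 DAE with algebraic potentials and turns the system into
a stiff ODE that the variable-order BDF solver integrates directly; the
capacitance value trades residual size against stiffness and is checked by
the electroneutrality test.

Hydraulic pressure is elastic: a cytosol and its vacuole share one turgor
computed from the combined protoplast volume (the wall confines the whole
protoplast; modulus 5 MPa), wall compartments are nearly rigid (50 MPa).
Protons are tracked as total H (free + bound); the free fraction is the
positive root of the single-buffer equilibrium. Buffer densities are set at
initialization to close the charge balance of the chosen initial
composition (cytosol pH 7.2, vacuole pH 5.5), so the buffer doubles as the
impermeant cytosolic anion background; apoplastic walls instead carry a
fixed anionic charge (default 2 mol m⁻³).

### State and integration

The state per compartment is the reference-volume-scaled amount of Na⁺,
K⁺, Cl⁻ and total H, plus the relative volume — conservation is exact by
construction, and a closed system conserves every species to <10⁻⁸
relative over 10⁶ s (tested). Edge solute fluxes use the
Scharfetter–Gummel exponential-fitting scheme (exact for constant
coefficients, smooth in all states, monotone in the advection-dominated
conduit); hard upwinding survives only on the purely advective xylem-top
outflow. Integration is `scipy` BDF with a grouped finite-difference
Jacobian on the model's sparsity pattern (fixed relative steps; the
solver's adaptive per-column factors misbehave on this widely scaled state
vector). Default tolerances rtol 10⁻⁶, atol 10⁻⁹ scaled by the initial
state; halving rtol moves day-one observables by <0.1%. The pre-salt
steady state is integrated from a documented uniform initial guess in
geometrically growing stages until the scaled rate norm max|ẏ|/max(|y|,1)
drops below 10⁻⁹ s⁻¹. Because the slowest proton modes relax on ~10⁶ s,
two different initial guesses agree at the steady state to ~0.5% on the
worst state (95% of states <10⁻⁴) — the practical uniqueness limit at that
rate tolerance. Headline 30-layer simulations in the test suite run at
rtol 10⁻⁵ with warm-started (but fully re-converged) steady states; a
15-day, 30-layer run takes a few minutes on one CPU.

## Calibration of the defaults

Most of the kinetic constants have no direct single-value measurements; the
defaults are this package's own calibration. They were chosen once, against
the standard experimental target structure — root Na⁺/K⁺
contents, epidermal transmembrane potentials, xylem sap concentrations, and
a Na⁺ flux to the shoot of ≈50 nmol min⁻¹ g(FW)⁻¹ in the 50 mM NaCl /
11.9 mM KCl / 0.5 mM Ca / pH 5.5 medium — plus physiological resting
behavior: Vm ≈ −50 to −90 mV depending on external K⁺ (≈ −90 mV in 0.5 mM
KCl), cytosolic pH ≈ 7.3–7.5, apoplastic pH ≈ 5.1–5.7, cytosolic K⁺ ≈
90–100 mM, and salt-step depolarization by tens of mV. The calibrated
values live in `parameters.ModelParams` with units in the docstrings; the
antiporter strengths, strength grid and scenario set are fixed by the study
design and were not adjusted.

## Two-stage optimization

The fit exploits the structural separation that outer-root transport
shapes every observable while stelar transport only shapes xylem
concentrations and fluxes to the shoot. Stage "outer" fits outer-tissue
parameters to root contents and epidermal potentials; stage "stele"
freezes them and fits stelar parameters to xylem concentrations and the
Na⁺ flux to the shoot (running the stele stage first is rejected). The
objective is weighted relative least squares; parameters are fitted in
log₁₀ space with bounded trust-region least squares and seeded
Latin-hypercube multi-start (default 8 starts; all starts logged, best
reported). Local identifiability is reported from the Fisher information
matrix in log-parameter space (condition number and eigenvalue floor), not
assumed. A sensitivity screen (central differences of normalized target
sensitivities in log-parameter space) ranks candidate parameters before
fitting; parameters whose perturbed runs fail are flagged, never silently
dropped.

## Synthetic targets

`synthetic_data` emulates the experimental target table by forward
simulation at known "true" parameters under the four bundled media
(50/11.9/0.5/pH 5.5; 50/2/2/pH 4.4; 100/7.5/0.8/pH 5.7; 50/0.5/0.1/pH 5.5
— NaCl/KCl/Ca in mM) for wild-type and sos1 genotypes, perturbed by
multiplicative lognormal noise (all targets are positive and span decades).
A fixed seed reproduces the table bit-for-bit, and identical conditions
share one simulation. What passing recovery tests show is that the
optimizer can find parameters the model itself generated under realistic
ionic regimes; they do not show that real inter-laboratory scatter is
lognormal, that real measurements are as internally consistent as a forward
model, or that the real root's parameters are identifiable from this few
observables.

## Observables and conventions

"Day d" means d × 86 400 s after the salt-medium switch (instantaneous by
default; a linear ramp option exists). Flux to the shoot is the
(advective) species flow through the xylem-top boundary; at steady state it
equals the net surface influx to 10⁻⁶ relative (tested per species). Mean
cytosolic concentrations are volume-weighted (the per-cell alternative is
not implemented; flagged here because the averaging convention is not
uniquely determined by the study design). Zone surface efflux is the *net*
flux across the external boundary of a zone (positive outward) and
partitions exactly into the whole-root surface flux; the tracer-comparable
quantity is `zone_tracer_efflux`, the unidirectional outward plasma-membrane
Na⁺ flux of the outer tissues per zone fresh weight (antiporter efflux plus
net-outward channel flux) — net fluxes cannot be
positive in both zones while the root is a net absorber, which is why the
efflux-experiment comparison uses the gross quantity. Reporting units
(nmol min⁻¹ g⁻¹, µmol g⁻¹, mM) are converted in `units` with round-trip
tests.

## Scenario analysis

Seventeen SOS1 spatial patterns (four mature-individual, five
apex-individual including the non-functional xylem, four mature
combinations, two mature-and-apex combinations, all-apex, all-tissues) are
crossed with strengths {1, 10, 100, 1000}×10⁻⁸ m⁴ mol⁻¹ s⁻¹. Mature
patterns carry no apex antiporters and vice versa. A sweep produces one
row per (pattern, strength) with content, fluxes and cytosolic means;
failures are flagged per row. "Reasonable" scenarios have both root Na⁺
content and Na⁺ flux to shoot within 50% (inclusive, with a 10⁻⁹ roundoff
guard) of the wild-type reference, which is a configuration input (the
shipped tests use the synthetic generator's reference).

## Known limitations

* The apoplastic bypass at the unsuberized apex is coarse: five discrete
  layers with an 8% wall fraction overestimate the axial wall conductance
  compared to a real maturation gradient, so apex *net* fluxes carry more
  bypass flow than a finer-grained root would show.
* The salt-step epidermal potential shows the large rapid depolarization
  but only a weak partial recovery at default parameters.
* Gating is instantaneous (no channel kinetics), temperature is fixed, and
  Ca²⁺ enters only as an external modifier of NSCC permeability.
* Cl⁻ is the only mobile anion, so its concentrations absorb the role of
  all free anions wherever electroneutrality demands it.
* The capacitive electroneutrality regularization leaves a documented
  nonzero charge-density residual (relative ~10⁻³); potentials are
  correspondingly smoothed on millisecond scales.
* Steady-state uniqueness is limited to ~0.5% on the slowest proton states
  at the 10⁻⁹ s⁻¹ rate criterion.
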