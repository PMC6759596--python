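# rootflux

Biophysical simulation of coupled ion (Na⁺, K⁺, Cl⁻, H⁺) and water transport
in a salt-stressed *Arabidopsis* root, built to ask where the plasma-membrane
Na⁺/H⁺ antiporter SOS1 operates and what it does: exclude Na⁺ from root
cytosols, load (or unload) the xylem transpiration stream, and shape Na⁺ and
water delivery to the shoot.

The package is for plant membrane-transport physiologists and modelers who
want a mechanistic, tissue-resolved root: 30 axial cell layers × five tissue
rings (epidermis, cortex, endodermis, xylem parenchyma, xylem), each living
cell split into apoplast, cytosol and vacuole, with a developmental apex
(no Casparian strip, no suberin, living "non-functional" xylem) below a
mature zone whose xylem is an open conduit held at −0.3 MPa at the top.

## The model in brief

Per compartment the model tracks the amounts of Na⁺, K⁺, Cl⁻ and total H⁺
plus the volume. Fluxes follow the field's standard laws:

* channels: Goldman–Hodgkin–Katz constant-field flux
  J = P·u·(c_in − c_out·e^(−u))/(1 − e^(−u)), u = zFV/RT, with two-state
  Boltzmann voltage gating for the K⁺ rectifiers, an apoplastic-K⁺-tracking
  midpoint for the outward rectifier, and hyperbolic external-Ca²⁺ block of
  the nonselective cation channels;
* pumps and symporters: four-state carrier cycles, J = N·(k₁₂k₂₃k₃₄k₄₁ −
  k₂₁k₃₂k₄₃k₁₄)/Σ (King–Altman), with symmetric Eyring voltage factors on
  the charge-translocating step;
* antiporters (SOS1, NHX): mass action, J = k_ap·(Na_in·H_out − Na_out·H_in);
* water: Kedem–Katchalsky Jv = Lp·(ΔP − σΔπ) across membranes (osmotic-only
  across the tonoplast, hydraulic-only through walls), π = RT·Σc;
* walls and symplast: electrodiffusion + convection (Nernst–Planck),
  discretized with the Scharfetter–Gummel exponential-fitting scheme.

Electric potentials enforce local electroneutrality through a capacitive
regularization (potential = accumulated net charge / compartment
capacitance), turning the index-1 DAE into a stiff ODE solved with
variable-order BDF. Protons are buffered in cytosols and vacuoles; walls
carry fixed anionic charge. See `docs/methods.md` for assumptions,
parameter defaults with units, and limitations.

On top of the simulator sit the study-design layers: the 17 SOS1
spatial-placement scenarios × strength grid {1, 10, 100, 1000}×10⁻⁸
m⁴ mol⁻¹ s⁻¹ with a "within 50% of wild type" reasonableness classifier
(`scenarios`), a two-stage parameter estimation with sensitivity screening
(`optimize`), and a synthetic experimental-target generator that makes the
whole pipeline testable offline (`synthetic_data`).

## Worked example

```python
from rootflux import build_root_grid, apply_barriers, RootModel, Protocol
from rootflux.parameters import BoundaryConditions, ModelParams, TransporterDistribution
from rootflux.simulate import (solve_presalt_steady_state, run_protocol,
    flux_to_shoot_nmol_min_g, root_ion_content_per_fw, water_flux_to_shoot,
    epidermal_membrane_potential, xylem_sap_concentration)

geometry = build_root_grid(n_axial=30, apex_layers=5)
graph = apply_barriers(geometry)
params = ModelParams()
pre = BoundaryConditions(NaCl=0.5, KCl=11.9, Ca=0.5, pH=5.5)
salt = BoundaryConditions(NaCl=50.0, KCl=11.9, Ca=0.5, pH=5.5)

model = RootModel(geometry, graph, params,
                  TransporterDistribution.wild_type(params), pre)
y0 = solve_presalt_steady_state(model, pre)

day = 86400.0
protocol = Protocol(pre_salt=pre, salt=salt, salt_onset=0.0,
                    duration=2 * day, output_times=[0.0, 2 * day])
traj = run_protocol(model, y0, protocol)

t = 2 * day
print(f"epidermal potential (pre-salt): {1e3 * epidermal_membrane_potential(traj, 0.0, 20):.0f} mV")
print(f"root Na+ content (day 2):       {1e3 * root_ion_content_per_fw(traj, t, 'Na'):.1f} umol/gFW")
print(f"xylem sap Na+ (day 2):          {xylem_sap_concentration(traj, t, 'Na'):.1f} mM")
print(f"Na+ flux to shoot (day 2):      {flux_to_shoot_nmol_min_g(traj, t, 'Na'):.1f} nmol/min/gFW")
```

prints (a few minutes on one CPU):

```
epidermal potential (pre-salt): -44 mV
root Na+ content (day 2):       34.2 umol/gFW
xylem sap Na+ (day 2):          9.3 mM
Na+ flux to shoot (day 2):      51.8 nmol/min/gFW
```

The resting potential is moderately polarized in this K⁺-rich medium and
depolarizes under salt; two days of 50 mM NaCl load the root to ~34 µmol
Na⁺ per g fresh weight and deliver Na⁺ to the shoot at ~52 nmol min⁻¹
g(FW)⁻¹ through a ~9 mM xylem sap — the scale reported for salt-stressed
*Arabidopsis*.

A command-line interface wraps the same pipeline:

```bash
rootflux run   --config config.yaml --out out/          # steady state + protocol
rootflux sweep --config config.yaml --out sweep.csv     # 17 patterns x 4 strengths
rootflux fit   --config config.yaml --targets targets.csv --out fit/
rootflux synth --preset toy --noise 0.1 --seed 7 --out targets.csv
```

Configs are YAML with explicit units ("50 mM", "-0.3 MPa", "1 day"); every
command writes a provenance block (config hash, version, seed) next to its
outputs.

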