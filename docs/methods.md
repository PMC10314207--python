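# Methods

## Scope and model structure

gastrosim simulates a two-vessel bench apparatus for interconnected
gastrointestinal dissolution and permeation: a stirred stomach reactor empties
into a small duodenal donor compartment wrapped in a dialysis membrane
(molecular-weight cut-off ≈ 3.5 kDa) that sits inside a larger acceptor vessel
containing a surfactant sink. The state is a set of amounts (μmol): suspended
solid, dissolved drug and co-dosed binder in the stomach; the same plus bile
salts in the duodenum; permeated drug in the acceptor; and cumulative ledgers
for duodenal waste and withdrawn samples. Volumes are in mL, flows in mL/min,
time in min, concentrations in μM (bile and binder in mM); flow·concentration
products carry an explicit 10⁻³ mL→L factor only where concentrations in μM
multiply volumes in cm³.

The stomach volume is a closed-form forcing function rather than a state:
fasted, `V(t) = V_fast + V_dose·e^(−kt)` with `k = ln2/T_1/2` (half-time
19 min by default), so emptying is `F2 = k·V_dose·e^(−kt) + F1` and the
volume derivative equals F1 − F2 identically; fed, the volume is constant
during a lag (15 min) and then declines linearly while
`F2 = F1 + V_dose/T_empty` until the dose volume is gone. Sampling
replacement keeps volumes unchanged, which preserves the closed form.

## Duodenal secretions and the bile program

Total duodenal secretion is constant (F3 = 2.5 mL/min fasted, 8 mL/min fed).
When a dynamic bile profile is requested, F3 is split between a bile-bearing
secretion medium (stock concentration `bile_stock_mM`) and a bile-free buffer
by inverting the duodenal bile balance at quasi-steady state,

    F3−1(t) = (F4·target(t) + V_duo·d target/dt) / stock,

clamped to [0, F3]; an unreachable target raises a warning and is clamped.
The bile amount is itself integrated as a state, so the realized concentration
is an outcome of the mass balance, not an imposed value. The fed stock is
32 mM (oxgall 17.48 g/L at an assumed mean bile-salt molar mass ≈ 546 g/mol;
the value is a config parameter because that conversion is an assumption),
chosen so the 15.4 mM plateau is reachable at F3 = 8 mL/min including the
ramp term. The fasted stock (6 mM) keeps the quasi-steady fasted duodenal
level near 3 mM. Whether secretions pause during the fed gastric lag is
configurable; by default all pumps start at the end of the lag.

## Stomach pH program

Fasted and carbohydrate-meal runs hold the gastric setpoint at pH 1.6. The
protein-meal run uses a logistic decline from 4.6 to 1.6; only the endpoints
and the span are physically constrained, so the midpoint (duration/2) and
steepness (0.045 min⁻¹, placing both ends within 1% of their asymptotes over
240 min) are exposed as configuration. The duodenal pH is held at its
setpoint (6.5 fasted, 5.8 fed) with no transient, as the bench device
controls it actively.

## Drug-state model

Solubility of an n-protic weak base follows Henderson–Hasselbalch,
`S(pH) = S0·(1 + Σ_j 10^(Σ_{i≤j} pKa_i − j·pH))`, capped at a salt-limited
ceiling `S_salt_cap` because the acidic branch otherwise diverges while real
low-pH solubility is bounded by the salt form. Apparent solubility adds
micellar and excipient solubilization,
`S_app = S(pH)·(1 + SR_bile·bile·f_s + bound/free(binder))`.

The binder isotherm doubles as the free-fraction model: `bound/free = K·B`
(linear) or `(K·B)^n` (hill, cooperative higher-order complexes), so one
constant controls both the solubility gain and the loss of permeating free
drug — the mechanism behind the solubility–permeability interplay. The binder
is an inert co-solute advected by the same flows as the drug, so its
intraluminal dilution (and the resulting collapse of solubilization when a
cyclodextrin dose is chased with water) emerges mechanistically.

Bile-salt effects are split into two per-protocol multipliers on the drug's
per-mM solubilization ratio, because the fed observations require bile plus
food components to act together: `bile_solub_factor` scales the
apparent-solubility term and `bile_entrapment_factor` scales the bile term in
the free-fraction denominator. Fasted and carbohydrate-meal runs use
entrapment 0 (fasted-level micelles barely restrict permeation); the
protein-meal run uses factors calibrated to the ~6-fold fed/fasted
intestinal-fluid solubility ratio; the carbohydrate high-bile run scales the
solubility term down (factor 0.2) so that elevated bile without food behaves
like fasted bile, matching the observation that high- and low-bile
carbohydrate runs are nearly equivalent.

No mechanistic rate law is available for interconversion between solid and
dissolved drug in this setting, so first-order (Noyes–Whitney-like) laws with
separate constants are used: dissolution `k_diss·(S_app − C)·V·10⁻³` while
solid remains, precipitation `−k_prec·(C − S_app)·V·10⁻³` once C exceeds an
induction threshold `DS_crit·S_app`. `DS_crit` defaults to 1; the
itraconazole parameter set uses 3 because cyclodextrin stabilizes moderate
gastric supersaturation (the with-water gastric solution sits at DS ≈ 2.8 and
must not nucleate, while duodenal DS far exceeds the threshold and
precipitates).

Permeation is `J = P_eff·A·(C_free,donor − C_free,acceptor)·10⁻³` with
A = 65 cm²; the acceptor is treated as a perfect sink by default (finite sink
binding is available as an option). P_eff is an *effective device*
permeability of the dialysis membrane, not an epithelial permeability; the
indinavir default (4.5·10⁻⁴ cm/min) puts the fasted permeate AUC on the
scale observed in such devices (~1.6·10³ μM·min over 4 h).

## Numerics

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 10⁻⁸, atol 10⁻¹⁰,
dense output every 0.5 min; all configurable), restarted at every breakpoint:
fed lag start and end, bile-profile nodes, and each sampling event. A
sampling event removes `v/V` of every suspended and dissolved species in each
vessel (1 mL of 55–705 mL stomach, 30 mL duodenum, 300 mL acceptor — small
individually but cumulative over 13–17 samples) and credits the withdrawn
drug to the sample ledger; reported sampled-table values are pre-event, as an
assay would see them. Two regularizations apply inside the ODE right-hand
side only (the exported rate functions implement the exact laws): the
dissolution term is gated by `solid/(solid + 10⁻⁶·dose)` so the vector field
stays continuous when solid depletes, and the precipitation induction switch
ramps in linearly over 5% of the threshold; without them the integrator's
step size collapses at the switching surfaces. Mass conservation (dose =
stomach + duodenum + acceptor + waste + sampled) holds to ≲10⁻¹³ relative in
the packaged scenarios and is asserted at 10⁻⁶ in the tests.

## Calibration

Transfer parameters (T_1/2, F1, F3, lag, emptying window) are estimated from
inert-marker curves — a fully soluble, non-permeating tracer whose
concentrations depend only on volumes and flows — and drug parameters
(P_eff, k_prec, binder affinity) from drug tables pooled across stomach,
duodenum and permeate series. Residuals are taken in log-concentration by
default to balance series spanning three orders of magnitude; the optimizer
is bounded least-squares (lmfit) with three seeded multi-starts. Fitting
P_eff without a permeate series triggers a structural-identifiability
warning. In-vivo marker reference curves are not distributed with the
package, so calibration is exercised on synthetic targets.

## Synthetic data

The generator reproduces the wet-lab measurement design: triplicate runs,
1 mL samples with replacement at the protocol times (13 for the 180-min
design, 17 for the 240-min designs), total vs solute vs permeated series, and
independent multiplicative lognormal noise per observation (CV 5% by
default), mean-one so replicate averages converge to the deterministic
trajectory; lognormal noise keeps concentrations positive across the dynamic
range. Values below the assay limit of quantification (defaults 0.024 μM
itraconazole, 0.050 μM indinavir) can be censored to a `<LOQ` marker on
export. What the generator does *not* emulate: analytical drift,
between-replicate biological variability of the media, pH-control transients,
or membrane fouling — so passing recovery tests demonstrates estimator
correctness under the stated noise model, not robustness to those real-data
features.

Problem sizes used in the shipped studies: single deterministic runs for the
six scenarios (each < 1 s), and 20-seed recovery studies with triplicates at
5% noise for the calibration checks.

## Known limitations

- Total gastric concentrations are exact under pure dilution, but the full
  duodenal concentration curves depend on the chosen kinetic constants; the
  shipped parameter sets reproduce scales and orderings, not digitized
  curves.
- The thermodynamic-solubility series reported for itraconazole is dominated
  by the hill binder isotherm; its absolute level is qualitative.
- The two bile multipliers encode the food dependence phenomenologically; no
  attempt is made to model micelle/vesicle speciation.
- Acid–base titrant volumes, buffer chemistry and enzymatic activity are out
  of scope; pH and bile are imposed programs, as in the physical device.
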