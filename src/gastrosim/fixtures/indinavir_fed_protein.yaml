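# Fed protein meal: dose with 400 mL nutritional drink + 250 mL water (V_dose 650 mL),
# 15 min gastric lag then linear emptying of the dose over 240 min; stomach pH falls
# sigmoidally 4.6 -> 1.6; duodenal bile tracks the fed profile (3 -> 15.4 -> 3 mM).
name: indinavir_fed_protein
prandial_state: fed
V_fast: 55.0
V_dose: 650.0
V_duo: 30.0
V_sink: 300.0
dose_umol: 977.517
dose_form: suspension
binder_dose_umol: 0.0
F1: 2.5
lag: 15.0
dose_empty_minutes: 240.0
F3_total: 8.0
bile_stock_mM: 32.0
bile_init_mM: 3.0
bile_profile: [[0.0, 3.0], [15.0, 3.0], [25.0, 15.4], [65.0, 15.4], [100.0, 3.0]]
bile_tracking: true
stomach_pH_schedule: {kind: sigmoid, start: 4.6, end: 1.6, steepness: 0.045}
duodenal_pH: 5.8
# food components + bile: solubilization calibrated to the 6-fold fed/fasted
# intestinal-fluid solubility ratio; colloidal entrapment active.
bile_solub_factor: 1.86
bile_entrapment_factor: 1.9
sampling_times: [7, 15, 30, 45, 60, 75, 90, 105, 120, 135, 150, 165, 180, 195, 210, 225, 240]
sample_volume: 1.0
duration: 240.0
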