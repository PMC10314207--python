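# Fasted cyclodextrin-based itraconazole solution, 20 mL dose, no water.
# 200 mg itraconazole (MW 705.6) = 283.447 umol; 8 g 2-HP-b-CD (mean MW ~1396) = 5731 umol.
name: sporanox_fasted_nowater
prandial_state: fasted
V_fast: 55.0
V_dose: 20.0
V_duo: 30.0
V_sink: 300.0
dose_umol: 283.447
dose_form: solution
binder_dose_umol: 5731.0
F1: 2.5
T_half: 19.0
F3_total: 2.5
bile_stock_mM: 6.0
bile_init_mM: 3.0
bile_profile: [[0.0, 3.0]]
bile_tracking: false
stomach_pH_schedule: {kind: constant, value_pH: 1.6}
duodenal_pH: 6.5
bile_solub_factor: 1.0
bile_entrapment_factor: 0.0
sampling_times: [7, 15, 30, 45, 60, 75, 90, 105, 120, 135, 150, 165, 180]
sample_volume: 1.0
duration: 180.0
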