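# Indinavir: weak base, pKa 3.7/5.9; S0 anchored to 50 uM at pH 6, salt-limited
# ceiling 162 mM at low pH; SR_bile calibrated so apparent solubility at pH 6.5
# with 3 mM bile matches the 84 uM measured in fasted human intestinal fluid.
name: indinavir
MW: 613.8
pKa: [3.7, 5.9]
S0: 27.81
S_salt_cap: 162000.0
SR_bile: 0.471
binder: {type: none}
k_diss: 1.5
k_prec: 0.08
DS_crit: 1.0
# effective permeability of the device's dialysis membrane for indinavir
P_eff: 4.5e-4
A: 65.0
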