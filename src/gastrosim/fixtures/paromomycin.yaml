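# Inert transfer marker: highly soluble aminoglycoside, not absorbed; its
# intraluminal concentrations reflect only volumes and flows.
name: paromomycin
MW: 615.6
pKa: []
S0: 1.0e9
S_salt_cap: 1.0e9
SR_bile: 0.0
binder: {type: none}
k_diss: 0.0
k_prec: 0.0
DS_crit: 1.0
P_eff: 0.0
A: 65.0
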