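# Itraconazole: lipophilic weak base, pKa 2.0/3.7, dosed as a 40% 2-HP-b-CD solution.
# S0 anchored so the pH 1.6 solubility matches the ~2.7 uM measured in simulated
# fasted gastric fluid; the hill isotherm (n=2) models higher-order cyclodextrin
# complexes, which both solubilize the drug and suppress its free fraction.
# DS_crit 3 reflects cyclodextrin-stabilized gastric supersaturation.
name: itraconazole
MW: 705.6
pKa: [2.0, 3.7]
S0: 0.0061
S_salt_cap: 10.0
SR_bile: 0.5
binder: {type: hill, K_per_mM: 2.0, n: 2}
k_diss: 2.0
k_prec: 0.05
DS_crit: 3.0
P_eff: 5.0e-3
A: 65.0
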