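scenario,compartment,measure,auc,units
indinavir_fasted,stomach,total,139394.8,uM*min
indinavir_fasted,stomach,solute,142108.9,uM*min
indinavir_fasted,duodenum,total,105320.9,uM*min
indinavir_fasted,duodenum,solute,55044.5,uM*min
indinavir_fasted,permeate,total,1641.7,uM*min
indinavir_fed_protein,stomach,total,194925.5,uM*min
indinavir_fed_protein,stomach,solute,168321.9,uM*min
indinavir_fed_protein,duodenum,total,72487.6,uM*min
indinavir_fed_protein,duodenum,solute,36225.8,uM*min
indinavir_fed_protein,permeate,total,450.4,uM*min
indinavir_fed_carb_highbile,stomach,total,171046.4,uM*min
indinavir_fed_carb_highbile,stomach,solute,184961.8,uM*min
indinavir_fed_carb_highbile,duodenum,total,70237.6,uM*min
indinavir_fed_carb_highbile,duodenum,solute,64432.4,uM*min
indinavir_fed_carb_highbile,permeate,total,1061.8,uM*min
indinavir_fed_carb_lowbile,stomach,total,182081.8,uM*min
indinavir_fed_carb_lowbile,stomach,solute,178266.3,uM*min
indinavir_fed_carb_lowbile,duodenum,total,74067.6,uM*min
indinavir_fed_carb_lowbile,duodenum,solute,59651.5,uM*min
indinavir_fed_carb_lowbile,permeate,total,1112.2,uM*min
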