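scenario,compartment,measure,auc,units
sporanox_fasted_nowater,stomach,total,73601.0,uM*min
sporanox_fasted_nowater,stomach,solute,70658.6,uM*min
sporanox_fasted_nowater,duodenum,total,45544.5,uM*min
sporanox_fasted_nowater,duodenum,solute,11878.6,uM*min
sporanox_fasted_nowater,permeate,total,8315.5,nM*min
sporanox_fasted_water,stomach,total,40478.0,uM*min
sporanox_fasted_water,stomach,solute,37434.3,uM*min
sporanox_fasted_water,duodenum,total,30930.9,uM*min
sporanox_fasted_water,duodenum,solute,5212.8,uM*min
sporanox_fasted_water,permeate,total,8050.8,nM*min
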