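biome,n_withheld,pred_mean,obs_mean,sd,pred_sum,obs_sum,sd_sum
Boreal forests,1116,98157,94459,1168,109542928,105416204,1303045
Deserts,2921,28115,24337,235,82122745,71089686,685260
Flooded grasslands,55,47691,50576,2894,2623006,2781658,159169
Mangroves,,,,,,,
Mediterranean forests,3333,99681,87080,902,332235677,290238564,3006751
Montane grasslands,28,88356,83125,6583,2473968,2327500,184337
Temperate broadleaf,54681,49524,48548,108,2708012198,2654674881,5892683
Temperate conifer,16808,43864,42661,132,737265239,717049203,2224412
Temperate grasslands,3415,30406,28215,264,103835175,96353092,900426
Tropical coniferous,,,,,,,
Tropical dry,17,48525,30938,4083,824925,525938,69415
Tropical grasslands,148,32038,26504,1130,4741584,3922520,167309
Tropical moist,1017,80839,77722,795,82212834,79043004,808476
Tundra,430,105216,105973,1815,45242812,45568300,780448
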