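biome,n_plots,total_billions,margin_billions,substituted
Boreal forests,8688,749.3,50.1,False
Deserts,14637,53.0,2.9,False
Flooded grasslands,271,64.6,14.2,False
Mangroves,21,8.2,0.3,True
Mediterranean forests,16727,53.4,1.2,False
Montane grasslands,138,60.3,24.0,False
Temperate broadleaf,278395,362.6,2.9,False
Temperate coniferous,85144,150.6,1.3,False
Temperate grasslands,17051,148.3,4.9,False
Tropical coniferous,,22.2,0.4,True
Tropical dry,115,156.4,63.4,False
Tropical grasslands,999,318.0,35.5,False
Tropical moist,5321,799.4,24.0,False
Tundra,2268,94.9,6.3,False
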