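class,experiment,nu,tau,kappa,reference_source
Grassland,SM,1545.8,,3.90,FLUXNET
Cropland,SM,7997.9,,0.20,FLUXNET
Savanna,SM,9770.4,,-0.10,FLUXNET
Shrubland,SM,4390.4,,0.60,FLUXNET
DeciduousForest,SM,10059.1,,-0.03,FLUXNET
EvergreenForest,SM,7147.7,,0.50,FLUXNET
MixedForest,SM,7488.6,,0.30,FLUXNET
Grassland,ST,,0.002,3.90,FLUXNET
Cropland,ST,,0.009,0.40,FLUXNET
Savanna,ST,,0.01,-0.09,FLUXNET
Shrubland,ST,,0.003,0.90,FLUXNET
DeciduousForest,ST,,0.01,0.01,FLUXNET
EvergreenForest,ST,,0.01,0.40,FLUXNET
MixedForest,ST,,0.01,0.40,FLUXNET
Grassland,SMST,2790.4,-0.0023,3.96,FLUXNET
Cropland,SMST,8588.3,-0.0008,0.20,FLUXNET
Savanna,SMST,10321.2,-0.0009,-0.07,FLUXNET
Shrubland,SMST,5059.4,-0.001,0.72,FLUXNET
DeciduousForest,SMST,11684.6,-0.003,0.02,FLUXNET
EvergreenForest,SMST,4505.6,0.005,0.44,FLUXNET
MixedForest,SMST,10214.6,-0.005,0.30,FLUXNET
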