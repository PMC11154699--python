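class,product,gamma,c
Grassland,gosif,22.03,1.12
Cropland,gosif,22.22,1.01
Savanna,gosif,22.27,1.39
Shrubland,gosif,21.75,1.69
DeciduousForest,gosif,22.30,1.41
EvergreenForest,gosif,21.98,2.57
MixedForest,gosif,22.02,2.40
Grassland,troposif,7.84,0.40
Cropland,troposif,4.81,0.22
Savanna,troposif,5.12,0.32
Shrubland,troposif,5,0.39
DeciduousForest,troposif,5.35,0.34
EvergreenForest,troposif,5.47,0.64
MixedForest,troposif,5.59,0.61
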