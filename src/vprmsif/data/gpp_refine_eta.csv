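class,product,eta
Grassland,troposif,3.2
Cropland,troposif,1.6
Savanna,troposif,3.7
Shrubland,troposif,3.3
DeciduousForest,troposif,2.4
EvergreenForest,troposif,1.7
MixedForest,troposif,2.3
Grassland,gosif,3.3
Cropland,gosif,1.7
Savanna,gosif,2.3
Shrubland,gosif,2.2
DeciduousForest,gosif,1.7
EvergreenForest,gosif,1.2
MixedForest,gosif,1.5
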