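class,s,r2,n
Grassland,2.81,0.22,
Cropland,4.62,0.45,
Savanna,4.35,0.56,
Shrubland,4.35,0.62,
DeciduousForest,4.17,0.56,
EvergreenForest,4.02,0.52,
MixedForest,3.94,0.55,
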