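class,set,lambda,swdown0,alpha,beta
Grassland,tropical,0.13,157,0.026,0
Cropland,tropical,0.12,646,0.004,0
Savanna,tropical,0.11,682,0.004,0
Shrubland,tropical,0.08,303,0.02,0
DeciduousForest,tropical,0.17,324,0.32,0
EvergreenForest,tropical,0.21,501,0.16,0
MixedForest,tropical,0.25,206,0.34,0
Grassland,european,-0.17,229.1,0.08,0.58
Cropland,european,-0.13,690.3,0.16,-0.01
Savanna,european,-0.11,682,0.004,0
Shrubland,european,-0.08,363,0.02,0
DeciduousForest,european,-0.19,271.4,0.14,0.82
EvergreenForest,european,-0.30,270.2,0.17,0.88
MixedForest,european,-0.28,236.6,0.22,0.43
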