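taxon,volume_um3,law_a,law_b,law_m,detection_limit_per_ml
Cry,664.0,0.216,0.939,1.0,3.3
Nav,100.0,0.288,0.811,1.0,10.0
Coleps,9850.0,0.14,1.0,1.0,0.5
Eup,26890.0,0.14,1.0,1.0,0.5
Bacteria,0.05,0.435,0.86,0.5,
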