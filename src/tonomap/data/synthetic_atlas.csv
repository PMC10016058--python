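# SYNTHETIC atlas border table (clearly-labelled stand-in; not the published
# copyrighted coordinates). Same schema as a real per-section edge table:
# one row per (section, area) with the dorsal and ventral DV edges in mm.
# AuV is deliberately absent at AP = -1.91 (discontinuity exercised by the
# split-equal patch); Au1 spans the missing AuV band there.
ap_mm,area,dorsal_dv_mm,ventral_dv_mm
-1.67,AuD,1.550,2.000
-1.67,Au1,2.000,2.700
-1.67,AuV,2.700,3.250
-1.79,AuD,1.483,1.962
-1.79,Au1,1.962,2.719
-1.79,AuV,2.719,3.317
-1.91,AuD,1.419,1.925
-1.91,Au1,1.925,3.381
-2.03,AuD,1.359,1.891
-2.03,Au1,1.891,2.755
-2.03,AuV,2.755,3.441
-2.15,AuD,1.307,1.861
-2.15,Au1,1.861,2.770
-2.15,AuV,2.770,3.493
-2.27,AuD,1.263,1.836
-2.27,Au1,1.836,2.782
-2.27,AuV,2.782,3.537
-2.39,AuD,1.230,1.817
-2.39,Au1,1.817,2.791
-2.39,AuV,2.791,3.570
-2.51,AuD,1.209,1.805
-2.51,Au1,1.805,2.797
-2.51,AuV,2.797,3.591
-2.63,AuD,1.200,1.800
-2.63,Au1,1.800,2.800
-2.63,AuV,2.800,3.600
-2.75,AuD,1.204,1.803
-2.75,Au1,1.803,2.799
-2.75,AuV,2.799,3.596
-2.87,AuD,1.222,1.812
-2.87,Au1,1.812,2.794
-2.87,AuV,2.794,3.578
-2.99,AuD,1.251,1.829
-2.99,Au1,1.829,2.786
-2.99,AuV,2.786,3.549
-3.11,AuD,1.291,1.852
-3.11,Au1,1.852,2.774
-3.11,AuV,2.774,3.509
-3.23,AuD,1.341,1.880
-3.23,Au1,1.880,2.760
-3.23,AuV,2.760,3.459
-3.35,AuD,1.398,1.913
-3.35,Au1,1.913,2.743
-3.35,AuV,2.743,3.402
-3.47,AuD,1.461,1.949
-3.47,Au1,1.949,2.725
-3.47,AuV,2.725,3.339
-3.63,AuD,1.550,2.000
-3.63,Au1,2.000,2.700
-3.63,AuV,2.700,3.250
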