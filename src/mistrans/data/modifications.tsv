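name	composition	delta_mass
Oxidation	O1	15.994915
Deamidation	H-1N-1O1	0.984016
Methylation	C1H2	14.015650
Dimethylation	C2H4	28.031300
Trimethylation	C3H6	42.046950
Acetylation	C2H2O1	42.010565
Phosphorylation	H1O3P1	79.966331
Formylation	C1O1	27.994915
Carbamidomethylation	C2H3N1O1	57.021464
Carbamylation	C1H1N1O1	43.005814
Sodium adduct	H-1Na1	21.981944
Potassium adduct	H-1K1	37.955882
Water loss	H-2O-1	-18.010565
Ammonia loss	H-3N-1	-17.026549
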