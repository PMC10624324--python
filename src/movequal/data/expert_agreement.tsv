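parameter	SDT	SLST
Overall Impression: Loss of balance	0,48 (12,34)	0,56 (8,38)
Overall Impression: Gross arm deviation	0,58 (8,38)	0,73 (4,42)
Overall Impression: Disruption of smooth movement	0,37 (7,39)	0,49 (6,40)
Overall Impression: Tremor	0,68 (6,40)	0,59 (10,36)
Overall Impression: Depth of squat	0,86 (8,38)	0,95 (0,46)
Trunk movement: Forward lean	0,68 (9,37)	0,95 (2,44)
Trunk movement: Lateroflexion	0,44 (5,41)	0,65 (2,44)
Trunk movement: Lateral rotation	0,87 (0,46)	0,93 (3,43)
Posture of the pelvis: Anteversion	1,00 (0,46)	1,00 (0,46)
Posture of the pelvis: Retroversion	1,00 (0,46)	1,00 (0,46)
Posture of the hip joint: Drop	0,45 (32,14)	0,84 (5,41)
Posture of the hip joint: Shift	0,24 (9,37)	0,92 (0,46)
Lower limbs: Hip joint, Adduction, internal rotation	0,15 (27,19)	0,13 (30,16)
Lower limbs: Knee-joint, valgosity	0,27 (20,26)	0,07 (22,24)
Lower limbs: Knee-joint, varosity	1,00 (0,46)	1,00 (0,46)
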