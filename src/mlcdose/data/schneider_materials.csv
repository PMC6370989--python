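# Schneider-style stoichiometric HU binning: 24 bins covering [-1024, 3500].
# density_lo/density_hi define a linear density ramp across the bin.
# Elemental columns are mass fractions (normalized on load).
# hu_lo,hu_hi,name,density_lo,density_hi,H,C,N,O,Na,Mg,P,S,Cl,Ar,K,Ca
-1024,-950,air,0.00121,0.00121,0.0,0.000124,0.755267,0.231781,0.0,0.0,0.0,0.0,0.0,0.012827,0.0,0.0
-950,-120,lung,0.093,0.930,0.103,0.105,0.031,0.749,0.002,0.0,0.002,0.003,0.003,0.0,0.002,0.0
-120,-83,adipose_3,0.930,0.951,0.116,0.681,0.002,0.198,0.001,0.0,0.0,0.001,0.001,0.0,0.0,0.0
-83,-53,adipose_2,0.951,0.969,0.113,0.567,0.009,0.308,0.001,0.0,0.0,0.001,0.001,0.0,0.0,0.0
-53,-23,adipose_1,0.969,0.984,0.110,0.458,0.015,0.411,0.001,0.0,0.001,0.001,0.002,0.0,0.001,0.0
-23,7,adipose_muscle,0.984,1.011,0.108,0.356,0.022,0.509,0.0,0.0,0.001,0.002,0.002,0.0,0.0,0.0
7,18,soft_tissue,1.011,1.029,0.106,0.284,0.026,0.578,0.0,0.0,0.001,0.002,0.002,0.0,0.001,0.0
18,80,muscle,1.029,1.061,0.103,0.134,0.030,0.723,0.002,0.0,0.002,0.002,0.002,0.0,0.002,0.0
80,120,connective,1.061,1.119,0.094,0.207,0.062,0.622,0.006,0.0,0.0,0.006,0.003,0.0,0.0,0.0
120,200,marrow_bone_01,1.076,1.111,0.095,0.455,0.025,0.355,0.001,0.0,0.021,0.001,0.001,0.0,0.001,0.045
200,300,marrow_bone_02,1.111,1.164,0.089,0.423,0.027,0.363,0.001,0.0,0.030,0.001,0.001,0.0,0.001,0.064
300,400,marrow_bone_03,1.164,1.223,0.082,0.391,0.029,0.372,0.001,0.001,0.039,0.002,0.001,0.0,0.001,0.081
400,500,marrow_bone_04,1.223,1.283,0.076,0.361,0.030,0.380,0.001,0.001,0.047,0.002,0.001,0.0,0.0,0.101
500,600,marrow_bone_05,1.283,1.342,0.071,0.335,0.032,0.387,0.001,0.001,0.054,0.002,0.001,0.0,0.0,0.116
600,700,marrow_bone_06,1.342,1.401,0.066,0.310,0.033,0.394,0.001,0.001,0.061,0.002,0.001,0.0,0.0,0.131
700,800,marrow_bone_07,1.401,1.461,0.061,0.287,0.035,0.400,0.001,0.001,0.067,0.002,0.001,0.0,0.0,0.145
800,900,marrow_bone_08,1.461,1.520,0.056,0.265,0.036,0.405,0.001,0.002,0.073,0.003,0.001,0.0,0.0,0.158
900,1000,marrow_bone_09,1.520,1.579,0.052,0.246,0.037,0.411,0.001,0.002,0.078,0.003,0.001,0.0,0.0,0.169
1000,1100,marrow_bone_10,1.579,1.639,0.049,0.227,0.038,0.416,0.001,0.002,0.083,0.003,0.001,0.0,0.0,0.180
1100,1200,marrow_bone_11,1.639,1.698,0.045,0.210,0.039,0.420,0.001,0.002,0.088,0.003,0.001,0.0,0.0,0.191
1200,1300,marrow_bone_12,1.698,1.757,0.042,0.194,0.040,0.425,0.001,0.002,0.092,0.003,0.001,0.0,0.0,0.200
1300,1400,marrow_bone_13,1.757,1.817,0.039,0.179,0.041,0.429,0.001,0.002,0.096,0.003,0.001,0.0,0.0,0.209
1400,1600,cortical_bone_lo,1.817,1.935,0.036,0.159,0.042,0.435,0.001,0.002,0.101,0.003,0.001,0.0,0.0,0.220
1600,3500,cortical_bone_hi,1.935,2.900,0.034,0.155,0.042,0.435,0.001,0.002,0.103,0.003,0.001,0.0,0.0,0.224
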