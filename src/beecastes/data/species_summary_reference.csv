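species,head_width_mean_mm,head_width_sd_mm,size_difference_pct,cv_headwidth,di_headwidth,t_guards,p_guards_adj,allometry_slope,t_allometry,p_allometry_adj,weight_mean_mg,weight_sd_mg,cv_weight,lestrimelitta_target
Friesella schrottkyi,1.41,0.033,-0.5,0.0239,0.23,-0.99,0.51,0.69,1.83,0.1,2.81,0.28,0.1033,yes
Frieseomelitta flavicornis,2.26,0.045,1.6,0.0203,0.88,3.55,0.0051,0.37,4.1,0.0012,9.49,1.5,0.1646,no
Frieseomelitta longipes,2.37,0.029,1.7,0.0129,1.35,2.96,0.025,0.41,2.16,0.073,10.8,1.7,0.1594,no
Frieseomelitta silvestrii,1.74,0.033,1.3,0.0195,0.67,2.59,0.039,0.72,1.17,0.26,5.05,0.44,0.0897,yes
Frieseomelitta varia,2.33,0.036,1.1,0.0156,0.74,3.38,0.0051,,,,,,,yes
Geotrigona mombuca,2.45,0.035,0.9,0.0142,0.63,2.12,0.082,0.55,1.76,0.1,12.37,1.4,0.1184,no
Lestrimelitta limao,2.19,0.032,0.2,0.0144,0.17,0.67,0.58,0.61,2.0,0.078,12.11,0.86,0.0713,no
Leurotrigona muelleri,1.11,0.024,1.2,0.0217,0.58,2.09,0.082,0.51,2.55,0.039,1.4,0.24,0.1705,no
Melipona fasciculata,4.45,0.048,0.2,0.0113,0.16,0.64,0.58,0.55,2.27,0.062,101.6,7.2,0.0721,no
Melipona flavolineata,3.77,0.075,0.6,0.0202,0.31,1.08,0.5,0.55,2.14,0.073,56.4,5.9,0.1063,no
Melipona melanoventer,4.4,0.063,-0.1,0.0119,0.10,-0.4,0.69,0.4,3.92,0.0016,92.2,11.0,0.1187,no
Melipona scutellaris,4.06,0.071,1.8,0.0178,1.05,3.38,0.0076,0.67,1.75,0.1,73.5,6.2,0.0872,yes
Melipona subnitida,3.7,0.052,0.9,0.0141,0.64,2.28,0.064,0.4,2.77,0.033,60.4,7.2,0.1217,no
Nannotrigona testaceicornis,1.88,0.03,-0.5,0.0160,0.34,-1.33,0.34,0.71,2.17,0.07,6.74,0.53,0.0804,yes
Paratrigona lineata,1.73,0.029,0.4,0.0169,0.24,0.74,0.58,0.33,3.77,0.003,6.27,0.91,0.1469,no
Partamona helleri,2.52,0.031,0.2,0.0121,0.15,0.59,0.6,0.74,1.38,0.19,15.97,0.90,0.0565,no
Plebeia droryana,1.63,0.036,1.1,0.0221,0.50,2.46,0.045,0.69,2.05,0.073,4.24,0.43,0.1035,yes
Scaptotrigona bipunctata,2.74,0.058,1.8,0.0210,0.99,4.51,0.0051,0.53,2.66,0.033,19.01,2.11,0.1107,yes
Scaptotrigona aff. depilis,2.65,0.034,1.3,0.0129,1.00,2.31,0.06,0.82,0.97,0.34,16.49,0.99,0.0614,no
Scaptotrigona tubiba,2.28,0.035,0.3,0.0152,0.17,0.7,0.58,,,,10.89,1.28,0.1192,no
Scaura latitarsis,1.73,0.03,-0.3,0.0177,0.17,-0.64,0.58,,,,,,,yes
Tetragona clavipes,2.51,0.035,-0.3,0.0141,0.23,-0.91,0.55,0.67,1.95,0.083,12.2,1.03,0.0854,no
Tetragonisca angustula,1.79,0.066,5.9,0.0380,1.59,11.75,<0.0001,0.81,2.48,0.04,4.62,0.67,0.1481,yes
Tetragonisca fiebrigi,1.79,0.056,4.8,0.0315,1.54,12.45,<0.0001,,,,,,,yes
Trigona fuscipennis,2.6,0.032,0.2,0.0124,0.14,0.65,0.58,0.57,2.65,0.033,15.51,0.98,0.0634,no
Trigona hypogea,2.28,0.025,0.3,0.0109,0.23,1.01,0.51,0.38,4.09,0.0012,10.54,0.85,0.0805,no
Trigona recursa,2.31,0.055,1.9,0.0242,0.80,3.52,0.0051,0.73,1.77,0.1,11.28,1.19,0.1067,no
Trigonisca nataliae,1.17,0.014,0.1,0.0122,0.12,0.4,0.69,0.54,1.75,0.1,1.5,0.12,0.0812,no
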