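image_id,manual_er_status,manual_intensity,manual_pscore,manual_iscore,manual_allred,auto_er_pct,auto_s,auto_m,auto_w,auto_pscore,auto_iscore,auto_allred,flag
05349,0%,NONE,0,0,0,0.83,0.01,0.02,0.8,1,1,2,
05367,0%,NONE,0,0,0,0.19,0.16,0.01,0.02,1,3,4,
05305,0%,NONE,0,0,0,1.87,0.02,0.03,1.83,2,1,3,
55522,0%,NONE,0,0,0,0.8,0.01,0.03,0.77,1,1,2,
60537,<1%,WEAK,1,1,2,0.14,0.02,0.01,0.12,1,1,2,
05409,<1%,WEAK,1,1,2,0.11,0.01,0.01,0.09,1,1,2,
05317,<1%,WEAK,1,1,2,1.29,0.02,0.04,1.23,2,1,3,
05343,<1%,WEAK,1,1,2,0.63,0.02,0.01,0.6,1,1,2,
78990,<1%,WEAK,1,1,2,0.33,0.03,0.05,0.25,1,1,2,
05337,<1%,WEAK,1,1,2,0.80,0.03,0.04,0.74,1,1,2,
05403,<1%,WEAK,1,1,2,1.09,0.03,0.05,1.01,2,1,3,
05267,<1%,WEAK,1,1,2,0.15,0.02,0,0.12,1,1,2,
05385,<1%,WEAK,1,1,2,0.5,0.07,0.12,0.31,1,1,2,
05329,<1%,WEAK,1,1,2,0.35,0.01,0.03,0.32,1,1,2,
05447,<1%,WEAK,1,1,2,0.56,0.02,0.01,0.53,1,1,2,
05459,<1%,WEAK,1,1,2,0.56,0.03,0.1,2.84,1,1,2,inconsistent_proportions
05441,<1%,WEAK,1,1,2,47.54,1.69,2.76,43.09,4,1,5,
05397,1-10%,WEAK,2,1,3,2.54,0.02,0.08,2.44,2,1,3,
05391,1-10%,WEAK,2,1,3,3.55,0.01,0.06,3.47,2,1,3,
05355,1-10%,WEAK,2,1,3,1.99,0.02,0.04,1.93,2,1,3,
05421,1-10%,WEAK,2,1,3,4.42,0.05,0.19,4.18,2,1,3,
05453,1-10%,WEAK,2,1,3,4.61,0.05,0.07,4.49,2,1,3,
05279,1-10%,WEAK,2,1,3,3.38,0.12,0.19,3.07,2,1,3,
05379,1-10%,WEAK,2,1,3,0.76,0.02,0.03,0.7,1,1,2,
05373,1-10%,WEAK,2,1,3,1.31,0.01,0.02,1.28,2,1,3,
05361,1-10%,WEAK,2,1,3,2.91,0.04,0.06,2.81,2,1,3,
05415,1-10%,WEAK,2,1,3,3.67,0.03,0.09,3.55,2,1,3,
05285,1-10%,WEAK,2,1,3,0.22,0.03,0.05,0.14,1,1,2,
05427,1-10%,WEAK,2,1,3,7.89,0.44,0.25,7.2,2,1,3,
05465,1-10%,WEAK,2,1,3,8.41,0.01,0.05,8.35,2,1,3,
05273,>95%,STRONG,5,3,8,46.39,9.59,19.65,17.15,4,2,6,
05299,>80%,MODERATE,5,2,7,47.73,4.97,26.56,16.19,4,2,6,
05435,>95%,MODERATE,5,2,7,77.44,12.46,36.19,28.8,5,2,7,
05247,>90%,MODERATE,5,2,7,49.84,12.36,17.87,19.6,4,1,5,
01099,>95%,MODERATE,5,2,7,62.63,7.55,21.58,33.5,4,1,5,
05255,>95%,STRONG,5,3,8,73.15,18.02,40.22,14.91,5,2,7,
05261,>95%,STRONG,5,3,8,49.47,14.65,23.91,10.91,4,2,6,
05311,>95%,MODERATE,5,2,7,73.5,22.27,40.96,10.26,5,2,7,
05293,>95%,MODERATE,5,2,7,43.75,16.66,19.54,7.54,4,2,6,
05323,>90%,STRONG,5,3,8,48.39,11.65,22.11,14.63,4,2,6,
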