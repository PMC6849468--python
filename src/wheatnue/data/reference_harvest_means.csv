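variety,n_level,dw_g,gy_g,wsc_pct,shoot_n_pct,grain_n_pct
Yitpi,low,19.21,7.34,8.52,0.40,1.65
Excalibur,low,15.74,7.74,5.55,0.36,1.94
Chara,low,13.43,6.52,6.18,0.31,2.11
Pastor,low,13.34,6.46,3.03,0.33,1.90
Bobwhite,low,12.66,6.31,4.30,0.28,2.07
Alsen,low,12.59,6.13,5.18,0.35,2.30
Gladius,low,12.30,6.13,6.00,0.31,2.08
Wyalkatchem,low,12.08,5.95,5.83,0.48,1.98
RAC875,low,12.06,5.59,6.93,0.31,2.28
Kukri,low,11.99,6.49,5.10,0.47,2.13
Baxter,low,11.21,5.32,3.93,0.41,2.17
Volcani DDI,low,10.53,4.95,4.35,0.29,2.45
Westonia,low,10.52,5.72,4.15,0.33,2.11
Kennedy,low,8.70,4.79,3.40,0.33,2.32
Drysdale,low,8.26,4.54,2.97,0.34,2.31
Yitpi,optimum,77.67,27.77,10.52,0.44,2.26
Excalibur,optimum,57.95,24.62,8.77,0.70,2.86
Chara,optimum,61.13,29.05,8.32,0.56,2.51
Pastor,optimum,60.53,28.13,6.58,0.57,2.51
Bobwhite,optimum,50.02,24.54,8.05,0.74,2.61
Alsen,optimum,61.37,28.23,9.33,0.49,2.73
Gladius,optimum,58.60,28.26,11.32,0.50,2.42
Wyalkatchem,optimum,48.71,22.30,8.90,0.71,2.68
RAC875,optimum,56.21,24.84,12.83,0.61,2.68
Kukri,optimum,54.14,25.35,10.12,0.66,2.72
Baxter,optimum,50.98,23.91,5.63,0.86,2.76
Volcani DDI,optimum,45.16,20.69,10.45,0.55,3.17
Westonia,optimum,49.45,23.99,8.08,0.57,2.74
Kennedy,optimum,41.33,21.97,5.48,0.76,2.92
Drysdale,optimum,38.78,18.87,7.00,0.90,2.78
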