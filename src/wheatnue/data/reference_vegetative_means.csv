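variety,n_level,mb_g,la_cm2,eb_kpix,tva_kpix
Bobwhite,low,8.33,191.01,245.86,57.22
Excalibur,low,8.04,238.46,347.36,74.14
Yitpi,low,7.66,217.56,254.35,48.70
Alsen,low,7.66,214.09,295.29,66.91
Kukri,low,7.63,191.82,251.00,51.20
RAC875,low,7.49,178.45,207.91,39.89
Wyalkatchem,low,6.67,190.34,242.24,46.49
Chara,low,6.59,174.86,218.43,39.50
Baxter,low,6.29,173.00,233.44,49.58
Pastor,low,6.10,157.68,251.98,51.37
Kennedy,low,6.00,136.43,170.16,33.02
Gladius,low,5.87,142.66,199.04,39.25
Westonia,low,5.62,125.66,221.09,45.03
Volcani DDI,low,5.49,123.79,199.42,43.58
Drysdale,low,5.01,96.90,173.51,33.09
Bobwhite,optimum,25.52,699.92,759.47,215.81
Excalibur,optimum,36.63,1162.61,1059.88,296.44
Yitpi,optimum,25.94,693.79,751.63,166.91
Alsen,optimum,31.61,906.27,921.56,249.65
Kukri,optimum,29.21,768.57,859.99,223.55
RAC875,optimum,26.79,636.31,699.55,180.93
Wyalkatchem,optimum,28.38,792.61,711.04,169.47
Chara,optimum,21.97,599.51,663.29,153.32
Baxter,optimum,25.97,784.56,840.74,218.80
Pastor,optimum,32.06,831.87,849.85,224.07
Kennedy,optimum,27.37,723.73,721.79,174.04
Gladius,optimum,23.14,587.06,647.07,163.88
Westonia,optimum,24.99,569.03,656.73,162.15
Volcani DDI,optimum,19.68,413.69,614.73,163.12
Drysdale,optimum,25.74,635.07,712.40,181.50
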