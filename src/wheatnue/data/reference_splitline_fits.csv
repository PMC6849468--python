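variety,n_level,breakpoint_x,breakpoint_y,slope1,slope2
Alsen,low,68.7,480.8,11.9,5.9
Baxter,low,71.2,413.4,10.0,5.4
Bobwhite,low,68.1,393.6,10.0,4.1
Chara,low,45.1,113.7,6.0,12.3
Drysdale,low,66.3,247.4,6.0,2.8
Excalibur,low,69.1,554.5,13.6,6.9
Gladius,low,42.5,97.3,5.6,9.5
Kennedy,low,67.8,268.9,6.7,3.7
Kukri,low,69.3,419.1,10.4,4.6
Pastor,low,38.2,77.3,5.4,11.2
RAC875,low,71.8,374.5,8.8,4.8
Volcani DDI,low,68.6,384.4,8.3,5.4
Westonia,low,66.5,326.1,8.1,3.7
Wyalkatchem,low,38.6,81.6,5.7,10.4
Yitpi,low,48.7,170.4,7.9,16.4
Alsen,optimum,46.2,570.9,28.1,49.8
Baxter,optimum,43.6,454.0,26.0,41.8
Bobwhite,optimum,37.8,242.0,18.1,33.8
Chara,optimum,52.4,578.7,22.1,50.2
Drysdale,optimum,62.0,939.1,25.9,16.5
Excalibur,optimum,52.3,1024.0,37.6,53.7
Gladius,optimum,49.9,514.5,22.3,36.5
Kennedy,optimum,37.7,241.2,17.6,30.4
Kukri,optimum,36.1,273.0,22.6,34.3
Pastor,optimum,46.4,501.0,24.8,54.2
RAC875,optimum,45.7,457.3,22.8,33.8
Volcani DDI,optimum,39.2,232.7,15.5,27.6
Westonia,optimum,45.5,408.1,21.2,31.2
Wyalkatchem,optimum,51.0,619.7,24.7,39.1
Yitpi,optimum,51.9,620.7,25.5,57.4
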