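term,coefficient,std_error
intercept,-7.155,1.949
temperature,0.582,0.158
temperature^2,-0.021,0.004
precipitation,-0.578,0.713
precipitation^2,-0.584,0.141
temperature:precipitation,0.114,0.028
elevation,-0.062,0.281
"max(6.5-ph,0)",-0.923,0.203
"max(ph-6.5,0)",-1.622,0.383
soil_carbon,0.157,0.047
slope,-6.142,2.289
latitude,0.044,0.015
latitude^2,0.0004,0.001
country[Argentina],0.392,0.300
country[Bolivia],0.611,0.516
country[Brazil],1.432,0.300
country[Canada],-3.965,1.277
country[Chile],0.377,0.527
country[Colombia],-0.333,0.327
country[Costa Rica],-0.743,0.439
country[Guatemala],1.155,0.578
country[Honduras],0.131,0.539
country[Mexico],0.450,0.641
country[Nicaragua],0.741,0.462
country[Panama],0.052,0.462
country[United States],-1.887,1.150
country[Venezuela],0.500,0.480
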