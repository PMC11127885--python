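# synthetic stand-in for the published model 1 survey dataset
# (same schema as a real reference CSV: group,location,<predictors>)
group,location,SLA,ARNODE,LOGCANH,LOGCAND,FLOWPER
1,g1_loc1,37.353352,17.015918,1.564894,1.541729,7.423533
1,g1_loc1,18.286084,15.693438,1.936379,1.52596,4.868278
1,g1_loc1,26.214787,13.320254,1.840633,1.146985,6.805301
1,g1_loc1,26.671983,12.491392,1.444028,1.559854,5.158136
1,g1_loc1,28.924458,18.294416,1.661044,1.329533,3.21068
1,g1_loc1,34.842576,10.807806,1.886634,1.418522,4.940713
1,g1_loc1,39.29288,13.981034,1.326015,1.256992,5.131163
1,g1_loc1,32.70761,7.60522,1.86477,0.97641,3.192236
1,g1_loc1,25.545327,12.463076,1.234487,1.151208,3.126282
1,g1_loc1,15.707317,11.417279,1.600039,1.514106,4.260506
1,g1_loc1,25.455783,14.993164,1.659201,1.523873,3.213626
1,g1_loc1,29.672893,17.311225,1.302226,1.435609,5.850257
1,g1_loc1,28.199999,16.444997,1.709766,1.611571,7.229833
1,g1_loc1,27.17109,19.58565,1.568232,1.596742,5.22045
1,g1_loc1,27.183307,16.803499,1.868494,1.394861,2.363513
1,g1_loc1,23.268468,6.024388,1.819521,1.127186,5.978953
1,g1_loc1,18.574749,3.195165,1.918655,1.34974,3.423901
1,g1_loc1,35.80768,7.075701,1.92691,1.513532,5.577296
1,g1_loc1,23.433963,21.170578,1.606663,1.581981,5.868335
1,g1_loc1,28.766698,17.016578,1.901967,1.331787,2.766099
1,g1_loc1,31.04476,10.062206,1.309123,1.040149,6.27508
1,g1_loc1,37.568712,8.711887,1.680035,1.558604,4.658013
1,g1_loc1,32.849136,19.447636,1.666396,1.16597,4.378257
1,g1_loc1,26.629979,11.862702,1.745485,1.472426,3.362859
2,g2_loc1,21.784189,12.770204,1.874619,0.875553,5.222982
2,g2_loc1,17.256913,9.758872,1.356326,1.031669,3.38808
2,g2_loc1,20.09509,8.256949,1.029599,0.471429,2.370969
2,g2_loc1,20.516449,9.67954,1.429227,1.171564,4.012072
2,g2_loc1,5.765724,11.132944,0.457457,1.126055,1.914689
2,g2_loc1,35.90155,4.334206,1.466746,1.151383,1.621808
2,g2_loc1,24.100873,10.738227,1.04427,1.072101,2.554149
2,g2_loc1,29.13621,7.96905,1.045584,0.816584,3.803983
2,g2_loc1,20.310862,16.310472,1.784257,0.816262,3.389707
2,g2_loc1,13.987758,5.456976,1.752455,1.298713,2.240772
2,g2_loc1,6.931541,9.122337,1.356109,1.001157,4.329754
2,g2_loc1,27.244075,9.085787,1.362528,0.804206,-0.207395
2,g2_loc1,29.207582,10.740559,1.595269,1.080361,0.847916
2,g2_loc1,20.390665,16.84328,1.577441,1.034284,2.734164
2,g2_loc1,23.307651,10.639979,1.547662,1.21762,0.590204
2,g2_loc1,24.794401,4.677788,1.150109,1.066266,1.752963
2,g2_loc1,9.023994,6.630049,1.335875,0.854687,2.65166
2,g2_loc1,23.546595,8.096228,1.609046,1.254758,3.891887
2,g2_loc1,20.307879,10.070612,1.148421,1.090369,3.744092
2,g2_loc1,17.368758,4.474211,1.067133,0.41814,3.007796
2,g2_loc1,25.677581,9.099006,1.310523,0.91506,1.901352
2,g2_loc1,20.929927,4.449623,1.338432,0.825628,2.659856
2,g2_loc1,27.091678,5.350949,1.279942,1.089032,5.106364
2,g2_loc1,21.896468,9.842982,1.230726,1.254664,1.495134
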