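# synthetic stand-in for the published model 2 survey dataset
# (same schema as a real reference CSV: group,location,<predictors>)
group,location,SLA,ARNODE,LOGCANH,LOGCAND
1,g1_loc1,26.066441,17.226146,1.770338,1.503228
1,g1_loc2,26.52384,24.22772,1.665852,1.144961
1,g1_loc1,31.502336,15.228869,2.226685,1.421246
1,g1_loc2,25.977929,14.516886,2.24294,1.756921
1,g1_loc1,29.621479,18.885931,1.354027,1.647749
1,g1_loc2,29.62708,12.364486,1.885943,1.327908
1,g1_loc1,29.531026,11.844609,1.791275,1.572863
1,g1_loc2,28.817148,19.128231,1.817944,1.372787
1,g1_loc1,33.058878,4.779888,1.733375,1.402618
1,g1_loc2,30.185337,9.653512,1.584706,1.391711
1,g1_loc1,29.199549,13.224448,1.495909,1.729381
1,g1_loc2,41.016953,4.795266,1.85036,1.673837
1,g1_loc1,18.247171,14.577583,2.22786,1.318137
1,g1_loc2,31.676298,16.221184,1.857668,1.006412
1,g1_loc1,28.303293,13.400458,1.180058,1.328278
1,g1_loc2,26.352123,11.287951,1.254222,1.9521
1,g1_loc1,30.96871,12.399973,1.650204,0.568716
1,g1_loc2,19.143743,7.208365,1.930424,1.806403
1,g1_loc1,33.471985,13.074902,1.126703,1.619677
1,g1_loc2,24.528829,17.491649,1.506143,0.962948
1,g1_loc1,29.04209,18.918958,1.161776,1.250806
1,g1_loc2,34.764924,11.193066,1.419036,1.500357
1,g1_loc1,25.007654,12.821433,1.97497,1.355621
1,g1_loc2,25.646014,11.121132,1.633691,1.437494
2,g2_loc1,26.184335,6.699862,1.302822,1.369366
2,g2_loc2,33.946653,11.209815,1.510159,1.174986
2,g2_loc1,14.098654,5.427919,1.1063,0.83158
2,g2_loc2,24.090948,9.131597,1.402958,1.050121
2,g2_loc1,26.15889,9.36977,0.946815,0.623829
2,g2_loc2,31.205526,11.913069,1.6848,1.372076
2,g2_loc1,33.628478,9.635986,1.302056,1.078967
2,g2_loc2,18.118002,10.849119,1.140625,1.341814
2,g2_loc1,20.359032,14.062664,1.344836,1.099987
2,g2_loc2,15.084533,14.285082,1.370349,0.92419
2,g2_loc1,16.531313,5.793325,0.694257,1.352226
2,g2_loc2,18.099437,10.946793,0.982338,0.609106
2,g2_loc1,24.135314,8.857032,1.130679,0.462762
2,g2_loc2,23.968329,9.919373,1.286606,1.353675
2,g2_loc1,27.634649,8.450229,1.587827,0.67941
2,g2_loc2,14.772077,6.054243,1.125892,1.447109
2,g2_loc1,29.035237,13.709901,1.485881,0.72746
2,g2_loc2,37.024148,12.606842,1.915065,1.227428
2,g2_loc1,24.906191,6.414432,1.746292,1.508737
2,g2_loc2,7.992654,5.62735,0.929372,0.884541
2,g2_loc1,14.516453,14.161714,0.707482,1.476496
2,g2_loc2,20.074837,10.457965,0.809063,0.812283
2,g2_loc1,24.677054,8.228454,1.292735,1.38052
2,g2_loc2,14.013939,4.513225,1.14678,0.987071
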