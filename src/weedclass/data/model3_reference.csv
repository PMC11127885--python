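# synthetic stand-in for the published model 3 survey dataset
# (same schema as a real reference CSV: group,location,<predictors>)
group,location,VEGPROP,FLOWPER
1,g1_loc1,0.711386,3.405853
1,g1_loc2,0.577179,3.55631
1,g1_loc1,0.531476,3.893156
1,g1_loc2,0.547641,3.323588
1,g1_loc1,0.699828,3.187445
1,g1_loc2,0.33159,4.370942
1,g1_loc1,0.583558,3.531139
1,g1_loc2,0.694113,6.420905
1,g1_loc1,0.637369,3.981401
1,g1_loc2,0.62534,4.642276
1,g1_loc1,0.609513,8.36514
1,g1_loc2,0.662536,4.191194
1,g1_loc1,0.381253,6.20053
1,g1_loc2,0.477251,5.035431
1,g1_loc1,0.641011,4.068681
1,g1_loc2,0.601959,5.296441
1,g1_loc1,0.47281,3.190765
1,g1_loc2,0.548033,4.899726
1,g1_loc1,0.451666,2.594235
1,g1_loc2,0.457695,4.809404
1,g1_loc1,0.441642,1.746726
1,g1_loc2,1.049519,2.852791
1,g1_loc1,0.744017,6.387138
1,g1_loc2,0.668993,6.833534
2,g2_loc1,0.267527,5.352599
2,g2_loc2,0.220893,3.375438
2,g2_loc1,0.315412,4.994316
2,g2_loc2,0.493753,4.022991
2,g2_loc1,0.253339,4.302581
2,g2_loc2,0.225402,4.485791
2,g2_loc1,0.325407,2.588252
2,g2_loc2,0.30576,3.911153
2,g2_loc1,0.313163,3.14162
2,g2_loc2,0.310213,3.783438
2,g2_loc1,0.328809,2.086161
2,g2_loc2,0.311371,2.795243
2,g2_loc1,0.293872,3.161887
2,g2_loc2,0.383511,2.17991
2,g2_loc1,0.377999,5.502829
2,g2_loc2,0.139397,2.156907
2,g2_loc1,0.548359,3.849988
2,g2_loc2,0.240944,1.973469
2,g2_loc1,0.311302,4.690415
2,g2_loc2,0.463821,2.647532
2,g2_loc1,0.396596,2.771741
2,g2_loc2,0.511298,4.954926
2,g2_loc1,0.325747,-0.164764
2,g2_loc2,0.194038,4.458442
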