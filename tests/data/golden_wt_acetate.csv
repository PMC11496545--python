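time_s,pH_in,dpsi_mV,I404,I454,F_acma,acetate_total_mM,acetic_acid_mM,methylamine_total_mM,K_mM
0.0,7.2,0.0,26.371598,73.628402,1.0,0.0,0.0,0.0,50.0
12.0,7.2,0.0,26.371598,73.628402,1.0,0.0,0.0,0.0,50.0
24.0,7.2,0.0,26.371598,73.628402,1.0,0.0,0.0,0.0,50.0
36.0,7.2,0.0,26.371598,73.628402,1.0,0.0,0.0,0.0,50.0
48.0,7.2,0.0,26.371598,73.628402,1.0,0.0,0.0,0.0,50.0
60.0,7.2,0.0,26.371598,73.628402,1.0,0.0,0.0,0.0,50.0
72.0,6.915732,-0.403739,16.981289,83.018711,0.964851,5.215473,0.03965,0.0,50.437647
84.0,6.930317,-0.609061,17.390344,82.609656,0.969407,5.39226,0.03965,0.0,50.848213
96.0,6.943708,-0.79952,17.77272,82.22728,0.973266,5.559885,0.039651,0.0,51.231766
108.0,6.956037,-0.976515,18.130588,81.869412,0.97655,5.718862,0.039651,0.0,51.590568
120.0,6.967418,-1.141268,18.465874,81.534126,0.979355,5.869666,0.039651,0.0,51.926619
132.0,6.977946,-1.294849,18.780304,81.219696,0.98176,6.012741,0.039651,0.0,52.241698
144.0,6.987705,-1.438206,19.075429,80.924571,0.98383,6.1485,0.039651,0.0,52.537395
156.0,6.996768,-1.572181,19.352648,80.647352,0.985618,6.277329,0.039651,0.0,52.815143
168.0,7.005197,-1.697525,19.613232,80.386768,0.987168,6.399593,0.039651,0.0,53.076233
180.0,7.013048,-1.81491,19.858336,80.141664,0.988515,6.515633,0.039651,0.0,53.321838
192.0,7.020372,-1.924942,20.089017,79.910983,0.989689,6.625772,0.039651,0.0,53.553024
204.0,7.02721,-2.028168,20.306241,79.693759,0.990715,6.730315,0.039651,0.0,53.770764
216.0,7.033603,-2.125083,20.510895,79.489105,0.991615,6.829548,0.039652,0.0,53.97595
228.0,7.039586,-2.216138,20.703795,79.296205,0.992407,6.923745,0.039652,0.0,54.1694
240.0,7.04519,-2.301743,20.885695,79.114305,0.993104,7.013164,0.039652,0.0,54.351868
252.0,7.050444,-2.382273,21.057289,78.942711,0.99372,7.098047,0.039652,0.0,54.524049
264.0,7.055373,-2.458072,21.219222,78.780778,0.994266,7.178626,0.039652,0.0,54.686585
276.0,7.060001,-2.529454,21.372091,78.627909,0.99475,7.25512,0.039652,0.0,54.84007
288.0,7.06435,-2.596709,21.516447,78.483553,0.995182,7.327737,0.039652,0.0,54.985056
300.0,7.068438,-2.660104,21.652808,78.347192,0.995566,7.396675,0.039652,0.0,55.122055
312.0,7.072283,-2.719887,21.781651,78.218349,0.995909,7.462118,0.039652,0.0,55.251544
324.0,7.075903,-2.776284,21.903424,78.096576,0.996217,7.524246,0.039652,0.0,55.373966
336.0,7.079311,-2.829508,22.018541,77.981459,0.996493,7.583226,0.039652,0.0,55.489735
348.0,7.082523,-2.879753,22.127394,77.872606,0.996741,7.639218,0.039652,0.0,55.599237
360.0,7.085549,-2.927201,22.230344,77.769656,0.996964,7.692373,0.039652,0.0,55.702835
372.0,7.088403,-2.972023,22.327731,77.672269,0.997166,7.742836,0.039652,0.0,55.800866
384.0,7.091095,-3.014374,22.419874,77.580126,0.997348,7.790741,0.039652,0.0,55.893645
396.0,7.093636,-3.054402,22.507072,77.492928,0.997513,7.83622,0.039652,0.0,55.98147
408.0,7.096034,-3.092243,22.589603,77.410397,0.997663,7.879395,0.039652,0.0,56.064619
420.0,7.098298,-3.128025,22.66773,77.33227,0.997799,7.920382,0.039652,0.0,56.143353
432.0,7.100437,-3.161868,22.741698,77.258302,0.997923,7.959293,0.039652,0.0,56.217917
444.0,7.102457,-3.193882,22.81174,77.18826,0.998036,7.996232,0.039652,0.0,56.28854
456.0,7.104367,-3.224174,22.878073,77.121927,0.998139,8.0313,0.039652,0.0,56.355441
468.0,7.106172,-3.25284,22.940901,77.059099,0.998233,8.064591,0.039652,0.0,56.418822
480.0,7.107879,-3.279973,23.000416,76.999584,0.998319,8.096196,0.039652,0.0,56.478875
492.0,7.109493,-3.305658,23.0568,76.9432,0.998398,8.126199,0.039652,0.0,56.535782
504.0,7.11102,-3.329976,23.110222,76.889778,0.998471,8.154682,0.039652,0.0,56.589711
516.0,7.112464,-3.353005,23.160844,76.839156,0.998537,8.181722,0.039652,0.0,56.640825
528.0,7.113831,-3.374814,23.208817,76.791183,0.998599,8.207392,0.039653,0.0,56.689273
540.0,7.115125,-3.395471,23.254284,76.745716,0.998655,8.231761,0.039653,0.0,56.7352
552.0,7.13026,-3.63758,23.790823,76.209177,0.999213,8.521849,0.039651,0.0,57.277388
564.0,7.135628,-3.724739,23.983172,76.016828,0.999367,8.627673,0.039652,0.0,57.472556
576.0,7.137565,-3.756265,24.052853,75.947147,0.999418,8.666191,0.039653,0.0,57.543307
588.0,7.138268,-3.767713,24.078171,75.921829,0.999436,8.68021,0.039653,0.0,57.56902
600.0,7.138524,-3.771876,24.08738,75.91262,0.999442,8.685312,0.039653,0.0,57.578373
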