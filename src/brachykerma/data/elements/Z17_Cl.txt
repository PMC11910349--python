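# element: Cl  Z: 17  A: 35.45
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 7.46074025e+01 1.84962041e-01 3.89545159e-01 7.51819097e+01 7.46108731e+01
10.886365 5.66125199e+01 1.84361181e-01 3.36855256e-01 5.71337364e+01 5.66162722e+01
11.851295 4.29579010e+01 1.83712886e-01 2.90641780e-01 4.34322557e+01 4.29619555e+01
12.901753 3.25966988e+01 1.83013934e-01 2.50232351e-01 3.30299450e+01 3.26010771e+01
14.045319 2.47345598e+01 1.82260976e-01 2.15001251e-01 2.51318220e+01 2.47392847e+01
15.290247 1.87687242e+01 1.81450542e-01 1.84372482e-01 1.91345472e+01 1.87738194e+01
16.645522 1.42418143e+01 1.80579063e-01 1.57819182e-01 1.45802125e+01 1.42473047e+01
18.120923 1.08067694e+01 1.79642882e-01 1.34861561e-01 1.11212738e+01 1.08126807e+01
19.727099 8.20023786e+00 1.78638283e-01 1.15064438e-01 8.49394059e+00 8.20659677e+00
21.475640 6.22238697e+00 1.77561515e-01 9.80347976e-02 6.49798328e+00 6.22922085e+00
23.379167 4.72158250e+00 1.76408828e-01 8.34194174e-02 4.98141075e+00 4.72891939e+00
25.451415 3.58276356e+00 1.75176510e-01 7.09025182e-02 3.82884259e+00 3.59063198e+00
27.707340 2.71862130e+00 1.73860932e-01 6.02033495e-02 2.95268558e+00 2.72705002e+00
30.163222 2.06290525e+00 1.72458599e-01 5.10736828e-02 2.28643753e+00 2.07192312e+00
32.836786 1.56534420e+00 1.70966202e-01 4.32952167e-02 1.77960562e+00 1.57497983e+00
35.747324 1.18779205e+00 1.69380685e-01 3.66769352e-02 1.39384967e+00 1.19807358e+00
38.915843 9.01303339e-01 1.67699306e-01 3.10524725e-02 1.10005512e+00 9.12258062e-01
42.365208 6.83914082e-01 1.65919709e-01 2.62775409e-02 8.76111332e-01 6.95568124e-01
46.120313 5.18957882e-01 1.64039993e-01 2.22274705e-02 7.05225346e-01 5.31335816e-01
50.208258 3.93788182e-01 1.62058790e-01 1.87949007e-02 5.74641873e-01 4.06912638e-01
54.658543 2.98808705e-01 1.59975331e-01 1.58876461e-02 4.74671681e-01 3.12699959e-01
59.503287 2.26737739e-01 1.57789517e-01 1.34267534e-02 3.97954009e-01 2.41413307e-01
64.777452 1.72049881e-01 1.55501984e-01 1.13447511e-02 3.38896617e-01 1.87524114e-01
70.519100 1.30552425e-01 1.53114153e-01 9.58409066e-03 2.93250668e-01 1.46836124e-01
76.769668 9.90639202e-02 1.50628270e-01 8.09576785e-03 2.57787958e-01 1.16163984e-01
83.574265 7.51702641e-02 1.48047441e-01 6.83811441e-03 2.30055819e-01 9.30893766e-02
90.981998 5.70396225e-02 1.45375633e-01 5.77574398e-03 2.08190999e-01 7.57759964e-02
99.046327 4.32819888e-02 1.42617669e-01 4.87863808e-03 1.90778296e-01 6.28291745e-02
107.825449 3.28426185e-02 1.39779196e-01 4.12135669e-03 1.76743171e-01 5.31893877e-02
117.382723 2.49211650e-02 1.36866629e-01 3.48235920e-03 1.65270154e-01 4.60514764e-02
127.787120 1.89103213e-02 1.33887077e-01 2.94342201e-03 1.55740820e-01 4.08033699e-02
139.113726 1.43492590e-02 1.30848243e-01 2.48914027e-03 1.47686642e-01 3.69796110e-02
151.444284 1.08882990e-02 1.27758310e-01 2.10650260e-03 1.40753111e-01 3.42261062e-02
164.867780 8.26210302e-03 1.24625806e-01 1.78452863e-03 1.34672438e-01 3.22733889e-02
179.481087 6.26933060e-03 1.21459466e-01 1.51396007e-03 1.29242757e-01 3.09163376e-02
195.389668 4.75720360e-03 1.18268078e-01 1.28699759e-03 1.24312279e-01 2.99987859e-02
212.708330 3.60979305e-03 1.15060337e-01 1.09707581e-03 1.19767206e-01 2.94018391e-02
231.562057 2.73913143e-03 1.11844707e-01 9.38670200e-04 1.15522508e-01 2.90349998e-02
252.086914 2.07846845e-03 1.08629284e-01 8.07129867e-04 1.11514883e-01 2.88294204e-02
274.431023 1.57715364e-03 1.05421693e-01 6.98531228e-04 1.07697378e-01 2.87327682e-02
298.755637 1.19675312e-03 1.02228990e-01 6.09548738e-04 1.04035292e-01 2.87053137e-02
325.236299 9.08103054e-04 9.90576001e-02 5.37340236e-04 1.00503043e-01 2.87169473e-02
354.064116 6.89073744e-04 9.59132795e-02 4.79446594e-04 9.70817999e-02 2.87449033e-02
385.447130 5.22873063e-04 9.28010993e-02 4.33707293e-04 9.37576796e-02 2.87720231e-02
419.611825 3.96759044e-04 8.97254579e-02 3.98194886e-04 9.05204119e-02 2.87854319e-02
456.804761 3.01063011e-04 8.66901142e-02 3.71170997e-04 8.73623482e-02 2.87755319e-02
497.294349 2.28448319e-04 8.36982375e-02 3.51064173e-04 8.42777500e-02 2.87352404e-02
541.372794 1.73347880e-04 8.07524720e-02 3.36466185e-04 8.12622861e-02 2.86594151e-02
589.358199 1.31537354e-04 7.78550091e-02 3.26139738e-04 7.83126862e-02 2.85444242e-02
641.596863 9.98112894e-05 7.50076634e-02 3.19028723e-04 7.54265034e-02 2.83878279e-02
698.465782 7.57373721e-05 7.22119479e-02 3.14263147e-04 7.26019484e-02 2.81881426e-02
760.375364 5.74699472e-05 6.94691452e-02 3.11154041e-04 6.98377692e-02 2.79446685e-02
827.772397 4.36085217e-05 6.67803700e-02 3.09177774e-04 6.71331562e-02 2.76573630e-02
901.143268 3.30903934e-05 6.41466229e-02 3.07952369e-04 6.44876656e-02 2.73267462e-02
981.017479 2.51091781e-05 6.15688326e-02 3.07210021e-04 6.19011518e-02 2.69538290e-02
1067.971463 1.90529867e-05 5.90478871e-02 3.06769885e-04 5.93737100e-02 2.65400548e-02
1162.632746 1.44575143e-05 5.65846530e-02 3.06514010e-04 5.69056245e-02 2.60872500e-02
1265.684477 1.09704438e-05 5.41799853e-02 3.06367876e-04 5.44973236e-02 2.55975790e-02
1377.870355 8.32443491e-06 5.18347280e-02 3.06285733e-04 5.21493382e-02 2.50734997e-02
1500.000000 6.31662840e-06 4.95497078e-02 3.06240208e-04 4.98622646e-02 2.45177202e-02
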