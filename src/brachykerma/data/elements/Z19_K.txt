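# element: K  Z: 19  A: 39.098
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 1.11587276e+02 1.87434264e-01 4.69748834e-01 1.12244459e+02 1.11590793e+02
10.886365 8.46730574e+01 1.86825373e-01 4.06620786e-01 8.52665036e+01 8.46768598e+01
11.851295 6.42503959e+01 1.86168413e-01 3.51174337e-01 6.47877387e+01 6.42545046e+01
12.901753 4.87535646e+01 1.85460119e-01 3.02627862e-01 4.92416526e+01 4.87580014e+01
14.045319 3.69944811e+01 1.84697096e-01 2.60248814e-01 3.74394270e+01 3.69992692e+01
15.290247 2.80716220e+01 1.83875831e-01 2.23360155e-01 2.84788580e+01 2.80767853e+01
16.645522 2.13009059e+01 1.82992703e-01 1.91341100e-01 2.16752397e+01 2.13064697e+01
18.120923 1.61632481e+01 1.82044009e-01 1.63625308e-01 1.65089174e+01 1.61692385e+01
19.727099 1.22647643e+01 1.81025982e-01 1.39698187e-01 1.25854884e+01 1.22712082e+01
21.475640 9.30657265e+00 1.79934822e-01 1.19094101e-01 9.60560157e+00 9.31349787e+00
23.379167 7.06188007e+00 1.78766728e-01 1.01393645e-01 7.34204045e+00 7.06931503e+00
25.451415 5.35859463e+00 1.77517939e-01 8.62209900e-02 5.62233356e+00 5.36656821e+00
27.707340 4.06613197e+00 1.76184777e-01 7.32411850e-02 4.31555794e+00 4.07467336e+00
30.163222 3.08540399e+00 1.74763700e-01 6.21573660e-02 3.32232505e+00 3.09454239e+00
32.836786 2.34122204e+00 1.73251356e-01 5.27078570e-02 2.56718125e+00 2.35098646e+00
35.747324 1.77653255e+00 1.71644646e-01 4.46631941e-02 1.99284039e+00 1.78695150e+00
38.915843 1.34804297e+00 1.69940794e-01 3.78231295e-02 1.55580689e+00 1.35914411e+00
42.365208 1.02290265e+00 1.68137410e-01 3.20136800e-02 1.22305374e+00 1.03471246e+00
46.120313 7.76184325e-01 1.66232570e-01 2.70842790e-02 9.69501174e-01 7.88727704e-01
50.208258 5.88973065e-01 1.64224886e-01 2.29050824e-02 7.76103033e-01 6.02272944e-01
54.658543 4.46916100e-01 1.62113579e-01 1.93644627e-02 6.28394142e-01 4.60993027e-01
59.503287 3.39122470e-01 1.59898550e-01 1.63667128e-02 5.15387732e-01 3.53994194e-01
64.777452 2.57328052e-01 1.57580441e-01 1.38299681e-02 4.28738462e-01 2.73009115e-01
70.519100 1.95261985e-01 1.55160693e-01 1.16843473e-02 3.62107025e-01 2.11763333e-01
76.769668 1.48165901e-01 1.52641584e-01 9.87030357e-03 3.10677789e-01 1.65494526e-01
83.574265 1.12429125e-01 1.50026259e-01 8.33717367e-03 2.70792558e-01 1.30587747e-01
90.981998 8.53118575e-02 1.47318740e-01 7.04190972e-03 2.39672507e-01 1.04298664e-01
99.046327 6.47351210e-02 1.44523913e-01 5.94797700e-03 2.15207011e-01 8.45435765e-02
107.825449 4.91213767e-02 1.41647501e-01 5.02440030e-03 1.95793278e-01 6.97401032e-02
117.382723 3.72735791e-02 1.38696004e-01 4.24494228e-03 1.80214525e-01 5.86863205e-02
127.787120 2.82834031e-02 1.35676627e-01 3.58739776e-03 1.67547428e-01 5.04690766e-02
139.113726 2.14616066e-02 1.32597175e-01 3.03298956e-03 1.57091771e-01 4.43944384e-02
151.444284 1.62851887e-02 1.29465941e-01 2.56585219e-03 1.48316982e-01 3.99349316e-02
164.867780 1.23572935e-02 1.26291569e-01 2.17259160e-03 1.40821454e-01 3.66895169e-02
179.481087 9.37678434e-03 1.23082907e-01 1.84191002e-03 1.34301601e-01 3.43532260e-02
195.389668 7.11515711e-03 1.19848862e-01 1.56428638e-03 1.28528305e-01 3.26941212e-02
212.708330 5.39902154e-03 1.16598246e-01 1.33170358e-03 1.23328972e-01 3.15358070e-02
231.562057 4.09680815e-03 1.13339636e-01 1.13741485e-03 1.18573859e-01 3.07441501e-02
252.086914 3.10868124e-03 1.10081236e-01 9.75742359e-04 1.14165659e-01 3.02171894e-02
274.431023 2.35888495e-03 1.06830771e-01 8.41901751e-04 1.10031558e-01 2.98774645e-02
298.755637 1.78993527e-03 1.03595394e-01 7.31847780e-04 1.06117177e-01 2.96661783e-02
325.236299 1.35821303e-03 1.00381615e-01 6.42137402e-04 1.02381965e-01 2.95387534e-02
354.064116 1.03061974e-03 9.71952671e-02 5.69808949e-04 9.87956958e-02 2.94614466e-02
385.447130 7.82040102e-04 9.40414891e-02 5.12278273e-04 9.53358075e-02 2.94087714e-02
419.611825 5.93416462e-04 9.09247384e-02 4.67254750e-04 9.19854096e-02 2.93615355e-02
456.804761 4.50287775e-04 8.78488240e-02 4.32680542e-04 8.87317923e-02 2.93053496e-02
497.294349 3.41680916e-04 8.48169575e-02 4.06694913e-04 8.55653333e-02 2.92294980e-02
541.372794 2.59269416e-04 8.18318186e-02 3.87621684e-04 8.24787097e-02 2.91260846e-02
589.358199 1.96735102e-04 7.88956279e-02 3.73973503e-04 7.94663365e-02 2.89893918e-02
641.596863 1.49283711e-04 7.60102242e-02 3.64463437e-04 7.65239713e-02 2.88154011e-02
698.465782 1.13277326e-04 7.31771409e-02 3.58014097e-04 7.36484323e-02 2.86014361e-02
760.375364 8.59554768e-05 7.03976775e-02 3.53757172e-04 7.08373902e-02 2.83458974e-02
827.772397 6.52235030e-05 6.76729638e-02 3.51020723e-04 6.80892081e-02 2.80480665e-02
901.143268 4.94919638e-05 6.50040138e-02 3.49305777e-04 6.54028115e-02 2.77079579e-02
981.017479 3.75547826e-05 6.23917685e-02 3.48256473e-04 6.27775798e-02 2.73262069e-02
1067.971463 2.84967819e-05 5.98371278e-02 3.47628611e-04 6.02132532e-02 2.69039812e-02
1162.632746 2.16235196e-05 5.73409698e-02 3.47260540e-04 5.77098538e-02 2.64429079e-02
1265.684477 1.64080493e-05 5.49041610e-02 3.47048741e-04 5.52676178e-02 2.59450100e-02
1377.870355 1.24505208e-05 5.25275568e-02 3.46928885e-04 5.28869362e-02 2.54126497e-02
1500.000000 9.44752574e-06 5.02119947e-02 3.46862062e-04 5.05683043e-02 2.48484732e-02
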