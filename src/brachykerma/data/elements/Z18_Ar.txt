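# element: Ar  Z: 18  A: 39.948
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 8.56267076e+01 1.73791043e-01 4.00265003e-01 8.62007636e+01 8.56299685e+01
10.886365 6.49740310e+01 1.73226473e-01 3.46303748e-01 6.54935613e+01 6.49775567e+01
11.851295 4.93026630e+01 1.72617333e-01 2.98941334e-01 4.97742217e+01 4.93064726e+01
12.901753 3.74111402e+01 1.71960595e-01 2.57499473e-01 3.78406002e+01 3.74152540e+01
14.045319 2.83877852e+01 1.71253112e-01 2.21344786e-01 2.87803831e+01 2.83922247e+01
15.290247 2.15408123e+01 1.70491626e-01 1.89893093e-01 2.19011970e+01 2.15455998e+01
16.645522 1.63452905e+01 1.69672781e-01 1.62609415e-01 1.66775727e+01 1.63504493e+01
18.120923 1.24028991e+01 1.68793141e-01 1.39006125e-01 1.27106983e+01 1.24084534e+01
19.727099 9.41139010e+00 1.67849216e-01 1.18640531e-01 9.69787985e+00 9.41736495e+00
21.475640 7.14141615e+00 1.66837481e-01 1.01112427e-01 7.40936606e+00 7.14783729e+00
23.379167 5.41894705e+00 1.65754412e-01 8.60617223e-02 5.67076319e+00 5.42584082e+00
25.451415 4.11192774e+00 1.64596521e-01 7.31661048e-02 4.34969037e+00 4.11932093e+00
27.707340 3.12015407e+00 1.63360399e-01 6.21386586e-02 3.34565313e+00 3.12807373e+00
30.163222 2.36759060e+00 1.62042761e-01 5.27253905e-02 2.58235875e+00 2.37606382e+00
32.836786 1.79654116e+00 1.60640500e-01 4.47026660e-02 2.00188433e+00 1.80559484e+00
35.747324 1.36322562e+00 1.59150742e-01 3.78745877e-02 1.56025095e+00 1.37288618e+00
38.915843 1.03442333e+00 1.57570912e-01 3.20703661e-02 1.22406460e+00 1.04471643e+00
42.365208 7.84926283e-01 1.55898795e-01 2.71417429e-02 9.67966821e-01 7.95876465e-01
46.120313 5.95606512e-01 1.54132607e-01 2.29605144e-02 7.72699634e-01 6.07236867e-01
50.208258 4.51949597e-01 1.52271061e-01 1.94161980e-02 6.23636856e-01 4.64281387e-01
54.658543 3.42941916e-01 1.50313435e-01 1.64138688e-02 5.09669220e-01 3.55994192e-01
59.503287 2.60226270e-01 1.48259636e-01 1.38721831e-02 4.22358089e-01 2.74015490e-01
64.777452 1.97461168e-01 1.46110261e-01 1.17215942e-02 3.55293024e-01 2.12000817e-01
70.519100 1.49834654e-01 1.43866645e-01 9.90275915e-03 3.03604058e-01 1.65134880e-01
76.769668 1.13695385e-01 1.41530901e-01 8.36512829e-03 2.63591414e-01 1.29762670e-01
83.574265 8.62727023e-02 1.39105944e-01 7.06570602e-03 2.32444352e-01 1.03109569e-01
90.981998 6.54642155e-02 1.36595503e-01 5.96796909e-03 2.08027687e-01 8.30689843e-02
99.046327 4.96746177e-02 1.34004109e-01 5.04092727e-03 1.88719654e-01 6.80412284e-02
107.825449 3.76933815e-02 1.31337069e-01 4.25831151e-03 1.73288762e-01 5.68112840e-02
117.382723 2.86019515e-02 1.28600410e-01 3.59787489e-03 1.60800237e-01 4.84560731e-02
127.787120 2.17033229e-02 1.25800811e-01 3.04079278e-03 1.50544927e-01 4.22741154e-02
139.113726 1.64686045e-02 1.22945511e-01 2.57114937e-03 1.41985265e-01 3.77321701e-02
151.444284 1.24964704e-02 1.20042198e-01 2.17549922e-03 1.34714168e-01 3.44247636e-02
164.867780 9.48239257e-03 1.17098886e-01 1.84249340e-03 1.28423772e-01 3.20434889e-02
179.481087 7.19529323e-03 1.14123780e-01 1.56256101e-03 1.22881635e-01 3.03537156e-02
195.389668 5.45982929e-03 1.11125140e-01 1.32763775e-03 1.17912607e-01 2.91769169e-02
212.708330 4.14294941e-03 1.08111134e-01 1.13093424e-03 1.13385018e-01 2.83772549e-02
231.562057 3.14369349e-03 1.05089716e-01 9.66737260e-04 1.09200146e-01 2.78513924e-02
252.086914 2.38545244e-03 1.02068493e-01 8.30238083e-04 1.05284183e-01 2.75207495e-02
274.431023 1.81009483e-03 9.90546275e-02 7.17382650e-04 1.01582105e-01 2.73256145e-02
298.755637 1.37351022e-03 9.60547511e-02 6.24739401e-04 9.80530007e-02 2.72206593e-02
325.236299 1.04222734e-03 9.30749012e-02 5.49382059e-04 9.46665106e-02 2.71715241e-02
354.064116 7.90848012e-04 9.01204855e-02 4.88786519e-04 9.14001201e-02 2.71522131e-02
385.447130 6.00099954e-04 8.71962690e-02 4.40743077e-04 8.82371121e-02 2.71431098e-02
419.611825 4.55359247e-04 8.43063846e-02 4.03286742e-04 8.51650306e-02 2.71294652e-02
456.804761 3.45529177e-04 8.14543640e-02 3.74648512e-04 8.21745417e-02 2.71002494e-02
497.294349 2.62189498e-04 7.86431852e-02 3.53228614e-04 7.92586033e-02 2.70472808e-02
541.372794 1.98950877e-04 7.58753326e-02 3.37589208e-04 7.64118727e-02 2.69645689e-02
589.358199 1.50965053e-04 7.31528654e-02 3.26460251e-04 7.36302907e-02 2.68478226e-02
641.596863 1.14553138e-04 7.04774884e-02 3.18749892e-04 7.09107914e-02 2.66940821e-02
698.465782 8.69235705e-05 6.78506234e-02 3.13551105e-04 6.82510981e-02 2.65014474e-02
760.375364 6.59580980e-05 6.52734754e-02 3.10139055e-04 6.56495726e-02 2.62688769e-02
827.772397 5.00493786e-05 6.27470919e-02 3.07957722e-04 6.31050990e-02 2.59960391e-02
901.143268 3.79777522e-05 6.02724130e-02 3.06597783e-04 6.06169886e-02 2.56832015e-02
981.017479 2.88177336e-05 5.78503115e-02 3.05769744e-04 5.81848989e-02 2.53311462e-02
1067.971463 2.18670596e-05 5.54816214e-02 3.05276503e-04 5.58087649e-02 2.49411021e-02
1162.632746 1.65928488e-05 5.31671571e-02 3.04988536e-04 5.34887385e-02 2.45146887e-02
1265.684477 1.25907477e-05 5.09077221e-02 3.04823444e-04 5.12251363e-02 2.40538663e-02
1377.870355 9.55393071e-06 4.87041094e-02 3.04730327e-04 4.90183937e-02 2.35608888e-02
1500.000000 7.24957677e-06 4.65570956e-02 3.04678564e-04 4.68690238e-02 2.30382584e-02
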