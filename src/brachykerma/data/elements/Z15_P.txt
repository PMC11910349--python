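# element: P  Z: 15  A: 30.974
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 4.86173615e+01 1.86785815e-01 3.23280640e-01 4.91274279e+01 4.86208662e+01
10.886365 3.68911294e+01 1.86179031e-01 2.79243362e-01 3.73565518e+01 3.68949187e+01
11.851295 2.79931981e+01 1.85524343e-01 2.40677777e-01 2.84194002e+01 2.79972926e+01
12.901753 2.12413974e+01 1.84818500e-01 2.07004533e-01 2.16332204e+01 2.12458189e+01
14.045319 1.61180927e+01 1.84058117e-01 1.77687764e-01 1.64798386e+01 1.61228642e+01
15.290247 1.22305001e+01 1.83239692e-01 1.52235915e-01 1.25659757e+01 1.22356456e+01
16.645522 9.28057282e+00 1.82359620e-01 1.30200394e-01 9.59313283e+00 9.28611737e+00
18.120923 7.04215126e+00 1.81414208e-01 1.11173488e-01 7.33473895e+00 7.04812089e+00
19.727099 5.34362429e+00 1.80399703e-01 9.47861513e-02 5.61881014e+00 5.35004590e+00
21.475640 4.05477240e+00 1.79312318e-01 8.07058673e-02 4.31479058e+00 4.06167366e+00
23.379167 3.07678428e+00 1.78148265e-01 6.86345504e-02 3.32356709e+00 3.08419351e+00
25.451415 2.33468135e+00 1.76903796e-01 5.83064318e-02 2.56989158e+00 2.34262735e+00
27.707340 1.77156944e+00 1.75575247e-01 4.94858686e-02 1.99663056e+00 1.78008127e+00
30.163222 1.34427693e+00 1.74159086e-01 4.19650689e-02 1.56040109e+00 1.35338372e+00
32.836786 1.02004496e+00 1.72651974e-01 3.55617535e-02 1.22825868e+00 1.02977560e+00
35.747324 7.74015894e-01 1.71050823e-01 3.01167986e-02 9.75183516e-01 7.84398802e-01
38.915843 5.87327648e-01 1.69352866e-01 2.54919088e-02 7.82172422e-01 5.98390387e-01
42.365208 4.45667548e-01 1.67555721e-01 2.15673701e-02 6.34790639e-01 4.57436501e-01
46.120313 3.38175061e-01 1.65657471e-01 1.82399197e-02 5.22072452e-01 3.50675045e-01
50.208258 2.56609153e-01 1.63656732e-01 1.54207636e-02 4.35686649e-01 2.69863020e-01
54.658543 1.94716480e-01 1.61552729e-01 1.30337576e-02 3.69302967e-01 2.08744706e-01
59.503287 1.47751969e-01 1.59345363e-01 1.10137605e-02 3.18111092e-01 1.62572242e-01
64.777452 1.12115031e-01 1.57035275e-01 9.30515857e-03 2.78455465e-01 1.27741844e-01
70.519100 8.50735212e-02 1.54623898e-01 7.86055696e-03 2.47557976e-01 1.01517782e-01
76.769668 6.45542701e-02 1.52113504e-01 6.63962731e-03 2.23307402e-01 8.18229450e-02
83.574265 4.89841460e-02 1.49507227e-01 5.60810012e-03 2.04099474e-01 6.70799457e-02
90.981998 3.71694477e-02 1.46809075e-01 4.73688858e-03 1.88715411e-01 5.60905671e-02
99.046327 2.82043876e-02 1.44023917e-01 4.00133029e-03 1.76229635e-01 4.79443136e-02
107.825449 2.14016491e-02 1.41157456e-01 3.38053379e-03 1.65939639e-01 4.19490429e-02
117.382723 1.62396927e-02 1.38216170e-01 2.85681717e-03 1.57312680e-01 3.75783544e-02
127.787120 1.23227708e-02 1.35207239e-01 2.41522734e-03 1.49945237e-01 3.44316906e-02
139.113726 9.35058836e-03 1.32138441e-01 2.04312916e-03 1.43532158e-01 3.22040816e-02
151.444284 7.09527945e-03 1.29018040e-01 1.72985507e-03 1.37843175e-01 3.06632035e-02
164.867780 5.38393826e-03 1.25854649e-01 1.46640651e-03 1.32704994e-01 2.96319817e-02
179.481087 4.08536287e-03 1.22657088e-01 1.24519954e-03 1.27987650e-01 2.89753958e-02
195.389668 3.09999650e-03 1.19434232e-01 1.05984785e-03 1.23594076e-01 2.85904674e-02
212.708330 2.35229492e-03 1.16194862e-01 9.04976927e-04 1.19452134e-01 2.83986573e-02
231.562057 1.78493471e-03 1.12947525e-01 7.76063910e-04 1.15508524e-01 2.83400873e-02
252.086914 1.35441858e-03 1.09700398e-01 6.69298258e-04 1.11724115e-01 2.83691419e-02
274.431023 1.02774049e-03 1.06461179e-01 5.81459193e-04 1.08070378e-01 2.84511165e-02
298.755637 7.79855312e-04 1.03236994e-01 5.09807066e-04 1.04526657e-01 2.85596575e-02
325.236299 5.91758631e-04 1.00034334e-01 4.51987375e-04 1.01078080e-01 2.86748054e-02
354.064116 4.49029803e-04 9.68590096e-02 4.05948040e-04 9.77139875e-02 2.87814972e-02
385.447130 3.40726360e-04 9.37161425e-02 3.69872096e-04 9.44267409e-02 2.88684204e-02
419.611825 2.58545093e-04 9.06101745e-02 3.42128511e-04 9.12108481e-02 2.89271377e-02
456.804761 1.96185482e-04 8.75449015e-02 3.21242700e-04 8.80623296e-02 2.89514201e-02
497.294349 1.48866656e-04 8.45235241e-02 3.05885467e-04 8.49782762e-02 2.89367432e-02
541.372794 1.12960862e-04 8.15487126e-02 2.94875644e-04 8.19565491e-02 2.88799082e-02
589.358199 8.57153425e-05 7.86226799e-02 2.87189064e-04 7.89955843e-02 2.87787607e-02
641.596863 6.50412877e-05 7.57472586e-02 2.81966098e-04 7.60942660e-02 2.86319852e-02
698.465782 4.93536978e-05 7.29239767e-02 2.78511959e-04 7.32518423e-02 2.84389546e-02
760.375364 3.74498656e-05 7.01541292e-02 2.76287382e-04 7.04678664e-02 2.81996235e-02
827.772397 2.84171703e-05 6.74388419e-02 2.74890733e-04 6.77421498e-02 2.79144505e-02
901.143268 2.15631099e-05 6.47791254e-02 2.74034748e-04 6.50747232e-02 2.75843416e-02
981.017479 1.63622100e-05 6.21759175e-02 2.73521765e-04 6.24658015e-02 2.72106063e-02
1067.971463 1.24157377e-05 5.96301148e-02 2.73220614e-04 5.99157511e-02 2.67949215e-02
1162.632746 9.42113213e-06 5.71425925e-02 2.73047101e-04 5.74250607e-02 2.63392982e-02
1265.684477 7.14880846e-06 5.47142141e-02 2.72948799e-04 5.49943117e-02 2.58460480e-02
1377.870355 5.42455638e-06 5.23458321e-02 2.72893936e-04 5.26241506e-02 2.53177490e-02
1500.000000 4.11618413e-06 5.00382809e-02 2.72863721e-04 5.03152608e-02 2.47572086e-02
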