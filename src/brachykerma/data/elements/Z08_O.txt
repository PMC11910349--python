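# element: O  Z: 8  A: 15.999
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 5.56147663e+00 1.92862182e-01 1.23555548e-01 5.87789436e+00 5.56509542e+00
10.886365 4.22007999e+00 1.92235658e-01 1.06168510e-01 4.51848416e+00 4.22399250e+00
11.851295 3.20222062e+00 1.91559673e-01 9.10510145e-02 3.48483130e+00 3.20644826e+00
12.901753 2.42986315e+00 1.90830867e-01 7.79435534e-02 2.69863757e+00 2.43442848e+00
14.045319 1.84379393e+00 1.90045748e-01 6.66097660e-02 2.10044945e+00 1.84872064e+00
15.290247 1.39908129e+00 1.89200699e-01 5.68352313e-02 1.64511722e+00 1.40439417e+00
16.645522 1.06163081e+00 1.88291997e-01 4.84262661e-02 1.29834907e+00 1.06735573e+00
18.120923 8.05571476e-01 1.87315830e-01 4.12087621e-02 1.03409607e+00 8.11735305e-01
19.727099 6.11272202e-01 1.86268322e-01 3.50270316e-02 8.32567556e-01 6.17902712e-01
21.475640 4.63836812e-01 1.85145563e-01 2.97426254e-02 6.78725000e-01 4.70962581e-01
23.379167 3.51962002e-01 1.83943642e-01 2.52331041e-02 5.61138748e-01 3.59612268e-01
25.451415 2.67070762e-01 1.82658689e-01 2.13907667e-02 4.71120218e-01 2.75275253e-01
27.707340 2.02654808e-01 1.81286920e-01 1.81213547e-02 4.02063083e-01 2.11443540e-01
30.163222 1.53775617e-01 1.79824690e-01 1.53427582e-02 3.48943065e-01 1.63178656e-01
32.836786 1.16685810e-01 1.78268550e-01 1.29837523e-02 3.07938112e-01 1.26733005e-01
35.747324 8.85418537e-02 1.76615312e-01 1.09827871e-02 2.76139953e-01 9.92625296e-02
38.915843 6.71860605e-02 1.74862117e-01 9.28685109e-03 2.51335029e-01 7.86086836e-02
42.365208 5.09811635e-02 1.73006509e-01 7.85042110e-03 2.31838094e-01 6.31329748e-02
46.120313 3.86847958e-02 1.71046507e-01 6.63450412e-03 2.16365807e-01 5.15914192e-02
50.208258 2.93542423e-02 1.68980682e-01 5.60577504e-03 2.03940699e-01 4.30392731e-02
54.658543 2.22741655e-02 1.66808233e-01 4.73580755e-03 1.93818206e-01 3.67587465e-02
59.503287 1.69017630e-02 1.64529059e-01 4.00039443e-03 1.85431217e-01 3.22041576e-02
64.777452 1.28251536e-02 1.62143821e-01 3.37895109e-03 1.78347925e-01 2.89603253e-02
70.519100 9.73179922e-03 1.59653999e-01 2.85399545e-03 1.72239794e-01 2.67110113e-02
76.769668 7.38454441e-03 1.57061939e-01 2.41069668e-03 1.66857180e-01 2.52149900e-02
83.574265 5.60343415e-03 1.54370877e-01 2.03648550e-03 1.62010797e-01 2.42879119e-02
90.981998 4.25191759e-03 1.51584950e-01 1.72071885e-03 1.57557587e-01 2.37885638e-02
99.046327 3.22637917e-03 1.48709188e-01 1.45439228e-03 1.53389959e-01 2.36084687e-02
107.825449 2.44819480e-03 1.45749477e-01 1.22989384e-03 1.49427566e-01 2.36640199e-02
117.382723 1.85770409e-03 1.42712508e-01 1.04079405e-03 1.45611006e-01 2.38905381e-02
127.787120 1.40963639e-03 1.39605692e-01 8.81666817e-04 1.41896996e-01 2.42377859e-02
139.113726 1.06964009e-03 1.36437063e-01 7.47936909e-04 1.38254640e-01 2.46665849e-02
151.444284 8.11648960e-04 1.33215152e-01 6.35749904e-04 1.34662551e-01 2.51462658e-02
164.867780 6.15883831e-04 1.29948852e-01 5.41861133e-04 1.31106597e-01 2.56527452e-02
179.481087 4.67336142e-04 1.26647270e-01 4.63540312e-04 1.27578147e-01 2.61670718e-02
195.389668 3.54617313e-04 1.23319571e-01 3.98489017e-04 1.24072677e-01 2.66743239e-02
212.708330 2.69085627e-04 1.19974821e-01 3.44768511e-04 1.20588675e-01 2.71627675e-02
231.562057 2.04183699e-04 1.16621843e-01 3.00735988e-04 1.17126763e-01 2.76232072e-02
252.086914 1.54935748e-04 1.13269083e-01 2.64988029e-04 1.13689007e-01 2.80484804e-02
274.431023 1.17566124e-04 1.09924489e-01 2.36311059e-04 1.10278366e-01 2.84330575e-02
298.755637 8.92098412e-05 1.06595418e-01 2.13639569e-04 1.06898267e-01 2.87727223e-02
325.236299 6.76929331e-05 1.03288571e-01 1.96023550e-04 1.03552287e-01 2.90643149e-02
354.064116 5.13657813e-05 1.00009949e-01 1.82606440e-04 1.00243922e-01 2.93055223e-02
385.447130 3.89766460e-05 9.67648410e-02 1.72613840e-04 9.69764315e-02 2.94947108e-02
419.611825 2.95756999e-05 9.35578322e-02 1.65351377e-04 9.37527593e-02 2.96307920e-02
456.804761 2.24422087e-05 9.03928422e-02 1.60208341e-04 9.05754927e-02 2.97131191e-02
497.294349 1.70292752e-05 8.72731757e-02 1.56662752e-04 8.74468678e-02 2.97414100e-02
541.372794 1.29219105e-05 8.42015900e-02 1.54283939e-04 8.43687959e-02 2.97156925e-02
589.358199 9.80521895e-06 8.11803701e-02 1.52730270e-04 8.13429055e-02 2.96362698e-02
641.596863 7.44025572e-06 7.82114078e-02 1.51741654e-04 7.83705897e-02 2.95037011e-02
698.465782 5.64570821e-06 7.52962811e-02 1.51128039e-04 7.54530549e-02 2.93187944e-02
760.375364 4.28399539e-06 7.24363272e-02 1.50755966e-04 7.25913671e-02 2.90826069e-02
827.772397 3.25071998e-06 6.96327084e-02 1.50535175e-04 6.97864943e-02 2.87964502e-02
901.143268 2.46666475e-06 6.68864681e-02 1.50406719e-04 6.70393414e-02 2.84618954e-02
981.017479 1.87171919e-06 6.41985747e-02 1.50333303e-04 6.43507797e-02 2.80807772e-02
1067.971463 1.42027113e-06 6.15699540e-02 1.50292011e-04 6.17216663e-02 2.76551931e-02
1162.632746 1.07770978e-06 5.90015096e-02 1.50269113e-04 5.91528564e-02 2.71874973e-02
1265.684477 8.17772293e-07 5.64941332e-02 1.50256573e-04 5.66452075e-02 2.66802874e-02
1377.870355 6.20530251e-07 5.40487048e-02 1.50249780e-04 5.41995751e-02 2.61363853e-02
1500.000000 4.70861872e-07 5.16660862e-02 1.50246136e-04 5.18168032e-02 2.55588111e-02
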