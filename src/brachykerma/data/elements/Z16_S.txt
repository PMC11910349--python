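# element: S  Z: 16  A: 32.06
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 6.27992443e+01 1.92489211e-01 3.68659077e-01 6.33603926e+01 6.28028561e+01
10.886365 4.76524225e+01 1.91863898e-01 3.18621768e-01 4.81629082e+01 4.76563275e+01
11.851295 3.61589283e+01 1.91189220e-01 2.74767502e-01 3.66248850e+01 3.61631478e+01
12.901753 2.74375997e+01 1.90461824e-01 2.36448000e-01 2.78645096e+01 2.74421562e+01
14.045319 2.08198062e+01 1.89678224e-01 2.03061880e-01 2.12125463e+01 2.08247234e+01
15.290247 1.57981869e+01 1.88834809e-01 1.74056547e-01 1.61610783e+01 1.58034896e+01
16.645522 1.19877538e+01 1.87927864e-01 1.48927133e-01 1.23246088e+01 1.19934677e+01
18.120923 9.09637553e+00 1.86953585e-01 1.27214312e-01 9.41054343e+00 9.10252744e+00
19.727099 6.90238131e+00 1.85908102e-01 1.08501874e-01 7.19679129e+00 6.90899900e+00
21.475640 5.23756606e+00 1.84787515e-01 9.24143533e-02 5.51476793e+00 5.24467805e+00
23.379167 3.97429481e+00 1.83587918e-01 7.86147119e-02 4.23649744e+00 3.98193028e+00
25.451415 3.01571743e+00 1.82305450e-01 6.68020330e-02 3.26482491e+00 3.02390606e+00
27.707340 2.28834348e+00 1.80936334e-01 5.67091336e-02 2.52598895e+00 2.29711521e+00
30.163222 1.73640800e+00 1.79476932e-01 4.81000872e-02 1.96398502e+00 1.74579286e+00
32.836786 1.31759623e+00 1.77923801e-01 4.07676669e-02 1.53628770e+00 1.32762400e+00
35.747324 9.99799490e-01 1.76273760e-01 3.45307544e-02 1.21060400e+00 1.01049943e+00
38.915843 7.58653520e-01 1.74523956e-01 2.92317689e-02 9.62409245e-01 7.70054053e-01
42.365208 5.75670591e-01 1.72671937e-01 2.47341692e-02 7.73076697e-01 5.87798902e-01
46.120313 4.36822107e-01 1.70715725e-01 2.09200772e-02 6.28457909e-01 4.49703771e-01
50.208258 3.31463091e-01 1.68653895e-01 1.76880549e-02 5.17805041e-01 3.45121657e-01
54.658543 2.51516072e-01 1.66485647e-01 1.49510582e-02 4.32952778e-01 2.65972642e-01
59.503287 1.90851821e-01 1.64210881e-01 1.26345785e-02 3.67697280e-01 2.06124623e-01
64.777452 1.44819444e-01 1.61830255e-01 1.06749732e-02 3.17324672e-01 1.60923412e-01
70.519100 1.09889815e-01 1.59345248e-01 9.01798204e-03 2.78253045e-01 1.26836191e-01
76.769668 8.33850142e-02 1.56758201e-01 7.61741779e-03 2.47760633e-01 1.01180978e-01
83.574265 6.32730214e-02 1.54072343e-01 6.43401955e-03 2.23779384e-01 8.19213657e-02
90.981998 4.80119273e-02 1.51291804e-01 5.43445461e-03 2.04738186e-01 6.75107921e-02
99.046327 3.64317226e-02 1.48421603e-01 4.59045343e-03 1.89443779e-01 5.67743957e-02
107.825449 2.76445976e-02 1.45467616e-01 3.87806343e-03 1.76990277e-01 4.88193939e-02
117.382723 2.09768773e-02 1.42436520e-01 3.27700760e-03 1.66690405e-01 4.29671026e-02
127.787120 1.59173734e-02 1.39335713e-01 2.77013466e-03 1.58023221e-01 3.87013761e-02
139.113726 1.20781932e-02 1.36173211e-01 2.34294904e-03 1.50594353e-01 3.56295044e-02
151.444284 9.16500143e-03 1.32957530e-01 1.98320984e-03 1.44105742e-01 3.34525582e-02
164.867780 6.95445503e-03 1.29697547e-01 1.68058900e-03 1.38332591e-01 3.19428983e-02
179.481087 5.27707990e-03 1.26402350e-01 1.42638013e-03 1.33105810e-01 3.09271155e-02
195.389668 4.00427814e-03 1.23081086e-01 1.21325026e-03 1.28298615e-01 3.02730857e-02
212.708330 3.03846895e-03 1.19742804e-01 1.03502744e-03 1.23816301e-01 2.98801418e-02
231.562057 2.30560746e-03 1.16396311e-01 8.86518138e-04 1.19588437e-01 2.96716060e-02
252.086914 1.74950801e-03 1.13050035e-01 7.63348733e-04 1.15562892e-01 2.95891101e-02
274.431023 1.32753659e-03 1.09711908e-01 6.61826466e-04 1.11701271e-01 2.95882693e-02
298.755637 1.00734229e-03 1.06389276e-01 5.78816362e-04 1.07975434e-01 2.96353845e-02
325.236299 7.64377040e-04 1.03088824e-01 5.11632229e-04 1.04364833e-01 2.97049232e-02
354.064116 5.80013630e-04 9.98165428e-02 4.57941856e-04 1.00854498e-01 2.97775963e-02
385.447130 4.40117630e-04 9.65777100e-02 4.15688447e-04 9.74335161e-02 2.98388881e-02
419.611825 3.33963752e-04 9.33769031e-02 3.83031263e-04 9.40938981e-02 2.98779350e-02
456.804761 2.53413588e-04 9.02180338e-02 3.58307714e-04 9.08297551e-02 2.98866725e-02
497.294349 1.92291667e-04 8.71044004e-02 3.40016412e-04 8.76367085e-02 2.98591892e-02
541.372794 1.45912007e-04 8.40387548e-02 3.26816944e-04 8.45114837e-02 2.97912412e-02
589.358199 1.10718858e-04 8.10233774e-02 3.17538808e-04 8.14516351e-02 2.96798896e-02
641.596863 8.40140969e-05 7.80601568e-02 3.11190832e-04 7.84553617e-02 2.95232329e-02
698.465782 6.37503729e-05 7.51506676e-02 3.06963924e-04 7.55213819e-02 2.93202111e-02
760.375364 4.83741443e-05 7.22962444e-02 3.04223535e-04 7.26488421e-02 2.90704633e-02
827.772397 3.67065749e-05 6.94980475e-02 3.02492110e-04 6.98372462e-02 2.87742236e-02
901.143268 2.78531571e-05 6.67571181e-02 3.01424608e-04 6.70863958e-02 2.84322449e-02
981.017479 2.11351335e-05 6.40744227e-02 3.00781328e-04 6.43963392e-02 2.80457395e-02
1067.971463 1.60374591e-05 6.14508854e-02 3.00401774e-04 6.17673247e-02 2.76163314e-02
1162.632746 1.21693148e-05 5.88874081e-02 3.00182087e-04 5.91997595e-02 2.71460138e-02
1265.684477 9.23414507e-06 5.63848806e-02 3.00057116e-04 5.66941719e-02 2.66371090e-02
1377.870355 7.00692162e-06 5.39441814e-02 2.99987115e-04 5.42511754e-02 2.60922284e-02
1500.000000 5.31689184e-06 5.15661705e-02 2.99948439e-04 5.18714359e-02 2.55142305e-02
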