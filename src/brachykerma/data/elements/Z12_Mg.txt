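# element: Mg  Z: 12  A: 24.305
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 2.26985437e+01 1.90430079e-01 2.31960211e-01 2.31209340e+01 2.27021169e+01
10.886365 1.72237837e+01 1.89811456e-01 1.99978069e-01 1.76135732e+01 1.72276468e+01
11.851295 1.30695047e+01 1.89143995e-01 1.72042948e-01 1.34306916e+01 1.30736790e+01
12.901753 9.91721421e+00 1.88424381e-01 1.47713298e-01 1.02533519e+01 9.92172197e+00
14.045319 7.52523835e+00 1.87649162e-01 1.26583750e-01 7.83947127e+00 7.53010293e+00
15.290247 5.71019352e+00 1.86814770e-01 1.08284168e-01 6.00529245e+00 5.71543940e+00
16.645522 4.33292721e+00 1.85917527e-01 9.24779745e-02 4.61132271e+00 4.33857993e+00
18.120923 3.28784972e+00 1.84953670e-01 7.88603547e-02 3.55166375e+00 3.29393582e+00
19.727099 2.49483900e+00 1.83919371e-01 6.71564982e-02 2.74591487e+00 2.50138590e+00
21.475640 1.89309798e+00 1.82810771e-01 5.71198903e-02 2.13302864e+00 1.90013389e+00
23.379167 1.43649348e+00 1.81624007e-01 4.85305907e-02 1.66664807e+00 1.44404727e+00
25.451415 1.09001939e+00 1.80355258e-01 4.11934558e-02 1.31156811e+00 1.09812042e+00
27.707340 8.27112892e-01 1.79000788e-01 3.49362913e-02 1.04104997e+00 8.35790793e-01
30.163222 6.27617951e-01 1.77556997e-01 2.96079497e-02 8.34782898e-01 6.36902412e-01
32.836786 4.76240058e-01 1.76020481e-01 2.50764075e-02 6.77336947e-01 4.86160552e-01
35.747324 3.61373656e-01 1.74388091e-01 2.12268618e-02 5.56988609e-01 3.71959138e-01
38.915843 2.74212378e-01 1.72657006e-01 1.79598877e-02 4.64829272e-01 2.85490955e-01
42.365208 2.08073907e-01 1.70824798e-01 1.51896879e-02 3.94088393e-01 2.20072477e-01
46.120313 1.57887660e-01 1.68889512e-01 1.28424594e-02 3.39619632e-01 1.70631523e-01
50.208258 1.19806051e-01 1.66849739e-01 1.08548934e-02 2.97510683e-01 1.33318506e-01
54.658543 9.09095107e-02 1.64704686e-01 9.17281391e-03 2.64787010e-01 1.05211433e-01
59.503287 6.89826520e-02 1.62454253e-01 7.74995795e-03 2.39186863e-01 8.40920746e-02
64.777452 5.23444273e-02 1.60099094e-01 6.54689115e-03 2.18990412e-01 6.82761253e-02
70.519100 3.97192481e-02 1.57640671e-01 5.53005275e-03 2.02889971e-01 5.64843426e-02
76.769668 3.01391906e-02 1.55081298e-01 4.67091960e-03 1.89891408e-01 4.77447840e-02
83.574265 2.28697887e-02 1.52424172e-01 3.94527889e-03 1.79239239e-01 4.13186444e-02
90.981998 1.73537253e-02 1.49673377e-01 3.33259834e-03 1.70359700e-01 3.66440031e-02
99.046327 1.31681051e-02 1.46833879e-01 2.81548312e-03 1.62817468e-01 3.32931648e-02
107.825449 9.99203278e-03 1.43911493e-01 2.37920928e-03 1.56282735e-01 3.09403141e-02
117.382723 7.58201111e-03 1.40912821e-01 2.01132391e-03 1.50506156e-01 2.93369984e-02
127.787120 5.75327300e-03 1.37845185e-01 1.70130342e-03 1.45299761e-01 2.82935464e-02
139.113726 4.36561616e-03 1.34716513e-01 1.44026204e-03 1.40522392e-01 2.76649899e-02
151.444284 3.31265429e-03 1.31535232e-01 1.22070341e-03 1.36068590e-01 2.73403977e-02
164.867780 2.51366085e-03 1.28310122e-01 1.03630894e-03 1.31860092e-01 2.72347930e-02
179.481087 1.90738010e-03 1.25050176e-01 8.81757338e-04 1.27839313e-01 2.72830273e-02
195.389668 1.44733083e-03 1.21764440e-01 7.52570124e-04 1.23964341e-01 2.74351308e-02
212.708330 1.09824284e-03 1.18461869e-01 6.44978660e-04 1.20205091e-01 2.76527799e-02
231.562057 8.33352891e-04 1.15151175e-01 5.55808589e-04 1.16540336e-01 2.79066068e-02
252.086914 6.32352897e-04 1.11840695e-01 4.82378327e-04 1.12955426e-01 2.81741440e-02
274.431023 4.79832962e-04 1.08538278e-01 4.22409132e-04 1.09440520e-01 2.84382497e-02
298.755637 3.64099971e-04 1.05251188e-01 3.73945551e-04 1.05989234e-01 2.86858969e-02
325.236299 2.76281122e-04 1.01986043e-01 3.35286530e-04 1.02597610e-01 2.89072390e-02
354.064116 2.09643681e-04 9.87487665e-02 3.04928825e-04 9.92633391e-02 2.90948885e-02
385.447130 1.59078814e-04 9.55445808e-02 2.81524961e-04 9.59851846e-02 2.92433593e-02
419.611825 1.20709905e-04 9.23780142e-02 2.63857181e-04 9.27625813e-02 2.93486379e-02
456.804761 9.15953605e-05 8.92529365e-02 2.50826719e-04 8.95953586e-02 2.94078558e-02
497.294349 6.95030787e-05 8.61726109e-02 2.41454858e-04 8.64835688e-02 2.94190423e-02
541.372794 5.27393300e-05 8.31397597e-02 2.34889964e-04 8.34273890e-02 2.93809409e-02
589.358199 4.00189026e-05 8.01566390e-02 2.30414091e-04 8.04270720e-02 2.92928768e-02
641.596863 3.03665701e-05 7.72251171e-02 2.27444122e-04 7.74829278e-02 2.91546627e-02
698.465782 2.30423255e-05 7.43467518e-02 2.25525150e-04 7.45953193e-02 2.89665354e-02
760.375364 1.74846472e-05 7.15228635e-02 2.24316634e-04 7.17646648e-02 2.87291133e-02
827.772397 1.32674494e-05 6.87545999e-02 2.23573797e-04 6.89914412e-02 2.84433682e-02
901.143268 1.00674158e-05 6.60429913e-02 2.23127424e-04 6.62761862e-02 2.81106064e-02
981.017479 7.63921217e-06 6.33889938e-02 2.22864732e-04 6.36194978e-02 2.77324536e-02
1067.971463 5.79667749e-06 6.07935215e-02 2.22713041e-04 6.10220312e-02 2.73108396e-02
1162.632746 4.39855174e-06 5.82574667e-02 2.22626931e-04 5.84844922e-02 2.68479818e-02
1265.684477 3.33764599e-06 5.57817097e-02 2.22578788e-04 5.60076261e-02 2.63463638e-02
1377.870355 2.53262469e-06 5.33671196e-02 2.22552232e-04 5.35922045e-02 2.58087104e-02
1500.000000 1.92176997e-06 5.10145472e-02 2.22537757e-04 5.12390068e-02 2.52379566e-02
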