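# element: N  Z: 7  A: 14.007
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 3.48316514e+00 1.92753751e-01 9.98189628e-02 3.77573785e+00 3.48678190e+00
10.886365 2.64304545e+00 1.92127579e-01 8.56836548e-02 2.92085668e+00 2.64695576e+00
11.851295 2.00555787e+00 1.91451974e-01 7.34115518e-02 2.27042139e+00 2.00978313e+00
12.901753 1.52182868e+00 1.90723579e-01 6.27864490e-02 1.77533871e+00 1.52639144e+00
14.045319 1.15477223e+00 1.89938901e-01 5.36118357e-02 1.39832296e+00 1.15969616e+00
15.290247 8.76247710e-01 1.89094327e-01 4.57098326e-02 1.11105187e+00 8.81557606e-01
16.645522 6.64901729e-01 1.88186136e-01 3.89201596e-02 8.92008025e-01 6.70623435e-01
18.120923 5.04531201e-01 1.87210517e-01 3.30991272e-02 7.24840845e-01 5.10691564e-01
19.727099 3.82841135e-01 1.86163598e-01 2.81186178e-02 5.97123351e-01 3.89467917e-01
21.475640 2.90502023e-01 1.85041470e-01 2.38650308e-02 4.99408524e-01 2.97623786e-01
23.379167 2.20434582e-01 1.83840225e-01 2.02381878e-02 4.24512995e-01 2.28080547e-01
25.451415 1.67267010e-01 1.82555995e-01 1.71502062e-02 3.66973211e-01 1.75466888e-01
27.707340 1.26923155e-01 1.81184997e-01 1.45243644e-02 3.22632517e-01 1.35706946e-01
30.163222 9.63100096e-02 1.79723589e-01 1.22939811e-02 2.88327580e-01 1.05707762e-01
32.836786 7.30805812e-02 1.78168324e-01 1.04013319e-02 2.61650237e-01 8.31221273e-02
35.747324 5.54539592e-02 1.76516015e-01 8.79662391e-03 2.40766598e-01 6.61686077e-02
38.915843 4.20787786e-02 1.74763807e-01 7.43703982e-03 2.24279625e-01 5.34949797e-02
42.365208 3.19296157e-02 1.72909242e-01 6.28586141e-03 2.11124719e-01 4.40745950e-02
46.120313 2.42283733e-02 1.70950342e-01 5.31167562e-03 2.00490390e-01 3.71277403e-02
50.208258 1.83846270e-02 1.68885678e-01 4.48766348e-03 1.91757968e-01 3.20619638e-02
54.658543 1.39503592e-02 1.66714451e-01 3.79096912e-03 1.84455779e-01 2.84267967e-02
59.503287 1.05856116e-02 1.64436558e-01 3.20214417e-03 1.78224314e-01 2.58794029e-02
64.777452 8.03242210e-03 1.62052660e-01 2.70466200e-03 1.72789744e-01 2.41585224e-02
70.519100 6.09504742e-03 1.59564239e-01 2.28449520e-03 1.67943781e-01 2.30647134e-02
76.769668 4.62495653e-03 1.56973636e-01 1.92975001e-03 1.63528343e-01 2.24453775e-02
83.574265 3.50944323e-03 1.54284087e-01 1.63035114e-03 1.59423881e-01 2.21834162e-02
90.981998 2.66298541e-03 1.51499726e-01 1.37777112e-03 1.55540483e-01 2.21886477e-02
99.046327 2.02068842e-03 1.48625581e-01 1.16479846e-03 1.51811067e-01 2.23913188e-02
107.825449 1.53330983e-03 1.45667534e-01 9.85339511e-04 1.48186183e-01 2.27372070e-02
117.382723 1.16348419e-03 1.42632272e-01 8.34249516e-04 1.44630006e-01 2.31839309e-02
127.787120 8.82858397e-04 1.39527203e-01 7.07188597e-04 1.41117250e-01 2.36981735e-02
139.113726 6.69917956e-04 1.36360356e-01 6.00499110e-04 1.37630773e-01 2.42535961e-02
151.444284 5.08337542e-04 1.33140256e-01 5.11100989e-04 1.34159694e-01 2.48292730e-02
164.867780 3.85729408e-04 1.29875792e-01 4.36402138e-04 1.30697924e-01 2.54085146e-02
179.481087 2.92693661e-04 1.26576067e-01 3.74221221e-04 1.27242982e-01 2.59779804e-02
195.389668 2.22097609e-04 1.23250238e-01 3.22720477e-04 1.23795056e-01 2.65270067e-02
212.708330 1.68528925e-04 1.19907368e-01 2.80346640e-04 1.20356244e-01 2.70470906e-02
231.562057 1.27880703e-04 1.16556276e-01 2.45778568e-04 1.16929936e-01 2.75314887e-02
252.086914 9.70366024e-05 1.13205401e-01 2.17880969e-04 1.13520319e-01 2.79748990e-02
274.431023 7.36319239e-05 1.09862687e-01 1.95664506e-04 1.10131983e-01 2.83732038e-02
298.755637 5.58723212e-05 1.06535488e-01 1.78253309e-04 1.06769613e-01 2.87232584e-02
325.236299 4.23962340e-05 1.03230500e-01 1.64861213e-04 1.03437758e-01 2.90227158e-02
354.064116 3.21705027e-05 9.99537219e-02 1.54777478e-04 1.00140670e-01 2.92698798e-02
385.447130 2.44111598e-05 9.67104380e-02 1.47361393e-04 9.68822105e-02 2.94635848e-02
419.611825 1.85233264e-05 9.35052322e-02 1.42043502e-04 9.36657990e-02 2.96030973e-02
456.804761 1.40556051e-05 9.03420216e-02 1.38329922e-04 9.04944071e-02 2.96880399e-02
497.294349 1.06654728e-05 8.72241091e-02 1.35805985e-04 8.73705806e-02 2.97183346e-02
541.372794 8.09302120e-06 8.41542503e-02 1.34136426e-04 8.42964798e-02 2.96941642e-02
589.358199 6.14103036e-06 8.11347289e-02 1.33060935e-04 8.12739309e-02 2.96159491e-02
641.596863 4.65984864e-06 7.81674359e-02 1.32385568e-04 7.83044813e-02 2.94843374e-02
698.465782 3.53591956e-06 7.52539481e-02 1.31971563e-04 7.53894556e-02 2.93002042e-02
760.375364 2.68307581e-06 7.23956021e-02 1.31723408e-04 7.25300086e-02 2.90646576e-02
827.772397 2.03593313e-06 6.95935595e-02 1.31577702e-04 6.97271732e-02 2.87790473e-02
901.143268 1.54487760e-06 6.68488632e-02 1.31493738e-04 6.69819018e-02 2.84449732e-02
981.017479 1.17226188e-06 6.41624810e-02 1.31446162e-04 6.42950995e-02 2.80642912e-02
1067.971463 8.89518957e-07 6.15353382e-02 1.31419607e-04 6.16676473e-02 2.76391149e-02
1162.632746 6.74972027e-07 5.89683378e-02 1.31404981e-04 5.91004178e-02 2.71718098e-02
1265.684477 5.12172599e-07 5.64623711e-02 1.31397018e-04 5.65942803e-02 2.66649821e-02
1377.870355 3.88639471e-07 5.40183176e-02 1.31392727e-04 5.41500989e-02 2.61214593e-02
1500.000000 2.94901834e-07 5.16370386e-02 1.31390435e-04 5.17687239e-02 2.55442657e-02
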