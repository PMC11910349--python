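# element: C  Z: 6  A: 12.011
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 2.02992257e+00 1.92673510e-01 7.79942927e-02 2.30059038e+00 2.03353783e+00
10.886365 1.54031676e+00 1.92047599e-01 6.68723241e-02 1.79923668e+00 1.54422544e+00
11.851295 1.16880108e+00 1.91372276e-01 5.72325785e-02 1.41740594e+00 1.17302459e+00
12.901753 8.86892888e-01 1.90644183e-01 4.89001332e-02 1.12643720e+00 8.91453749e-01
14.045319 6.72979350e-01 1.89859832e-01 4.17163863e-02 9.04555568e-01 6.77901236e-01
15.290247 5.10660545e-01 1.89015610e-01 3.55381602e-02 7.35214315e-01 5.15968231e-01
16.645522 3.87492116e-01 1.88107797e-01 3.02368330e-02 6.05836746e-01 3.93211440e-01
18.120923 2.94031214e-01 1.87132584e-01 2.56974715e-02 5.06861270e-01 3.00189013e-01
19.727099 2.23112552e-01 1.86086101e-01 2.18179422e-02 4.31016595e-01 2.29736575e-01
21.475640 1.69299069e-01 1.84964440e-01 1.85079857e-02 3.72771495e-01 1.76417867e-01
23.379167 1.28465093e-01 1.83763696e-01 1.56882608e-02 3.27917049e-01 1.36107875e-01
25.451415 9.74800407e-02 1.82480000e-01 1.32893727e-02 2.93249413e-01 1.05676506e-01
27.707340 7.39684074e-02 1.81109573e-01 1.12509049e-02 2.66328885e-01 8.27485415e-02
30.163222 5.61276468e-02 1.79648773e-01 9.52047727e-03 2.45296897e-01 6.55214874e-02
32.836786 4.25899765e-02 1.78094155e-01 8.05284526e-03 2.28736977e-01 5.26273426e-02
35.747324 3.23175156e-02 1.76442534e-01 6.80905670e-03 2.15569107e-01 4.30277038e-02
38.915843 2.45227140e-02 1.74691055e-01 5.75567325e-03 2.04969442e-01 3.59341627e-02
42.365208 1.86079744e-02 1.72837262e-01 4.86406210e-03 1.96309299e-01 3.07478979e-02
46.120313 1.41198364e-02 1.70879177e-01 4.10975885e-03 1.89108773e-01 2.70138336e-02
50.208258 1.07142119e-02 1.68815373e-01 3.47190016e-03 1.83001485e-01 2.43858550e-02
54.658543 8.13000473e-03 1.66645050e-01 2.93272279e-03 1.77707778e-01 2.26004159e-02
59.503287 6.16909367e-03 1.64368105e-01 2.47712439e-03 1.73014323e-01 2.14565184e-02
64.777452 4.68114324e-03 1.61985200e-01 2.09228074e-03 1.68758624e-01 2.08005305e-02
70.519100 3.55207802e-03 1.59497814e-01 1.76731397e-03 1.64817206e-01 2.05146798e-02
76.769668 2.69533694e-03 1.56908290e-01 1.49300605e-03 1.61096633e-01 2.05083395e-02
83.574265 2.04523695e-03 1.54219861e-01 1.26155248e-03 1.57526650e-01 2.07114362e-02
90.981998 1.55193739e-03 1.51436659e-01 1.06635101e-03 1.54054947e-01 2.10694715e-02
99.046327 1.17761889e-03 1.48563710e-01 9.01821036e-04 1.50643150e-01 2.15397692e-02
107.825449 8.93583885e-04 1.45606895e-01 7.63249339e-04 1.47263728e-01 2.20886542e-02
117.382723 6.78056517e-04 1.42572897e-01 6.46658712e-04 1.43897612e-01 2.26893365e-02
127.787120 5.14513128e-04 1.39469120e-01 5.48695984e-04 1.40532330e-01 2.33203305e-02
139.113726 3.90415478e-04 1.36303591e-01 4.66536582e-04 1.37160543e-01 2.39642761e-02
151.444284 2.96249477e-04 1.33084831e-01 3.97802954e-04 1.33778884e-01 2.46070605e-02
164.867780 2.24795783e-04 1.29821727e-01 3.40494474e-04 1.30387017e-01 2.52371644e-02
179.481087 1.70576314e-04 1.26523375e-01 2.92926712e-04 1.26986878e-01 2.58451707e-02
195.389668 1.29434274e-04 1.23198931e-01 2.53678240e-04 1.23582043e-01 2.64233930e-02
212.708330 9.82154607e-05 1.19857453e-01 2.21543595e-04 1.20177212e-01 2.69655880e-02
231.562057 7.45264482e-05 1.16507756e-01 1.95491588e-04 1.16777774e-01 2.74667268e-02
252.086914 5.65510913e-05 1.13158276e-01 1.74628881e-04 1.13389456e-01 2.79228084e-02
274.431023 4.29112886e-05 1.09816953e-01 1.58169513e-04 1.10018034e-01 2.83307024e-02
298.755637 3.25613290e-05 1.06491139e-01 1.45411472e-04 1.06669111e-01 2.86880136e-02
325.236299 2.47077210e-05 1.03187527e-01 1.35721228e-04 1.03347956e-01 2.89929632e-02
354.064116 1.87483588e-05 9.99121127e-02 1.28526262e-04 1.00059387e-01 2.92442864e-02
385.447130 1.42263609e-05 9.66701789e-02 1.23314192e-04 9.68077194e-02 2.94411449e-02
419.611825 1.07950433e-05 9.34663074e-02 1.19635819e-04 9.35967382e-02 2.95830534e-02
456.804761 8.19134003e-06 9.03044136e-02 1.17108833e-04 9.04297137e-02 2.96698228e-02
497.294349 6.21563524e-06 8.71877990e-02 1.15419344e-04 8.73094340e-02 2.97015179e-02
541.372794 4.71645925e-06 8.41192182e-02 1.14319664e-04 8.42382543e-02 2.96784297e-02
589.358199 3.57887601e-06 8.11009537e-02 1.13622222e-04 8.12181548e-02 2.96010608e-02
641.596863 2.71567140e-06 7.81348960e-02 1.13190676e-04 7.82508023e-02 2.94701212e-02
698.465782 2.06066685e-06 7.52226210e-02 1.12929758e-04 7.53376115e-02 2.92865332e-02
760.375364 1.56364569e-06 7.23654649e-02 1.12775338e-04 7.24798039e-02 2.90514401e-02
827.772397 1.18650321e-06 6.95645888e-02 1.12685713e-04 6.96784610e-02 2.87662185e-02
901.143268 9.00325361e-07 6.68210350e-02 1.12634601e-04 6.69345700e-02 2.84324880e-02
981.017479 6.83171987e-07 6.41357712e-02 1.12605909e-04 6.42490602e-02 2.80521199e-02
1067.971463 5.18394776e-07 6.15097219e-02 1.12590025e-04 6.16228304e-02 2.76272384e-02
1162.632746 3.93360894e-07 5.89437902e-02 1.12581339e-04 5.90567649e-02 2.71602173e-02
1265.684477 2.98484476e-07 5.64388666e-02 1.12576641e-04 5.65517418e-02 2.66536684e-02
1377.870355 2.26491712e-07 5.39958306e-02 1.12574123e-04 5.41086312e-02 2.61104234e-02
1500.000000 1.71863195e-07 5.16155428e-02 1.12572784e-04 5.17282875e-02 2.55335091e-02
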