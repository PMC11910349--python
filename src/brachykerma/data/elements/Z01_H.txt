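# element: H  Z: 1  A: 1.008
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 7.61934224e-03 3.82639142e-01 8.46045869e-03 3.98718943e-01 1.47990400e-02
10.886365 5.78160008e-03 3.81396117e-01 7.18297179e-03 3.94360689e-01 1.35440339e-02
11.851295 4.38711091e-03 3.80054961e-01 6.09309617e-03 3.90535168e-01 1.27747623e-02
12.901753 3.32896463e-03 3.78609009e-01 5.16468314e-03 3.87102656e-01 1.23865874e-02
14.045319 2.52603723e-03 3.77051330e-01 4.37486560e-03 3.83952233e-01 1.23006352e-02
15.290247 1.91677136e-03 3.75374751e-01 3.70373796e-03 3.80995260e-01 1.24575468e-02
16.645522 1.45445698e-03 3.73571883e-01 3.13404447e-03 3.78160384e-01 1.28127232e-02
18.120923 1.10365020e-03 3.71635164e-01 2.65088188e-03 3.75389696e-01 1.33327047e-02
19.727099 8.37456025e-04 3.69556905e-01 2.24142086e-03 3.72635782e-01 1.39924080e-02
21.475640 6.35466378e-04 3.67329348e-01 1.89464909e-03 3.69859463e-01 1.47730136e-02
23.379167 4.82195490e-04 3.64944733e-01 1.60113759e-03 3.67028066e-01 1.56603463e-02
25.451415 3.65892671e-04 3.62395383e-01 1.35283058e-03 3.64114106e-01 1.66436277e-02
27.707340 2.77641432e-04 3.59673789e-01 1.14285849e-03 3.61094289e-01 1.77145115e-02
30.163222 2.10675893e-04 3.56772720e-01 9.65372758e-04 3.57948768e-01 1.88663338e-02
32.836786 1.59862061e-04 3.53685333e-01 8.15401149e-04 3.54660596e-01 2.00935267e-02
35.747324 1.21304238e-04 3.50405304e-01 6.88721635e-04 3.51215330e-01 2.13911571e-02
38.915843 9.20463436e-05 3.46926961e-01 5.81753078e-04 3.47600761e-01 2.27545646e-02
42.365208 6.98452872e-05 3.43245430e-01 4.91460882e-04 3.43806736e-01 2.41790750e-02
46.120313 5.29989998e-05 3.39356779e-01 4.15275856e-04 3.39825054e-01 2.56597781e-02
50.208258 4.02159415e-05 3.35258176e-01 3.51024643e-04 3.35649417e-01 2.71913576e-02
54.658543 3.05160843e-05 3.30948032e-01 2.96870238e-04 3.31275418e-01 2.87679680e-02
59.503287 2.31557777e-05 3.26426143e-01 2.51261209e-04 3.26700560e-01 3.03831522e-02
64.777452 1.75707354e-05 3.21693823e-01 2.12888428e-04 3.21924282e-01 3.20297996e-02
70.519100 1.33327736e-05 3.16754010e-01 1.80648205e-04 3.16947990e-01 3.37001400e-02
76.769668 1.01169842e-05 3.11611355e-01 1.53610863e-04 3.11775083e-01 3.53857741e-02
83.574265 7.67682494e-06 3.06272279e-01 1.30993873e-04 3.06410950e-01 3.70777363e-02
90.981998 5.82521828e-06 3.00744992e-01 1.12138763e-04 3.00862956e-01 3.87665894e-02
99.046327 4.42020865e-06 2.95039471e-01 9.64911069e-05 2.95140382e-01 4.04425465e-02
107.825449 3.35407938e-06 2.89167396e-01 8.35829932e-05 2.89254334e-01 4.20956142e-02
117.382723 2.54509444e-06 2.83142041e-01 7.30175157e-05 2.83217603e-01 4.37157533e-02
127.787120 1.93123209e-06 2.76978109e-01 6.44550286e-05 2.77044496e-01 4.52930477e-02
139.113726 1.46542985e-06 2.70691539e-01 5.76011524e-05 2.70750606e-01 4.68178741e-02
151.444284 1.11197648e-06 2.64299257e-01 5.21967570e-05 2.64352566e-01 4.82810643e-02
164.867780 8.43774055e-07 2.57818909e-01 4.80102878e-05 2.57867763e-01 4.96740513e-02
179.481087 6.40260536e-07 2.51268561e-01 4.48327368e-05 2.51314034e-01 5.09889922e-02
195.389668 4.85833323e-07 2.44666395e-01 4.24752493e-05 2.44709356e-01 5.22188619e-02
212.708330 3.68653079e-07 2.38030401e-01 4.07688937e-05 2.38071539e-01 5.33575135e-02
231.562057 2.79736046e-07 2.31378084e-01 3.95656943e-05 2.31417930e-01 5.43997040e-02
252.086914 2.12265297e-07 2.24726198e-01 3.87398466e-05 2.24765150e-01 5.53410879e-02
274.431023 1.61068111e-07 2.18090512e-01 3.81881901e-05 2.18128862e-01 5.61781802e-02
298.755637 1.22219395e-07 2.11485626e-01 3.78294290e-05 2.11523578e-01 5.69082964e-02
325.236299 9.27407700e-08 2.04924832e-01 3.76020830e-05 2.04962527e-01 5.75294770e-02
354.064116 7.03722219e-08 1.98420037e-01 3.74615209e-05 1.98457569e-01 5.80404040e-02
385.447130 5.33988409e-08 1.91981733e-01 3.73765971e-05 1.92019163e-01 5.84403177e-02
419.611825 4.05193431e-08 1.85619018e-01 3.73263700e-05 1.85656384e-01 5.87289418e-02
456.804761 3.07463072e-08 1.79339668e-01 3.72972355e-05 1.79376996e-01 5.89064221e-02
497.294349 2.33304722e-08 1.73150240e-01 3.72806298e-05 1.73187544e-01 5.89732832e-02
541.372794 1.77032945e-08 1.67056205e-01 3.72713124e-05 1.67093494e-01 5.89304030e-02
589.358199 1.34333602e-08 1.61062096e-01 3.72661566e-05 1.61099375e-01 5.87790074e-02
641.596863 1.01933099e-08 1.55171666e-01 3.72633384e-05 1.55208939e-01 5.85206795e-02
698.465782 7.73474131e-09 1.49388046e-01 3.72618143e-05 1.49425315e-01 5.81573820e-02
760.375364 5.86916555e-09 1.43713889e-01 3.72609977e-05 1.43751156e-01 5.76914851e-02
827.772397 4.45355608e-09 1.38151501e-01 3.72605638e-05 1.38188766e-01 5.71257979e-02
901.143268 3.37938360e-09 1.32702952e-01 3.72603347e-05 1.32740215e-01 5.64635947e-02
981.017479 2.56429543e-09 1.27370163e-01 3.72602146e-05 1.27407426e-01 5.57086346e-02
1067.971463 1.94580191e-09 1.22154972e-01 3.72601519e-05 1.22192234e-01 5.48651696e-02
1162.632746 1.47648552e-09 1.17059171e-01 3.72601193e-05 1.17096432e-01 5.39379388e-02
1265.684477 1.12036558e-09 1.12084528e-01 3.72601024e-05 1.12121790e-01 5.29321482e-02
1377.870355 8.50139751e-10 1.07232791e-01 3.72600937e-05 1.07270052e-01 5.18534359e-02
1500.000000 6.45090861e-10 1.02505669e-01 3.72600892e-05 1.02542930e-01 5.07078237e-02
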