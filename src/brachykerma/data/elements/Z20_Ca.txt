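# element: Ca  Z: 20  A: 40.078
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 1.37121941e+02 1.92474802e-01 5.22589811e-01 1.37837006e+02 1.37125553e+02
10.886365 1.04048906e+02 1.91849537e-01 4.52574783e-01 1.04693331e+02 1.04052811e+02
11.851295 7.89528998e+01 1.91174909e-01 3.91038272e-01 7.95351130e+01 7.89571190e+01
12.901753 5.99099079e+01 1.90447568e-01 3.37126428e-01 6.04374819e+01 5.99144640e+01
14.045319 4.54599777e+01 1.89664026e-01 2.90035900e-01 4.59396776e+01 4.54648945e+01
15.290247 3.44952887e+01 1.88820674e-01 2.49022567e-01 3.49331320e+01 3.45005909e+01
16.645522 2.61752206e+01 1.87913797e-01 2.13403261e-01 2.65765377e+01 2.61809340e+01
18.120923 1.98619058e+01 1.86939590e-01 1.82554171e-01 2.02313995e+01 1.98680572e+01
19.727099 1.50713267e+01 1.85894186e-01 1.55908040e-01 1.54131289e+01 1.50779439e+01
21.475640 1.14362081e+01 1.84773683e-01 1.32951129e-01 1.17539329e+01 1.14433196e+01
23.379167 8.67785952e+00 1.83574176e-01 1.13220258e-01 8.97465396e+00 8.68549442e+00
25.451415 6.58480899e+00 1.82291804e-01 9.62999261e-02 6.86340072e+00 6.59299700e+00
27.707340 4.99659039e+00 1.80922790e-01 8.18194155e-02 5.25933259e+00 5.00536146e+00
30.163222 3.79144111e+00 1.79463497e-01 6.94497941e-02 4.04035440e+00 3.80082526e+00
32.836786 2.87696700e+00 1.77910482e-01 5.89008048e-02 3.11377829e+00 2.88699401e+00
35.747324 2.18305887e+00 1.76260565e-01 4.99176618e-02 2.40923709e+00 2.19375801e+00
38.915843 1.65651744e+00 1.74510892e-01 4.22778105e-02 1.87330614e+00 1.66791712e+00
42.365208 1.25697482e+00 1.72659012e-01 3.57877218e-02 1.46542156e+00 1.26910223e+00
46.120313 9.53799621e-01 1.70702946e-01 3.02797866e-02 1.15478235e+00 9.66680320e-01
50.208258 7.23748558e-01 1.68641270e-01 2.56093665e-02 9.17999195e-01 7.37406102e-01
54.658543 5.49184508e-01 1.66473185e-01 2.16520416e-02 7.37309735e-01 5.63639996e-01
59.503287 4.16724318e-01 1.64198589e-01 1.83010819e-02 5.99223988e-01 4.31995976e-01
64.777452 3.16212774e-01 1.61818141e-01 1.54651535e-02 4.93496069e-01 3.32315537e-01
70.519100 2.39944045e-01 1.59333321e-01 1.30662616e-02 4.12343628e-01 2.56889153e-01
76.769668 1.82070902e-01 1.56746467e-01 1.10379235e-02 3.49855292e-01 1.99865533e-01
83.574265 1.38156432e-01 1.54060810e-01 9.32355831e-03 3.01540801e-01 1.56803381e-01
90.981998 1.04833884e-01 1.51280479e-01 7.87507792e-03 2.63989441e-01 1.24331289e-01
99.046327 7.95485452e-02 1.48410493e-01 6.65166091e-03 2.34610699e-01 9.98896956e-02
107.825449 6.03618870e-02 1.45456727e-01 5.61869085e-03 2.11437305e-01 8.15350983e-02
117.382723 4.58029420e-02 1.42425858e-01 4.74684082e-03 1.92975641e-01 6.77915212e-02
127.787120 3.47555320e-02 1.39325283e-01 4.01128672e-03 1.78092101e-01 5.75378292e-02
139.113726 2.63726947e-02 1.36163018e-01 3.39103327e-03 1.65926746e-01 4.99222430e-02
151.444284 2.00117502e-02 1.32947578e-01 2.86833794e-03 1.55827666e-01 4.42974890e-02
164.867780 1.51850295e-02 1.29687839e-01 2.42821944e-03 1.47301088e-01 4.01716022e-02
179.481087 1.15224864e-02 1.26392889e-01 2.05803895e-03 1.39973414e-01 3.71706020e-02
195.389668 8.74332801e-03 1.23071873e-01 1.74714332e-03 1.33562344e-01 3.50101692e-02
212.708330 6.63448685e-03 1.19733841e-01 1.48656080e-03 1.27854889e-01 3.34741505e-02
231.562057 5.03428623e-03 1.16387599e-01 1.26874063e-03 1.22690626e-01 3.23982364e-02
252.086914 3.82004492e-03 1.13041573e-01 1.08732885e-03 1.17948947e-01 3.16575631e-02
274.431023 2.89867174e-03 1.09703696e-01 9.36973504e-04 1.13539341e-01 3.11572891e-02
298.755637 2.19952855e-03 1.06381312e-01 8.13153556e-04 1.09393994e-01 3.08254278e-02
325.236299 1.66901473e-03 1.03081107e-01 7.12027288e-04 1.05462149e-01 3.06073946e-02
354.064116 1.26645784e-03 9.98090711e-02 6.30298207e-04 1.01705827e-01 3.04618550e-02
385.447130 9.60995384e-04 9.65704808e-02 5.65098899e-04 9.80965751e-02 3.03575653e-02
419.611825 7.29208744e-04 9.33699135e-02 5.13895596e-04 9.46130178e-02 3.02709685e-02
456.804761 5.53327728e-04 9.02112806e-02 4.74417215e-04 9.12390255e-02 3.01843685e-02
497.294349 4.19868216e-04 8.70978803e-02 4.44611345e-04 8.79623599e-02 3.00845451e-02
541.372794 3.18598382e-04 8.40324641e-02 4.22626055e-04 8.47736886e-02 2.99617085e-02
589.358199 2.41754258e-04 8.10173125e-02 4.06811601e-04 8.16658784e-02 2.98087116e-02
641.596863 1.83444501e-04 7.80543137e-02 3.95732255e-04 7.86334905e-02 2.96204597e-02
698.465782 1.39198727e-04 7.51450423e-02 3.88177454e-04 7.56724185e-02 2.93934695e-02
760.375364 1.05624783e-04 7.22908328e-02 3.83163787e-04 7.27796213e-02 2.91255415e-02
827.772397 8.01486843e-05 6.94928453e-02 3.79923908e-04 6.99529179e-02 2.88155146e-02
901.143268 6.08172759e-05 6.67521210e-02 3.77883265e-04 6.71908216e-02 2.84630829e-02
981.017479 4.61484937e-05 6.40696265e-02 3.76628800e-04 6.44924038e-02 2.80686551e-02
1067.971463 3.50177386e-05 6.14462856e-02 3.75874907e-04 6.18571782e-02 2.76332457e-02
1162.632746 2.65716585e-05 5.88830002e-02 3.75431193e-04 5.92850030e-02 2.71583850e-02
1265.684477 2.01627251e-05 5.63806600e-02 3.75174949e-04 5.67759977e-02 2.66460444e-02
1377.870355 1.52995901e-05 5.39401435e-02 3.75029476e-04 5.43304725e-02 2.60985685e-02
1500.000000 1.16094157e-05 5.15623106e-02 3.74948137e-04 5.19488681e-02 2.55186136e-02
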