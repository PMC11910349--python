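# element: Na  Z: 11  A: 22.99
# columns: energy_keV mu_pe mu_incoh mu_coh mu_total mu_en   (all cm^2/g)
# provenance: generated by scripts/build_xs_tables.py -- analytic Klein-Nishina incoherent,
#   Wentzel screened-form-factor coherent, fitted power-law photoelectric; approximate
#   reconstruction of public attenuation/energy-absorption tabulations.
10.000000 1.62220646e+01 1.84545577e-01 1.95926848e-01 1.66025370e+01 1.62255273e+01
10.886365 1.23093945e+01 1.83946070e-01 1.68789712e-01 1.26621303e+01 1.23131383e+01
11.851295 9.34043834e+00 1.83299235e-01 1.45110137e-01 9.66884771e+00 9.34448368e+00
12.901753 7.08757756e+00 1.82601857e-01 1.24506871e-01 7.39468628e+00 7.09194602e+00
14.045319 5.37809402e+00 1.81850594e-01 1.06630642e-01 5.66657526e+00 5.38280828e+00
15.290247 4.08092823e+00 1.81041985e-01 9.11630032e-02 4.35313322e+00 4.08601201e+00
16.645522 3.09663147e+00 1.80172468e-01 7.78147736e-02 3.35461871e+00 3.10210952e+00
18.120923 2.34974151e+00 1.79238395e-01 6.63244493e-02 2.59530435e+00 2.35563954e+00
19.727099 1.78299718e+00 1.78236058e-01 5.64566597e-02 2.01768989e+00 1.78934177e+00
21.475640 1.35294836e+00 1.77161714e-01 4.80006520e-02 1.57811073e+00 1.35976686e+00
23.379167 1.02662489e+00 1.76011623e-01 4.07687479e-02 1.24340526e+00 1.03394526e+00
25.451415 7.79008783e-01 1.74782079e-01 3.45947434e-02 9.88385606e-01 7.86859480e-01
27.707340 5.91116280e-01 1.73469464e-01 2.93322483e-02 7.93917992e-01 5.99526024e-01
30.163222 4.48542384e-01 1.72070288e-01 2.48529859e-02 6.45465657e-01 4.57539945e-01
32.836786 3.40356503e-01 1.70581252e-01 2.10450869e-02 5.31982841e-01 3.49970443e-01
35.747324 2.58264444e-01 1.68999305e-01 1.78114133e-02 4.45075162e-01 2.68522822e-01
38.915843 1.95972524e-01 1.67321712e-01 1.50679463e-02 3.78362181e-01 2.06902580e-01
42.365208 1.48705062e-01 1.65546121e-01 1.27422648e-02 3.26993448e-01 1.60332862e-01
46.120313 1.12838244e-01 1.63670638e-01 1.07721342e-02 2.87281016e-01 1.25188307e-01
50.208258 8.56222989e-02 1.61693895e-01 9.10421498e-03 2.56420409e-01 9.87172036e-02
54.658543 6.49706857e-02 1.59615127e-01 7.69289696e-03 2.32278710e-01 7.88306625e-02
59.503287 4.93001246e-02 1.57434235e-01 6.49925682e-03 2.13233617e-01 6.39426491e-02
64.777452 3.74092139e-02 1.55151853e-01 5.49013528e-03 1.98051202e-01 5.28486047e-02
70.519100 2.83863236e-02 1.52769398e-01 4.63732572e-03 1.85793047e-01 4.46333579e-02
76.769668 2.15397032e-02 1.50289113e-01 3.91686565e-03 1.75745682e-01 3.86012642e-02
83.574265 1.63444489e-02 1.47714095e-01 3.30842129e-03 1.67366965e-01 3.42232144e-02
90.981998 1.24022605e-02 1.45048302e-01 2.79475548e-03 1.60245318e-01 3.10964472e-02
99.046327 9.41090553e-03 1.42296549e-01 2.36126947e-03 1.54068724e-01 2.89140784e-02
107.825449 7.14104846e-03 1.39464467e-01 1.99560953e-03 1.48601125e-01 2.74420045e-02
117.382723 5.41866805e-03 1.36558458e-01 1.68733033e-03 1.43664456e-01 2.65014020e-02
127.787120 4.11171603e-03 1.33585614e-01 1.42760728e-03 1.39124938e-01 2.59554698e-02
139.113726 3.11999343e-03 1.30553623e-01 1.20899139e-03 1.34882607e-01 2.56993905e-02
151.444284 2.36746870e-03 1.27470647e-01 1.02520030e-03 1.30863316e-01 2.56527280e-02
164.867780 1.79644867e-03 1.24345196e-01 8.70940291e-04 1.27012585e-01 2.57536703e-02
179.481087 1.36315543e-03 1.21185986e-01 7.41754322e-04 1.23290895e-01 2.59546668e-02
195.389668 1.03437007e-03 1.18001783e-01 6.33891773e-04 1.19670045e-01 2.62191180e-02
212.708330 7.84885869e-04 1.14801265e-01 5.44195963e-04 1.16130347e-01 2.65188581e-02
231.562057 5.95575846e-04 1.11592875e-01 4.70006068e-04 1.12658457e-01 2.68322360e-02
252.086914 4.51926328e-04 1.08384693e-01 4.09070652e-04 1.09245690e-01 2.71426453e-02
274.431023 3.42924259e-04 1.05184324e-01 3.59470989e-04 1.05886719e-01 2.74373947e-02
298.755637 2.60212871e-04 1.01998809e-01 3.19553519e-04 1.02578575e-01 2.77068347e-02
325.236299 1.97451002e-04 9.88345602e-02 2.87872184e-04 9.93198834e-02 2.79436804e-02
354.064116 1.49826939e-04 9.56973194e-02 2.63142348e-04 9.61102887e-02 2.81424855e-02
385.447130 1.13689531e-04 9.25921466e-02 2.44208229e-04 9.29500444e-02 2.82992333e-02
419.611825 8.62682603e-05 8.95234305e-02 2.30024600e-04 8.98397233e-02 2.84110206e-02
456.804761 6.54608449e-05 8.64949211e-02 2.19651309e-04 8.67800333e-02 2.84758161e-02
497.294349 4.96720601e-05 8.35097810e-02 2.12256679e-04 8.37717098e-02 2.84922778e-02
541.372794 3.76914408e-05 8.05706483e-02 2.07124242e-04 8.08154640e-02 2.84596189e-02
589.358199 2.86004789e-05 7.76797094e-02 2.03657337e-04 7.79119672e-02 2.83775124e-02
641.596863 2.17022055e-05 7.48387747e-02 2.01377871e-04 7.50618548e-02 2.82460250e-02
698.465782 1.64677565e-05 7.20493542e-02 1.99918079e-04 7.22657400e-02 2.80655746e-02
760.375364 1.24958270e-05 6.93127272e-02 1.99006486e-04 6.95242295e-02 2.78369031e-02
827.772397 9.48190435e-06 6.66300060e-02 1.98450584e-04 6.68379385e-02 2.75610608e-02
901.143268 7.19492276e-06 6.40021891e-02 1.98118980e-04 6.42075030e-02 2.72393959e-02
981.017479 5.45954817e-06 6.14302031e-02 1.97925131e-04 6.16335878e-02 2.68735462e-02
1067.971463 4.14273610e-06 5.89149338e-02 1.97813868e-04 5.91168904e-02 2.64654293e-02
1162.632746 3.14353163e-06 5.64572459e-02 1.97751047e-04 5.66581405e-02 2.60172301e-02
1265.684477 2.38532962e-06 5.40579926e-02 1.97716094e-04 5.42580940e-02 2.55313826e-02
1377.870355 1.81000164e-06 5.17180160e-02 1.97696894e-04 5.19175229e-02 2.50105480e-02
1500.000000 1.37343950e-06 4.94381408e-02 1.97686468e-04 4.96372007e-02 2.44575867e-02
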