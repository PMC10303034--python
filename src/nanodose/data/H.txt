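# element: H
# Z: 1
# A_g_per_mol: 1.008
# columns: energy_keV pe incoherent coherent muen  (cm^2/g)
1.000000e+00 6.700169e+00 1.447546e-01 3.720759e-01 6.700941e+00
1.061879e+00 5.505888e+00 1.564784e-01 3.690707e-01 5.506706e+00
1.127587e+00 4.506382e+00 1.685081e-01 3.657398e-01 4.507251e+00
1.197360e+00 3.669776e+00 1.807562e-01 3.620553e-01 3.670698e+00
1.271452e+00 2.969453e+00 1.931284e-01 3.579887e-01 2.970431e+00
1.350128e+00 2.383195e+00 2.055264e-01 3.535115e-01 2.384233e+00
1.433672e+00 1.892455e+00 2.178507e-01 3.485955e-01 1.893557e+00
1.500000e+00 1.576388e+00 2.270262e-01 3.445863e-01 1.577540e+00
1.522386e+00 1.497967e+00 2.300036e-01 3.432138e-01 1.499137e+00
1.616589e+00 1.207741e+00 2.418928e-01 3.373413e-01 1.208982e+00
1.716622e+00 9.573752e-01 2.534333e-01 3.309561e-01 9.586917e-01
1.822844e+00 7.416120e-01 2.645501e-01 3.240401e-01 7.430088e-01
1.935640e+00 5.559105e-01 2.751798e-01 3.165805e-01 5.573924e-01
2.000000e+00 4.659680e-01 2.807469e-01 3.122852e-01 4.674983e-01
2.055415e+00 4.207867e-01 2.852709e-01 3.085707e-01 4.223587e-01
2.182602e+00 3.287752e-01 2.947851e-01 3.000116e-01 3.304427e-01
2.317659e+00 2.460781e-01 3.036963e-01 2.909128e-01 2.478469e-01
2.461073e+00 1.719574e-01 3.119903e-01 2.812932e-01 1.738335e-01
2.613361e+00 1.057202e-01 3.196632e-01 2.711820e-01 1.077099e-01
2.775072e+00 4.671353e-02 3.267210e-01 2.606187e-01 4.882360e-02
2.946791e+00 0.000000e+00 3.274977e-01 2.496532e-01 2.237522e-03
3.000000e+00 0.000000e+00 3.148843e-01 2.463157e-01 2.276944e-03
3.129135e+00 0.000000e+00 3.058000e-01 2.383454e-01 2.372477e-03
3.322762e+00 0.000000e+00 2.939764e-01 2.267639e-01 2.515347e-03
3.528370e+00 0.000000e+00 2.833572e-01 2.149848e-01 2.666567e-03
3.746702e+00 0.000000e+00 2.738176e-01 2.030894e-01 2.826594e-03
3.978543e+00 0.000000e+00 2.652314e-01 1.911626e-01 2.995905e-03
4.000000e+00 0.000000e+00 2.645045e-01 1.900955e-01 3.011542e-03
4.224731e+00 0.000000e+00 2.663972e-01 1.792901e-01 3.174999e-03
4.486152e+00 0.000000e+00 2.685428e-01 1.675560e-01 3.364397e-03
4.763750e+00 0.000000e+00 2.706760e-01 1.560406e-01 3.564641e-03
5.000000e+00 0.000000e+00 2.723330e-01 1.469670e-01 3.734355e-03
5.058525e+00 0.000000e+00 2.735016e-01 1.448180e-01 3.776298e-03
5.371541e+00 0.000000e+00 2.793429e-01 1.339546e-01 3.999955e-03
5.703926e+00 0.000000e+00 2.848280e-01 1.235078e-01 4.236222e-03
6.000000e+00 0.000000e+00 2.891389e-01 1.150611e-01 4.445619e-03
6.056878e+00 0.000000e+00 2.902490e-01 1.135246e-01 4.485732e-03
6.431670e+00 0.000000e+00 2.970290e-01 1.040420e-01 4.749140e-03
6.829655e+00 0.000000e+00 3.033003e-01 9.508608e-02 5.027121e-03
7.252266e+00 0.000000e+00 3.090465e-01 8.667338e-02 5.320374e-03
7.701027e+00 0.000000e+00 3.142601e-01 7.881099e-02 5.629615e-03
8.000000e+00 0.000000e+00 3.172917e-01 7.410833e-02 5.834413e-03
8.177558e+00 0.000000e+00 3.193079e-01 7.149772e-02 5.955580e-03
8.683575e+00 0.000000e+00 3.244593e-01 6.472523e-02 6.299022e-03
9.220905e+00 0.000000e+00 3.290911e-01 5.847916e-02 6.660709e-03
9.791484e+00 0.000000e+00 3.332223e-01 5.274030e-02 7.041422e-03
1.000000e+01 0.000000e+00 3.345578e-01 5.084221e-02 7.179697e-03
1.039737e+01 0.000000e+00 3.370401e-01 4.748572e-02 7.441953e-03
1.104075e+01 0.000000e+00 3.404929e-01 4.268983e-02 7.863101e-03
1.172393e+01 0.000000e+00 3.435190e-01 3.832526e-02 8.305670e-03
1.244940e+01 0.000000e+00 3.461469e-01 3.436369e-02 8.770464e-03
1.321975e+01 0.000000e+00 3.484050e-01 3.077653e-02 9.258280e-03
1.403777e+01 0.000000e+00 3.503217e-01 2.753542e-02 9.769909e-03
1.490642e+01 0.000000e+00 3.519246e-01 2.461273e-02 1.030612e-02
1.500000e+01 0.000000e+00 3.520747e-01 2.432531e-02 1.036346e-02
1.582881e+01 0.000000e+00 3.531185e-01 2.198183e-02 1.086768e-02
1.680828e+01 0.000000e+00 3.540374e-01 1.961735e-02 1.145529e-02
1.784835e+01 0.000000e+00 3.547194e-01 1.749535e-02 1.206966e-02
1.895279e+01 0.000000e+00 3.551868e-01 1.559342e-02 1.271142e-02
2.000000e+01 0.000000e+00 3.554405e-01 1.405946e-02 1.331003e-02
2.012556e+01 0.000000e+00 3.554131e-01 1.389069e-02 1.338117e-02
2.137091e+01 0.000000e+00 3.550587e-01 1.236786e-02 1.407942e-02
2.269332e+01 0.000000e+00 3.545517e-01 1.100719e-02 1.480664e-02
2.409755e+01 0.000000e+00 3.539083e-01 9.792415e-03 1.556320e-02
2.558868e+01 0.000000e+00 3.531433e-01 8.708680e-03 1.634938e-02
2.717208e+01 0.000000e+00 3.522702e-01 7.742488e-03 1.716533e-02
2.885345e+01 0.000000e+00 3.513011e-01 6.881592e-03 1.801113e-02
3.000000e+01 0.000000e+00 3.506261e-01 6.373914e-03 1.857601e-02
3.063887e+01 0.000000e+00 3.500525e-01 6.114919e-03 1.888668e-02
3.253477e+01 0.000000e+00 3.483735e-01 5.432472e-03 1.979177e-02
3.454798e+01 0.000000e+00 3.466348e-01 4.825250e-03 2.072603e-02
3.668577e+01 0.000000e+00 3.448446e-01 4.285159e-03 2.168891e-02
3.895584e+01 0.000000e+00 3.430100e-01 3.804934e-03 2.267970e-02
4.000000e+01 0.000000e+00 3.421893e-01 3.610660e-03 2.312483e-02
4.136638e+01 0.000000e+00 3.408515e-01 3.378064e-03 2.369751e-02
4.392609e+01 0.000000e+00 3.384415e-01 2.998720e-03 2.474123e-02
4.664418e+01 0.000000e+00 3.360118e-01 2.661686e-03 2.580957e-02
4.953047e+01 0.000000e+00 3.335669e-01 2.362306e-03 2.690103e-02
5.000000e+01 0.000000e+00 3.331816e-01 2.318405e-03 2.707454e-02
5.259536e+01 0.000000e+00 3.307394e-01 2.096421e-03 2.801388e-02
5.584989e+01 0.000000e+00 3.278419e-01 1.860321e-03 2.914622e-02
5.930582e+01 0.000000e+00 3.249475e-01 1.650699e-03 3.029588e-02
6.000000e+01 0.000000e+00 3.243871e-01 1.612878e-03 3.052053e-02
6.297560e+01 0.000000e+00 3.216286e-01 1.464611e-03 3.146054e-02
6.687245e+01 0.000000e+00 3.182242e-01 1.299431e-03 3.263765e-02
7.101044e+01 0.000000e+00 3.148406e-01 1.152827e-03 3.382446e-02
7.540448e+01 0.000000e+00 3.114796e-01 1.022720e-03 3.501808e-02
8.000000e+01 0.000000e+00 3.081911e-01 9.088576e-04 3.619787e-02
8.007042e+01 0.000000e+00 3.081334e-01 9.072633e-04 3.621542e-02
8.502509e+01 0.000000e+00 3.042106e-01 8.048141e-04 3.741330e-02
9.028634e+01 0.000000e+00 3.003288e-01 7.139129e-04 3.860836e-02
9.587315e+01 0.000000e+00 2.964885e-01 6.332622e-04 3.979721e-02
1.000000e+02 0.000000e+00 2.938179e-01 5.821481e-04 4.062611e-02
1.018057e+02 0.000000e+00 2.924793e-01 5.617097e-04 4.097635e-02
1.081053e+02 0.000000e+00 2.880290e-01 4.982318e-04 4.214227e-02
1.147947e+02 0.000000e+00 2.836410e-01 4.419195e-04 4.329145e-02
1.218981e+02 0.000000e+00 2.793151e-01 3.919655e-04 4.442040e-02
1.294410e+02 0.000000e+00 2.750510e-01 3.476534e-04 4.552568e-02
1.374506e+02 0.000000e+00 2.708483e-01 3.083468e-04 4.660395e-02
1.459559e+02 0.000000e+00 2.667064e-01 2.734813e-04 4.765197e-02
1.500000e+02 0.000000e+00 2.648411e-01 2.589432e-04 4.811818e-02
1.549875e+02 0.000000e+00 2.622344e-01 2.425558e-04 4.866666e-02
1.645780e+02 0.000000e+00 2.575144e-01 2.151254e-04 4.964511e-02
1.747618e+02 0.000000e+00 2.528772e-01 1.907956e-04 5.058457e-02
1.855759e+02 0.000000e+00 2.483216e-01 1.692162e-04 5.148253e-02
1.970591e+02 0.000000e+00 2.438463e-01 1.500766e-04 5.233667e-02
2.000000e+02 0.000000e+00 2.427543e-01 1.456971e-04 5.254042e-02
2.092529e+02 0.000000e+00 2.390074e-01 1.331011e-04 5.314489e-02
2.222012e+02 0.000000e+00 2.341214e-01 1.180452e-04 5.390534e-02
2.359508e+02 0.000000e+00 2.293341e-01 1.046918e-04 5.461638e-02
2.505511e+02 0.000000e+00 2.246436e-01 9.284871e-05 5.527658e-02
2.660549e+02 0.000000e+00 2.200482e-01 8.234504e-05 5.588475e-02
2.825181e+02 0.000000e+00 2.155460e-01 7.302939e-05 5.643987e-02
3.000000e+02 0.000000e+00 2.111352e-01 6.476745e-05 5.694113e-02
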