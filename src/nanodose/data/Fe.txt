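# element: Fe
# Z: 26
# A_g_per_mol: 55.845
# edges_keV: 7.112
# columns: energy_keV pe incoherent coherent muen  (cm^2/g)
1.000000e+00 9.080223e+03 2.124930e-04 4.777197e+00 9.052000e+03
1.061879e+00 7.849400e+03 2.409521e-04 4.768129e+00 7.826100e+03
1.127587e+00 6.785331e+03 2.732131e-04 4.757945e+00 6.766221e+03
1.197360e+00 5.865424e+03 3.097814e-04 4.746514e+00 5.849881e+03
1.271452e+00 5.070148e+03 3.512290e-04 4.733690e+00 5.057639e+03
1.350128e+00 4.382620e+03 3.982032e-04 4.719313e+00 4.372690e+03
1.433672e+00 3.788241e+03 4.514360e-04 4.703206e+00 3.780502e+03
1.500000e+00 3.394310e+03 4.961652e-04 4.689814e+00 3.388000e+03
1.522386e+00 3.267678e+03 5.117551e-04 4.685175e+00 3.258453e+03
1.616589e+00 2.800954e+03 5.800961e-04 4.665009e+00 2.782186e+03
1.716622e+00 2.400805e+03 6.575162e-04 4.642477e+00 2.375532e+03
1.822844e+00 2.057736e+03 7.452093e-04 4.617330e+00 2.028316e+03
1.935640e+00 1.763606e+03 8.445229e-04 4.589300e+00 1.731850e+03
2.000000e+00 1.621426e+03 9.040531e-04 4.572714e+00 1.589000e+03
2.055415e+00 1.508273e+03 9.569773e-04 4.558098e+00 1.477597e+03
2.182602e+00 1.286591e+03 1.084286e-03 4.523421e+00 1.259527e+03
2.317659e+00 1.097407e+03 1.228381e-03 4.484947e+00 1.073641e+03
2.461073e+00 9.359589e+02 1.391434e-03 4.442342e+00 9.151892e+02
2.613361e+00 7.981830e+02 1.575890e-03 4.395261e+00 7.801220e+02
2.775072e+00 6.806108e+02 1.784494e-03 4.343357e+00 6.649886e+02
2.946791e+00 5.802824e+02 2.020328e-03 4.286282e+00 5.668470e+02
3.000000e+00 5.533297e+02 2.096390e-03 4.268219e+00 5.405000e+02
3.129135e+00 4.934753e+02 2.286842e-03 4.223697e+00 4.817744e+02
3.322762e+00 4.191514e+02 2.587899e-03 4.155285e+00 4.089600e+02
3.528370e+00 3.559530e+02 2.927812e-03 4.080754e+00 3.471506e+02
3.746702e+00 3.022183e+02 3.311389e-03 3.999858e+00 2.946829e+02
3.978543e+00 2.565340e+02 3.743975e-03 3.912404e+00 2.501451e+02
4.000000e+00 2.527920e+02 3.785316e-03 3.904244e+00 2.465000e+02
4.224731e+00 2.173730e+02 4.231501e-03 3.818268e+00 2.119611e+02
4.486152e+00 1.841080e+02 4.780526e-03 3.717413e+00 1.795743e+02
4.763750e+00 1.558824e+02 5.398279e-03 3.609896e+00 1.521361e+02
5.000000e+00 1.362756e+02 5.951717e-03 3.518479e+00 1.331000e+02
5.058525e+00 1.319117e+02 6.092699e-03 3.495885e+00 1.288396e+02
5.371541e+00 1.114946e+02 6.872465e-03 3.375670e+00 1.089316e+02
5.703926e+00 9.419774e+01 7.747014e-03 3.249664e+00 9.209978e+01
6.000000e+00 8.169208e+01 8.565230e-03 3.139358e+00 7.995000e+01
6.056878e+00 7.954295e+01 8.726550e-03 3.118410e+00 7.761826e+01
6.431670e+00 6.711188e+01 9.822032e-03 2.982573e+00 6.429296e+01
6.829655e+00 5.659448e+01 1.104513e-02 2.842936e+00 5.325532e+01
7.111993e+00 5.043103e+01 1.194862e-02 2.747018e+00 4.690000e+01
7.112007e+00 4.048410e+02 1.194867e-02 2.747013e+00 3.050000e+02
7.252266e+00 3.858601e+02 1.240816e-02 2.700381e+00 2.937096e+02
7.701027e+00 3.328930e+02 1.392397e-02 2.555868e+00 2.615503e+02
8.000000e+00 3.031214e+02 1.497077e-02 2.463640e+00 2.430000e+02
8.177558e+00 2.861412e+02 1.560578e-02 2.410415e+00 2.296628e+02
8.683575e+00 2.443935e+02 1.746697e-02 2.265066e+00 1.968064e+02
9.220905e+00 2.087258e+02 1.952082e-02 2.120859e+00 1.686506e+02
9.791484e+00 1.782543e+02 2.178012e-02 1.978804e+00 1.445228e+02
1.000000e+01 1.686477e+02 2.262403e-02 1.929636e+00 1.369000e+02
1.039737e+01 1.516969e+02 2.425682e-02 1.839849e+00 1.240184e+02
1.104075e+01 1.288466e+02 2.696146e-02 1.704856e+00 1.065027e+02
1.172393e+01 1.094310e+02 2.990266e-02 1.574585e+00 9.146090e+01
1.244940e+01 9.293467e+01 3.308650e-02 1.449680e+00 7.854348e+01
1.321975e+01 7.891934e+01 3.651585e-02 1.330658e+00 6.745045e+01
1.403777e+01 6.701239e+01 4.018970e-02 1.217907e+00 5.792414e+01
1.490642e+01 5.689704e+01 4.410258e-02 1.111691e+00 4.974326e+01
1.500000e+01 5.593447e+01 4.452384e-02 1.101002e+00 4.896000e+01
1.582881e+01 4.810212e+01 4.824394e-02 1.012157e+00 4.237182e+01
1.680828e+01 4.064189e+01 5.259779e-02 9.193420e-01 3.605861e+01
1.784835e+01 3.433388e+01 5.714239e-02 8.331907e-01 3.068604e+01
1.895279e+01 2.900028e+01 6.185032e-02 7.535645e-01 2.611396e+01
2.000000e+01 2.492621e+01 6.617929e-02 6.876126e-01 2.260000e+01
2.012556e+01 2.448337e+01 6.668864e-02 6.802592e-01 2.220689e+01
2.137091e+01 2.061248e+01 7.161952e-02 6.130176e-01 1.876640e+01
2.269332e+01 1.734892e+01 7.660101e-02 5.515434e-01 1.585894e+01
2.409755e+01 1.459748e+01 8.158815e-02 4.955128e-01 1.340193e+01
2.558868e+01 1.227787e+01 8.653424e-02 4.445855e-01 1.132558e+01
2.717208e+01 1.032236e+01 9.139227e-02 3.984135e-01 9.570914e+00
2.885345e+01 8.673874e+00 9.611637e-02 3.566483e-01 8.088101e+00
3.000000e+01 7.745172e+00 9.909017e-02 3.317375e-01 7.251000e+00
3.063887e+01 7.284143e+00 1.006632e-01 3.189476e-01 6.822228e+00
3.253477e+01 6.112551e+00 1.049932e-01 2.849794e-01 5.734580e+00
3.454798e+01 5.125102e+00 1.090716e-01 2.544256e-01 4.820333e+00
3.668577e+01 4.292920e+00 1.128691e-01 2.269848e-01 4.051842e+00
3.895584e+01 3.591660e+00 1.163624e-01 2.023732e-01 3.405868e+00
4.000000e+01 3.318841e+00 1.178002e-01 1.923592e-01 3.155000e+00
4.136638e+01 3.007257e+00 1.195344e-01 1.803261e-01 2.858555e+00
4.392609e+01 2.518250e+00 1.223739e-01 1.605979e-01 2.396338e+00
4.664418e+01 2.104876e+00 1.248755e-01 1.429619e-01 2.008859e+00
4.953047e+01 1.755507e+00 1.270389e-01 1.272101e-01 1.684035e+00
5.000000e+01 1.705758e+00 1.273483e-01 1.248934e-01 1.638000e+00
5.259536e+01 1.469162e+00 1.288681e-01 1.131521e-01 1.410400e+00
5.584989e+01 1.227392e+00 1.303712e-01 1.006145e-01 1.181019e+00
5.930582e+01 1.021922e+00 1.315592e-01 8.943994e-02 9.889438e-01
6.000000e+01 9.858264e-01 1.317541e-01 8.741943e-02 9.555000e-01
6.297560e+01 8.582265e-01 1.324456e-01 7.948567e-02 8.288554e-01
6.687245e+01 7.200026e-01 1.330456e-01 7.062283e-02 6.948327e-01
7.101044e+01 6.011252e-01 1.333756e-01 6.273522e-02 5.824810e-01
7.540448e+01 4.989368e-01 1.334527e-01 5.571828e-02 4.882961e-01
8.000000e+01 4.123376e-01 1.332981e-01 4.956432e-02 4.104000e-01
8.007042e+01 4.113238e-01 1.332942e-01 4.947807e-02 4.093753e-01
8.502509e+01 3.465612e-01 1.329174e-01 4.393033e-02 3.451717e-01
9.028634e+01 2.897934e-01 1.323393e-01 3.899958e-02 2.910374e-01
9.587315e+01 2.400708e-01 1.315765e-01 3.461827e-02 2.453932e-01
1.000000e+02 2.089224e-01 1.309392e-01 3.183831e-02 2.177000e-01
1.018057e+02 2.000096e-01 1.306448e-01 3.072602e-02 2.082456e-01
1.081053e+02 1.719780e-01 1.295592e-01 2.726892e-02 1.794249e-01
1.147947e+02 1.466349e-01 1.283343e-01 2.419883e-02 1.545928e-01
1.218981e+02 1.237452e-01 1.269834e-01 2.147285e-02 1.331975e-01
1.294410e+02 1.030935e-01 1.255193e-01 1.905274e-02 1.147633e-01
1.374506e+02 8.448289e-02 1.239541e-01 1.690444e-02 9.888029e-02
1.459559e+02 6.773311e-02 1.222987e-01 1.499761e-02 8.519547e-02
1.500000e+02 6.067960e-02 1.215182e-01 1.420216e-02 7.961000e-02
1.549875e+02 5.601930e-02 1.205638e-01 1.330528e-02 7.520409e-02
1.645780e+02 4.793015e-02 1.187589e-01 1.180345e-02 6.774152e-02
1.747618e+02 4.041664e-02 1.168931e-01 1.047077e-02 6.101948e-02
1.855759e+02 3.344832e-02 1.149748e-01 9.288273e-03 5.496446e-02
1.970591e+02 2.699569e-02 1.130118e-01 8.239089e-03 4.951029e-02
2.000000e+02 2.547964e-02 1.125214e-01 7.998965e-03 4.825000e-02
2.092529e+02 2.312748e-02 1.110112e-01 7.308239e-03 4.634278e-02
2.222012e+02 2.015892e-02 1.089799e-01 6.482416e-03 4.392683e-02
2.359508e+02 1.736182e-02 1.069238e-01 5.749799e-03 4.163682e-02
2.505511e+02 1.473115e-02 1.048486e-01 5.099892e-03 3.946620e-02
2.660549e+02 1.226159e-02 1.027596e-01 4.523377e-03 3.740874e-02
2.825181e+02 9.947611e-03 1.006613e-01 4.011979e-03 3.545853e-02
3.000000e+02 7.783552e-03 9.855809e-02 3.558356e-03 3.361000e-02
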