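# element: Cu
# Z: 29
# A_g_per_mol: 63.546
# edges_keV: 8.979
# columns: energy_keV pe incoherent coherent muen  (cm^2/g)
1.000000e+00 1.056477e+04 1.860031e-04 5.226815e+00 1.049000e+04
1.061879e+00 9.283940e+03 2.109179e-04 5.217374e+00 9.221477e+03
1.127587e+00 8.158318e+03 2.391621e-04 5.206769e+00 8.106353e+03
1.197360e+00 7.169097e+03 2.711786e-04 5.194862e+00 7.126077e+03
1.271452e+00 6.299751e+03 3.074686e-04 5.181502e+00 6.264343e+03
1.350128e+00 5.535752e+03 3.485997e-04 5.166519e+00 5.506815e+03
1.433672e+00 4.864336e+03 3.952135e-04 5.149728e+00 4.840893e+03
1.500000e+00 4.412864e+03 4.343833e-04 5.135764e+00 4.393000e+03
1.522386e+00 4.252430e+03 4.480360e-04 5.130926e+00 4.233489e+03
1.616589e+00 3.659688e+03 5.078880e-04 5.109888e+00 3.644144e+03
1.716622e+00 3.149476e+03 5.756970e-04 5.086373e+00 3.136842e+03
1.822844e+00 2.710305e+03 6.525111e-04 5.060115e+00 2.700162e+03
1.935640e+00 2.332285e+03 7.395135e-04 5.030830e+00 2.324272e+03
2.000000e+00 2.148986e+03 7.916689e-04 5.013494e+00 2.142000e+03
2.055415e+00 2.000926e+03 8.380398e-04 4.998213e+00 1.993530e+03
2.182602e+00 1.710437e+03 9.495966e-04 4.961939e+00 1.702510e+03
2.317659e+00 1.462030e+03 1.075882e-03 4.921662e+00 1.453974e+03
2.461073e+00 1.249611e+03 1.218808e-03 4.877024e+00 1.241720e+03
2.613361e+00 1.067968e+03 1.380529e-03 4.827653e+00 1.060451e+03
2.775072e+00 9.126453e+02 1.563463e-03 4.773167e+00 9.056442e+02
2.946791e+00 7.798320e+02 1.770330e-03 4.713187e+00 7.734364e+02
3.000000e+00 7.441040e+02 1.837061e-03 4.694190e+00 7.379000e+02
3.129135e+00 6.644428e+02 2.004178e-03 4.647337e+00 6.592834e+02
3.322762e+00 5.653901e+02 2.268423e-03 4.575258e+00 5.615283e+02
3.528370e+00 4.810290e+02 2.566885e-03 4.496619e+00 4.782678e+02
3.746702e+00 4.091843e+02 2.903830e-03 4.411127e+00 4.073527e+02
3.978543e+00 3.480028e+02 3.284010e-03 4.318546e+00 3.469526e+02
4.000000e+00 3.429868e+02 3.320353e-03 4.309900e+00 3.420000e+02
4.224731e+00 2.953358e+02 3.712708e-03 4.218706e+00 2.947926e+02
4.486152e+00 2.505311e+02 4.195780e-03 4.111525e+00 2.504145e+02
4.763750e+00 2.124670e+02 4.739702e-03 3.997019e+00 2.127170e+02
5.000000e+00 1.859953e+02 5.227336e-03 3.899461e+00 1.865000e+02
5.058525e+00 1.800973e+02 5.351607e-03 3.875322e+00 1.806504e+02
5.371541e+00 1.524822e+02 6.039321e-03 3.746692e+00 1.532620e+02
5.703926e+00 1.290570e+02 6.811394e-03 3.611523e+00 1.300259e+02
6.000000e+00 1.120996e+02 7.534471e-03 3.492907e+00 1.132000e+02
6.056878e+00 1.091713e+02 7.677117e-03 3.470351e+00 1.102860e+02
6.431670e+00 9.222667e+01 8.646526e-03 3.323846e+00 9.342157e+01
6.829655e+00 7.787919e+01 9.730383e-03 3.172813e+00 7.913597e+01
7.252266e+00 6.573462e+01 1.094014e-02 3.018172e+00 6.703485e+01
7.701027e+00 5.545825e+01 1.228786e-02 2.860941e+00 5.678419e+01
8.000000e+00 4.977643e+01 1.322004e-02 2.760348e+00 5.111000e+01
8.177558e+00 4.676399e+01 1.378610e-02 2.702209e+00 4.805986e+01
8.683575e+00 3.941026e+01 1.544777e-02 2.543109e+00 4.061557e+01
8.978991e+00 3.581883e+01 1.644937e-02 2.454722e+00 3.698000e+01
8.979009e+00 2.759288e+02 1.644943e-02 2.454717e+00 2.050000e+02
9.220905e+00 2.590631e+02 1.728589e-02 2.384784e+00 1.928348e+02
9.791484e+00 2.246642e+02 1.931332e-02 2.228354e+00 1.679500e+02
1.000000e+01 2.137058e+02 2.007209e-02 2.174102e+00 1.600000e+02
1.039737e+01 1.927038e+02 2.154243e-02 2.074887e+00 1.451043e+02
1.104075e+01 1.643055e+02 2.398465e-02 1.925369e+00 1.248220e+02
1.172393e+01 1.400850e+02 2.665003e-02 1.780680e+00 1.073746e+02
1.244940e+01 1.194288e+02 2.954662e-02 1.641578e+00 9.236607e+01
1.321975e+01 1.018130e+02 3.267993e-02 1.508687e+00 7.945536e+01
1.403777e+01 8.679058e+01 3.605222e-02 1.382490e+00 6.834928e+01
1.490642e+01 7.398024e+01 3.966193e-02 1.263334e+00 5.879558e+01
1.500000e+01 7.275862e+01 4.005166e-02 1.251329e+00 5.788000e+01
1.582881e+01 6.275282e+01 4.350300e-02 1.151431e+00 5.049196e+01
1.680828e+01 5.319469e+01 4.756442e-02 1.046871e+00 4.335254e+01
1.784835e+01 4.508787e+01 5.182976e-02 9.496335e-01 3.722261e+01
1.895279e+01 3.821215e+01 5.627701e-02 8.596031e-01 3.195943e+01
2.000000e+01 3.294469e+01 6.039263e-02 7.849187e-01 2.788000e+01
2.012556e+01 3.236850e+01 6.087857e-02 7.765852e-01 2.741374e+01
2.137091e+01 2.732558e+01 6.560157e-02 7.003209e-01 2.331857e+01
2.269332e+01 2.306387e+01 7.040839e-02 6.305027e-01 1.983515e+01
2.409755e+01 1.946242e+01 7.525753e-02 5.667876e-01 1.687210e+01
2.558868e+01 1.641901e+01 8.010470e-02 5.088099e-01 1.435168e+01
2.717208e+01 1.384723e+01 8.490409e-02 4.561916e-01 1.220778e+01
2.885345e+01 1.167404e+01 8.960979e-02 4.085509e-01 1.038413e+01
3.000000e+01 1.044729e+01 9.259260e-02 3.801155e-01 9.349000e+00
3.063887e+01 9.831910e+00 9.417716e-02 3.655101e-01 8.811075e+00
3.253477e+01 8.267207e+00 9.856423e-02 3.267010e-01 7.442170e+00
3.454798e+01 6.947320e+00 1.027329e-01 2.917689e-01 6.285942e+00
3.668577e+01 5.834011e+00 1.066497e-01 2.603765e-01 5.309347e+00
3.895584e+01 4.895018e+00 1.102870e-01 2.322051e-01 4.484477e+00
4.000000e+01 4.529467e+00 1.117948e-01 2.207385e-01 4.163000e+00
4.136638e+01 4.107562e+00 1.136228e-01 2.069566e-01 3.779852e+00
4.392609e+01 3.445815e+00 1.166411e-01 1.843537e-01 3.180701e+00
4.664418e+01 2.886838e+00 1.193320e-01 1.641398e-01 2.676522e+00
4.953047e+01 2.414743e+00 1.216909e-01 1.460791e-01 2.252262e+00
5.000000e+01 2.347546e+00 1.220314e-01 1.434223e-01 2.192000e+00
5.259536e+01 2.023969e+00 1.237183e-01 1.299553e-01 1.892050e+00
5.584989e+01 1.694138e+00 1.254188e-01 1.155714e-01 1.588947e+00
5.930582e+01 1.414572e+00 1.268011e-01 1.027479e-01 1.334400e+00
6.000000e+01 1.365538e+00 1.270331e-01 1.004289e-01 1.290000e+00
6.297560e+01 1.188234e+00 1.278764e-01 9.132217e-02 1.120384e+00
6.687245e+01 9.971944e-01 1.286585e-01 8.114720e-02 9.406435e-01
7.101044e+01 8.338587e-01 1.291625e-01 7.209022e-02 7.897380e-01
7.540448e+01 6.942647e-01 1.294050e-01 6.403171e-02 6.630420e-01
8.000000e+01 5.766321e-01 1.294046e-01 5.696330e-02 5.581000e-01
8.007042e+01 5.752015e-01 1.294029e-01 5.686422e-02 5.566979e-01
8.502509e+01 4.842521e-01 1.291734e-01 5.049129e-02 4.688986e-01
9.028634e+01 4.053021e-01 1.287337e-01 4.482650e-02 3.949465e-01
9.587315e+01 3.368111e-01 1.281006e-01 3.979244e-02 3.326578e-01
1.000000e+02 2.942525e-01 1.275494e-01 3.659806e-02 2.949000e-01
1.018057e+02 2.813261e-01 1.272903e-01 3.531991e-02 2.814854e-01
1.081053e+02 2.409971e-01 1.263185e-01 3.134708e-02 2.407806e-01
1.147947e+02 2.049874e-01 1.252002e-01 2.781876e-02 2.059619e-01
1.218981e+02 1.728611e-01 1.239493e-01 2.468572e-02 1.761784e-01
1.294410e+02 1.442260e-01 1.225792e-01 2.190407e-02 1.507017e-01
1.374506e+02 1.187291e-01 1.211023e-01 1.943470e-02 1.289091e-01
1.459559e+02 9.605232e-02 1.195305e-01 1.724281e-02 1.102679e-01
1.500000e+02 8.658513e-02 1.187864e-01 1.632842e-02 1.027000e-01
1.549875e+02 7.982775e-02 1.178745e-01 1.529742e-02 9.620438e-02
1.645780e+02 6.819295e-02 1.161445e-01 1.357094e-02 8.533154e-02
1.747618e+02 5.749747e-02 1.143501e-01 1.203887e-02 7.568754e-02
1.855759e+02 4.767859e-02 1.124999e-01 1.067942e-02 6.713348e-02
1.970591e+02 3.867718e-02 1.106021e-01 9.473197e-03 5.954618e-02
2.000000e+02 3.657550e-02 1.101274e-01 9.197129e-03 5.781000e-02
2.092529e+02 3.317174e-02 1.086641e-01 8.403002e-03 5.486394e-02
2.222012e+02 2.889325e-02 1.066930e-01 7.453537e-03 5.118357e-02
2.359508e+02 2.487939e-02 1.046951e-01 6.611220e-03 4.775009e-02
2.505511e+02 2.111986e-02 1.026762e-01 5.863986e-03 4.454693e-02
2.660549e+02 1.760427e-02 1.006417e-01 5.201126e-03 4.155864e-02
2.825181e+02 1.432228e-02 9.859641e-02 4.613130e-03 3.877081e-02
3.000000e+02 1.126364e-02 9.654480e-02 4.091556e-03 3.617000e-02
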