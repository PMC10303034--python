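# element: Al
# Z: 13
# A_g_per_mol: 26.982
# edges_keV: 1.56
# columns: energy_keV pe incoherent coherent muen  (cm^2/g)
1.000000e+00 1.182542e+03 4.508071e-04 2.458027e+00 1.183000e+03
1.061879e+00 1.007334e+03 5.111011e-04 2.451641e+00 1.007590e+03
1.127587e+00 8.580351e+02 5.794263e-04 2.444479e+00 8.581898e+02
1.197360e+00 7.308130e+02 6.568435e-04 2.436454e+00 7.309416e+02
1.271452e+00 6.224039e+02 7.445518e-04 2.427467e+00 6.225611e+02
1.350128e+00 5.300266e+02 8.439049e-04 2.417414e+00 5.302507e+02
1.433672e+00 4.513107e+02 9.564312e-04 2.406177e+00 4.516277e+02
1.500000e+00 3.998021e+02 1.050930e-03 2.396855e+00 4.002000e+02
1.522386e+00 3.841622e+02 1.083855e-03 2.393631e+00 3.847156e+02
1.559998e+00 3.597107e+02 1.140348e-03 2.388126e+00 3.605000e+02
1.560002e+00 3.954611e+03 1.140353e-03 2.388125e+00 3.829000e+03
1.616589e+00 3.649891e+03 1.228119e-03 2.379640e+00 3.537407e+03
1.716622e+00 3.188583e+03 1.391413e-03 2.364059e+00 3.095424e+03
1.822844e+00 2.785546e+03 1.576201e-03 2.346734e+00 2.708665e+03
1.935640e+00 2.433422e+03 1.785253e-03 2.327499e+00 2.370229e+03
2.000000e+00 2.260682e+03 1.910449e-03 2.316157e+00 2.204000e+03
2.055415e+00 2.105359e+03 2.021681e-03 2.306186e+00 2.053785e+03
2.182602e+00 1.800565e+03 2.288974e-03 2.282617e+00 1.758769e+03
2.317659e+00 1.539858e+03 2.591043e-03 2.256612e+00 1.506130e+03
2.461073e+00 1.316860e+03 2.932257e-03 2.227990e+00 1.289782e+03
2.613361e+00 1.126120e+03 3.317497e-03 2.196576e+00 1.104511e+03
2.775072e+00 9.629732e+02 3.752196e-03 2.162200e+00 9.458533e+02
2.946791e+00 8.234289e+02 4.242394e-03 2.124705e+00 8.099861e+02
3.000000e+00 7.858827e+02 4.400214e-03 2.112906e+00 7.734000e+02
3.129135e+00 7.006165e+02 4.794781e-03 2.083957e+00 6.901072e+02
3.322762e+00 5.948438e+02 5.416749e-03 2.039846e+00 5.866988e+02
3.528370e+00 5.050087e+02 6.116433e-03 1.992294e+00 4.987855e+02
3.746702e+00 4.287118e+02 6.902750e-03 1.941266e+00 4.240454e+02
3.978543e+00 3.639149e+02 7.785428e-03 1.886775e+00 3.605048e+02
4.000000e+00 3.586104e+02 7.869557e-03 1.881726e+00 3.553000e+02
4.224731e+00 3.076591e+02 8.775020e-03 1.828889e+00 3.051851e+02
4.486152e+00 2.599733e+02 9.882904e-03 1.767735e+00 2.582463e+02
4.763750e+00 2.196562e+02 1.112126e-02 1.703506e+00 2.185268e+02
5.000000e+00 1.917381e+02 1.222334e-02 1.649662e+00 1.910000e+02
5.058525e+00 1.854706e+02 1.250299e-02 1.636461e+00 1.848110e+02
5.371541e+00 1.562338e+02 1.404166e-02 1.566923e+00 1.559268e+02
5.703926e+00 1.315885e+02 1.575133e-02 1.495278e+00 1.315569e+02
6.000000e+00 1.138491e+02 1.733571e-02 1.433577e+00 1.140000e+02
6.056878e+00 1.107680e+02 1.764637e-02 1.421965e+00 1.109343e+02
6.431670e+00 9.301480e+01 1.974117e-02 1.347470e+00 9.326686e+01
6.829655e+00 7.809385e+01 2.204986e-02 1.272312e+00 7.841316e+01
7.252266e+00 6.555476e+01 2.458586e-02 1.197026e+00 6.592506e+01
7.701027e+00 5.501857e+01 2.736139e-02 1.122153e+00 5.542582e+01
8.000000e+00 4.922564e+01 2.925116e-02 1.075111e+00 4.965000e+01
8.177558e+00 4.612592e+01 3.038694e-02 1.048222e+00 4.648725e+01
8.683575e+00 3.860297e+01 3.367062e-02 9.757366e-01 3.882855e+01
9.220905e+00 3.229894e+01 3.721747e-02 9.051578e-01 3.243162e+01
9.791484e+00 2.701702e+01 4.102879e-02 8.368981e-01 2.708857e+01
1.000000e+01 2.537401e+01 4.242870e-02 8.135585e-01 2.543000e+01
1.039737e+01 2.257196e+01 4.510143e-02 7.713109e-01 2.261051e+01
1.104075e+01 1.884266e+01 4.942719e-02 7.086856e-01 1.886583e+01
1.172393e+01 1.572330e+01 5.399226e-02 6.492455e-01 1.574134e+01
1.244940e+01 1.311443e+01 5.877695e-02 5.931485e-01 1.313432e+01
1.321975e+01 1.093273e+01 6.375549e-02 5.404901e-01 1.095906e+01
1.403777e+01 9.108430e+00 6.889620e-02 4.913078e-01 9.144056e+00
1.490642e+01 7.583106e+00 7.416197e-02 4.455881e-01 7.629650e+00
1.500000e+01 7.439264e+00 7.471641e-02 4.410196e-01 7.487000e+00
1.582881e+01 6.318639e+00 7.951092e-02 4.032726e-01 6.346874e+00
1.680828e+01 5.260908e+00 8.489750e-02 3.642664e-01 5.277918e+00
1.784835e+01 4.375119e+00 9.027370e-02 3.284446e-01 4.388999e+00
1.895279e+01 3.633371e+00 9.559051e-02 2.956599e-01 3.649793e+00
2.000000e+01 3.071999e+00 1.002629e-01 2.687377e-01 3.094000e+00
2.012556e+01 3.015721e+00 1.007994e-01 2.657489e-01 3.034417e+00
2.137091e+01 2.522977e+00 1.058538e-01 2.385379e-01 2.518019e+00
2.269332e+01 2.106296e+00 1.107106e-01 2.138475e-01 2.089502e+00
2.409755e+01 1.753965e+00 1.153309e-01 1.914972e-01 1.733910e+00
2.558868e+01 1.456078e+00 1.196815e-01 1.713086e-01 1.438832e+00
2.717208e+01 1.204260e+00 1.237349e-01 1.531077e-01 1.193971e+00
2.885345e+01 9.914294e-01 1.274699e-01 1.367275e-01 9.907810e-01
3.000000e+01 8.712884e-01 1.297165e-01 1.269951e-01 8.778000e-01
3.063887e+01 8.199027e-01 1.308718e-01 1.220090e-01 8.223386e-01
3.253477e+01 6.871032e-01 1.339316e-01 1.088023e-01 6.827925e-01
3.454798e+01 5.723252e-01 1.366457e-01 9.696702e-02 5.669266e-01
3.668577e+01 4.731597e-01 1.390156e-01 8.637286e-02 4.707225e-01
3.895584e+01 3.875216e-01 1.410470e-01 7.689926e-02 3.908436e-01
4.000000e+01 3.536110e-01 1.418368e-01 7.305227e-02 3.601000e-01
4.136638e+01 3.213116e-01 1.427489e-01 6.843540e-02 3.254833e-01
4.392609e+01 2.687124e-01 1.441331e-01 6.087980e-02 2.716866e-01
4.664418e+01 2.220879e-01 1.452134e-01 5.413986e-02 2.267817e-01
4.953047e+01 1.807909e-01 1.460051e-01 4.813143e-02 1.892987e-01
5.000000e+01 1.747471e-01 1.461043e-01 4.724865e-02 1.840000e-01
5.259536e+01 1.511362e-01 1.465243e-01 4.277820e-02 1.594758e-01
5.584989e+01 1.255046e-01 1.467876e-01 3.801116e-02 1.345827e-01
5.930582e+01 1.022559e-01 1.468117e-01 3.376807e-02 1.135752e-01
6.000000e+01 9.800851e-02 1.467901e-01 3.300144e-02 1.099000e-01
6.297560e+01 8.664949e-02 1.466130e-01 2.999288e-02 9.785018e-02
6.687245e+01 7.342475e-02 1.462075e-01 2.663520e-02 8.472267e-02
7.101044e+01 6.111528e-02 1.456107e-01 2.364983e-02 7.335633e-02
7.540448e+01 4.967610e-02 1.448373e-01 2.099624e-02 6.351489e-02
8.000000e+01 3.921306e-02 1.439162e-01 1.867074e-02 5.511000e-02
8.007042e+01 3.912594e-02 1.439014e-01 1.863815e-02 5.502893e-02
8.502509e+01 3.333486e-02 1.428161e-01 1.654315e-02 4.976992e-02
9.028634e+01 2.784564e-02 1.415939e-01 1.468224e-02 4.501351e-02
9.587315e+01 2.265465e-02 1.402467e-01 1.302957e-02 4.071165e-02
1.000000e+02 1.918645e-02 1.392322e-01 1.198137e-02 3.794000e-02
1.018057e+02 1.846310e-02 1.387853e-01 1.156206e-02 3.745053e-02
1.081053e+02 1.610575e-02 1.372202e-01 1.025916e-02 3.585404e-02
1.147947e+02 1.385790e-02 1.355610e-01 9.102547e-03 3.432560e-02
1.218981e+02 1.172171e-02 1.338169e-01 8.075907e-03 3.286232e-02
1.294410e+02 9.698263e-03 1.319966e-01 7.164726e-03 3.146141e-02
1.374506e+02 7.787689e-03 1.301080e-01 6.356090e-03 3.012023e-02
1.459559e+02 5.989293e-03 1.281587e-01 5.638513e-03 2.883622e-02
1.500000e+02 5.207451e-03 1.272533e-01 5.339215e-03 2.827000e-02
1.549875e+02 4.785161e-03 1.261561e-01 5.001786e-03 2.817555e-02
1.645780e+02 4.055734e-03 1.241068e-01 4.436834e-03 2.800299e-02
1.747618e+02 3.385102e-03 1.220173e-01 3.935592e-03 2.783149e-02
1.855759e+02 2.772389e-03 1.198935e-01 3.490899e-03 2.766104e-02
1.970591e+02 2.216320e-03 1.177411e-01 3.096390e-03 2.749164e-02
2.000000e+02 2.087655e-03 1.172062e-01 3.006107e-03 2.745000e-02
2.092529e+02 1.822669e-03 1.155654e-01 2.746417e-03 2.752830e-02
2.222012e+02 1.511389e-03 1.133715e-01 2.435961e-03 2.763259e-02
2.359508e+02 1.244658e-03 1.111639e-01 2.160569e-03 2.773728e-02
2.505511e+02 1.020545e-03 1.089471e-01 1.916287e-03 2.784236e-02
2.660549e+02 8.370228e-04 1.067250e-01 1.699605e-03 2.794784e-02
2.825181e+02 6.920145e-04 1.045014e-01 1.507410e-03 2.805372e-02
3.000000e+02 5.834265e-04 1.022796e-01 1.336937e-03 2.816000e-02
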