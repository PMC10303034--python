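# element: O
# Z: 8
# A_g_per_mol: 15.999
# columns: energy_keV pe incoherent coherent muen  (cm^2/g)
1.000000e+00 4.589388e+03 7.730218e-04 1.561843e+00 4.576378e+03
1.061879e+00 3.907189e+03 8.762310e-04 1.556793e+00 3.896512e+03
1.127587e+00 3.326364e+03 9.931363e-04 1.551139e+00 3.317649e+03
1.197360e+00 2.831849e+03 1.125532e-03 1.544812e+00 2.824783e+03
1.271452e+00 2.410820e+03 1.275443e-03 1.537740e+00 2.405138e+03
1.350128e+00 2.052356e+03 1.445149e-03 1.529842e+00 2.047837e+03
1.433672e+00 1.747162e+03 1.637217e-03 1.521034e+00 1.743617e+03
1.500000e+00 1.547601e+03 1.798400e-03 1.513742e+00 1.544684e+03
1.522386e+00 1.484963e+03 1.854535e-03 1.511223e+00 1.482064e+03
1.616589e+00 1.255982e+03 2.100345e-03 1.500310e+00 1.253208e+03
1.716622e+00 1.062278e+03 2.378288e-03 1.488193e+00 1.059693e+03
1.822844e+00 8.984175e+02 2.692442e-03 1.474763e+00 8.960622e+02
1.935640e+00 7.598030e+02 3.047369e-03 1.459906e+00 7.576995e+02
2.000000e+00 6.934968e+02 3.259683e-03 1.451172e+00 6.915351e+02
2.055415e+00 6.410934e+02 3.448163e-03 1.443510e+00 6.393132e+02
2.182602e+00 5.394377e+02 3.900502e-03 1.425458e+00 5.380247e+02
2.317659e+00 4.538715e+02 4.410695e-03 1.405636e+00 4.527849e+02
2.461073e+00 3.818494e+02 4.985740e-03 1.383937e+00 3.810508e+02
2.613361e+00 3.212288e+02 5.633370e-03 1.360259e+00 3.206827e+02
2.775072e+00 2.702059e+02 6.362103e-03 1.334513e+00 2.698796e+02
2.946791e+00 2.272626e+02 7.181280e-03 1.306627e+00 2.271253e+02
3.000000e+00 2.158309e+02 7.444432e-03 1.297893e+00 2.157428e+02
3.129135e+00 1.905358e+02 8.101103e-03 1.276549e+00 1.905438e+02
3.322762e+00 1.595127e+02 9.132647e-03 1.244253e+00 1.596424e+02
3.528370e+00 1.335182e+02 1.028787e-02 1.209742e+00 1.337524e+02
3.746702e+00 1.117386e+02 1.157956e-02 1.173054e+00 1.120611e+02
3.978543e+00 9.349216e+01 1.302134e-02 1.134267e+00 9.388762e+01
4.000000e+00 9.200980e+01 1.315830e-02 1.130693e+00 9.241109e+01
4.224731e+00 7.803880e+01 1.462749e-02 1.093497e+00 7.848013e+01
4.486152e+00 6.510824e+01 1.641287e-02 1.050904e+00 6.558620e+01
4.763750e+00 5.430385e+01 1.839270e-02 1.006689e+00 5.481066e+01
5.000000e+00 4.690241e+01 2.014078e-02 9.700265e-01 4.742698e+01
5.058525e+00 4.526593e+01 2.058227e-02 9.610938e-01 4.578958e+01
5.371541e+00 3.767856e+01 2.299663e-02 9.143949e-01 3.819803e+01
5.703926e+00 3.134988e+01 2.565012e-02 8.668986e-01 3.186507e+01
6.000000e+00 2.683933e+01 2.808210e-02 8.264883e-01 2.735017e+01
6.056878e+00 2.607003e+01 2.855594e-02 8.189336e-01 2.657939e+01
6.431670e+00 2.165879e+01 3.172550e-02 7.708417e-01 2.215858e+01
6.829655e+00 1.798349e+01 3.516779e-02 7.229686e-01 1.847302e+01
7.252266e+00 1.492208e+01 3.888866e-02 6.756534e-01 1.540044e+01
7.701027e+00 1.237267e+01 4.289013e-02 6.292197e-01 1.283889e+01
8.000000e+00 1.098145e+01 4.557306e-02 6.003576e-01 1.143950e+01
8.177558e+00 1.025607e+01 4.716960e-02 5.839666e-01 1.065690e+01
8.683575e+00 8.501920e+00 5.171924e-02 5.401621e-01 8.779203e+00
9.220905e+00 7.039991e+00 5.652543e-02 4.980368e-01 7.232306e+00
9.791484e+00 5.821869e+00 6.156837e-02 4.577812e-01 5.957928e+00
1.000000e+01 5.444418e+00 6.338974e-02 4.441248e-01 5.566078e+00
1.039737e+01 4.833414e+00 6.682193e-02 4.195435e-01 4.921452e+00
1.104075e+01 4.017992e+00 7.225380e-02 3.834300e-01 4.071236e+00
1.172393e+01 3.333650e+00 7.782593e-02 3.495067e-01 3.367852e+00
1.244940e+01 2.759369e+00 8.349521e-02 3.178023e-01 2.785939e+00
1.321975e+01 2.277487e+00 8.921461e-02 2.883122e-01 2.304517e+00
1.403777e+01 1.873163e+00 9.493443e-02 2.610026e-01 1.906230e+00
1.490642e+01 1.533935e+00 1.006038e-01 2.358158e-01 1.576718e+00
1.500000e+01 1.501883e+00 1.011898e-01 2.333095e-01 1.545829e+00
1.582881e+01 1.278665e+00 1.061721e-01 2.126742e-01 1.302511e+00
1.680828e+01 1.063415e+00 1.115908e-01 1.914853e-01 1.075771e+00
1.784835e+01 8.790094e-01 1.168146e-01 1.721461e-01 8.884316e-01
1.895279e+01 7.210304e-01 1.218029e-01 1.545462e-01 7.336420e-01
2.000000e+01 5.988499e-01 1.260421e-01 1.401640e-01 6.179650e-01
2.012556e+01 5.892461e-01 1.265203e-01 1.385713e-01 6.059975e-01
2.137091e+01 5.026895e-01 1.309379e-01 1.241062e-01 5.022899e-01
2.269332e+01 4.254688e-01 1.350328e-01 1.110365e-01 4.162473e-01
2.409755e+01 3.565927e-01 1.387890e-01 9.925078e-02 3.448571e-01
2.558868e+01 2.951800e-01 1.421963e-01 8.864170e-02 2.856200e-01
2.717208e+01 2.404458e-01 1.452504e-01 7.910697e-02 2.364632e-01
2.885345e+01 1.916904e-01 1.479520e-01 7.055005e-02 1.956671e-01
3.000000e+01 1.629481e-01 1.495190e-01 6.547661e-02 1.729787e-01
3.063887e+01 1.545675e-01 1.503062e-01 6.288052e-02 1.628762e-01
3.253477e+01 1.317381e-01 1.523215e-01 5.601426e-02 1.371458e-01
3.454798e+01 1.104055e-01 1.540096e-01 4.987348e-02 1.153826e-01
3.668577e+01 9.049911e-02 1.553840e-01 4.438658e-02 9.697103e-02
3.895584e+01 7.194955e-02 1.564597e-01 3.948799e-02 8.139111e-02
4.000000e+01 6.419044e-02 1.568430e-01 3.750092e-02 7.530986e-02
4.136638e+01 5.883535e-02 1.572529e-01 3.511782e-02 6.959082e-02
4.392609e+01 4.956708e-02 1.577800e-01 3.122165e-02 6.036187e-02
4.664418e+01 4.069363e-02 1.580575e-01 2.775009e-02 5.227017e-02
4.953047e+01 3.221812e-02 1.581018e-01 2.465847e-02 4.517297e-02
5.000000e+01 3.092247e-02 1.580886e-01 2.420449e-02 4.413971e-02
5.259536e+01 2.692107e-02 1.579286e-01 2.190650e-02 4.045938e-02
5.584989e+01 2.231197e-02 1.575533e-01 1.945787e-02 3.643506e-02
5.930582e+01 1.786253e-02 1.569902e-01 1.727995e-02 3.275107e-02
6.000000e+01 1.701930e-02 1.568606e-01 1.688660e-02 3.207382e-02
6.297560e+01 1.512822e-02 1.562532e-01 1.534344e-02 3.073370e-02
6.687245e+01 1.284610e-02 1.553551e-01 1.362208e-02 2.912757e-02
7.101044e+01 1.064220e-02 1.543081e-01 1.209237e-02 2.758145e-02
7.540448e+01 8.523277e-03 1.531236e-01 1.073328e-02 2.609316e-02
8.000000e+01 6.523696e-03 1.518322e-01 9.542707e-03 2.468121e-02
8.007042e+01 6.508089e-03 1.518121e-01 9.526028e-03 2.467671e-02
8.502509e+01 5.472277e-03 1.503837e-01 8.453842e-03 2.437014e-02
9.028634e+01 4.496455e-03 1.488476e-01 7.501766e-03 2.406476e-02
9.587315e+01 3.583723e-03 1.472127e-01 6.656466e-03 2.376099e-02
1.000000e+02 2.981939e-03 1.460104e-01 6.120453e-03 2.354895e-02
1.018057e+02 2.825433e-03 1.454871e-01 5.906061e-03 2.360896e-02
1.081053e+02 2.336944e-03 1.436788e-01 5.239974e-03 2.381420e-02
1.147947e+02 1.905452e-03 1.417950e-01 4.648790e-03 2.402587e-02
1.218981e+02 1.531243e-03 1.398429e-01 4.124132e-03 2.424445e-02
1.294410e+02 1.214030e-03 1.378291e-01 3.658551e-03 2.447042e-02
1.374506e+02 9.530253e-04 1.357599e-01 3.245424e-03 2.470427e-02
1.459559e+02 7.470059e-04 1.336415e-01 2.878863e-03 2.494646e-02
1.500000e+02 6.710156e-04 1.326625e-01 2.725985e-03 2.505959e-02
1.549875e+02 5.554372e-04 1.314797e-01 2.553638e-03 2.524228e-02
1.645780e+02 3.852122e-04 1.292802e-01 2.265102e-03 2.558651e-02
1.747618e+02 2.673227e-04 1.270481e-01 2.009127e-03 2.594261e-02
1.855759e+02 1.992996e-04 1.247887e-01 1.782046e-03 2.631102e-02
1.970591e+02 1.785209e-04 1.225068e-01 1.580606e-03 2.669212e-02
2.000000e+02 1.803479e-04 1.219409e-01 1.534509e-03 2.678815e-02
2.092529e+02 5.871691e-05 1.202071e-01 1.401917e-03 2.698548e-02
2.222012e+02 0.000000e+00 1.178343e-01 1.243413e-03 2.725621e-02
2.359508e+02 0.000000e+00 1.154401e-01 1.102817e-03 2.753715e-02
2.505511e+02 0.000000e+00 1.130839e-01 9.781094e-04 2.782853e-02
2.660549e+02 0.000000e+00 1.107664e-01 8.674961e-04 2.813055e-02
2.825181e+02 0.000000e+00 1.084881e-01 7.693859e-04 2.844337e-02
3.000000e+02 0.000000e+00 1.062493e-01 6.823668e-04 2.876714e-02
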