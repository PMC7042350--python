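# The ten replicate symbolic-regression equations for depth-integrated net
# primary productivity, transcribed digit-for-digit, one per line, in
# publication order. y = NPP (mg C m-2 d-1, 0-120 m); x1 Julian day,
# x2 day of year, x3 MLD, x4 density gradient (rho20/rho120), x5 mean
# temperature 0-120 m, x6 nitrate, x7 phosphate, x8 silicate, x9 fucoxanthin,
# x10 chlorophyll b, x11 chlorophyll a, x12 lutein+zeaxanthin.
7.114e4 + 0.06431*x9 + 2.427e-7*x11^2 - 0.003803*x11 - 7.022e4*x4 - 0.0009147*x1*x5
792.9 + 1.49*x6 + 0.09097*x9 + 4.264e-6*x12*x3^2 - 0.013*x1 - 0.00675*x3*x5^2
8.915e4 + 0.05748*x9 + 0.03729*x11 + 1.383*x3*cos(19.8*x3) - 61.88*x5 - 8.773e4*x4 - 8.336e-7*x1*x11
1.062e5 + 0.05927*x9 + 0.009645*x11 - 0.01879*x1 - 47.86*x5 - 1.044e5*x4
1.196e5 + 0.0129*x11 - 77.74*x5 - 1.18e5*x4
9.061e4 + x6 + 0.06108*x9 + 0.008486*x11 - 0.0126*x10 - 0.01606*x1 - 43.62*x5 - 8.902e4*x4
1.02e5 + x6 + 0.06454*x9 + 0.03581*x12 - x3*sin(17.72*x11) - 70.7*x5 - 1.005e5*x4
1e5 + 0.07668*x9 + 0.04596*x1 + 6.468e-8*x6*x12^2 - 1.004e5*x4 - 4.023e-8*x5*x1^2
9.307e4 + 0.05733*x9 + 0.009636*x11 - x8*cos(0.05969*x9*x11) - 0.01275*x1 - 54.09*x5 - 9.143e4*x4
978 + x6 + 0.06605*x9 + 0.005877*x11 + 57.83*sin(1959*x9) + 4.59e-6*x12*x3^2 - 0.01948*x1 - 3.408*x3
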