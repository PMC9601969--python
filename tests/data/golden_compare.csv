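y,x2,x3,x4,x5
6.273451,-6.931225,1.405713,-19.963263,14.957717
5.433359,-2.119493,2.038354,-3.676603,-1.259089
7.817411,0.358721,-1.854766,0.609163,-5.140184
-11.668808,-0.304828,-14.744262,-5.772787,7.566216
18.657375,7.418366,17.246103,-8.131887,14.482068
9.758084,-10.695295,12.514582,7.33923,12.377168
1.459649,-4.190133,-5.573853,4.065371,9.767182
2.649053,-7.258165,13.44317,4.939459,8.197279
3.053612,26.594578,30.509081,15.184131,9.271065
2.619009,-3.426921,-1.216508,-3.904332,3.8383
-8.129503,-8.854038,-11.029566,-10.682773,-13.31103
-3.29416,-4.93312,1.571077,-13.16894,2.696506
14.859834,23.545389,-6.829697,10.199764,5.550541
8.426433,13.869094,-2.773835,14.274245,-6.19079
-1.861022,4.731602,-13.338015,-7.640627,-0.959802
-16.335899,6.880192,-20.570845,-19.052541,-11.815633
-9.977498,-2.823565,1.506505,-11.631117,-9.468362
6.572597,10.472167,-4.567143,12.964531,2.978549
9.713725,5.873776,10.478064,-9.019543,-21.880492
10.16666,0.728228,15.643,-12.028418,8.647973
5.476386,12.185082,-5.583623,-7.815097,11.389828
13.0887,3.122896,15.235631,-3.820803,-9.603292
-1.977103,9.185035,-15.649287,-5.523643,22.06584
-15.142077,-8.915622,-25.59975,14.163809,-13.169425
5.829685,-8.488964,14.526331,14.493375,6.514442
0.897059,-9.95908,-3.390638,-2.049331,-7.522329
-16.170883,-3.53419,-23.528778,3.968185,8.426055
6.549663,10.397911,-10.419907,25.635402,-8.20318
8.078038,-7.79723,12.953486,2.545937,6.709546
-11.455182,-7.60938,-18.791593,13.25127,-3.267288
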