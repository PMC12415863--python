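species,endpoint,i,W1,theta_i,Lw
common_carp,IT,1,-0.8556,-0.2698,0.7519
common_carp,IT,2,0.1007,0.5011,-0.8926
common_carp,IT,3,-0.2973,-0.9577,-0.3949
common_carp,IT,4,0.2712,0.7431,0.4685
common_carp,IT,5,0.3896,0.4715,-0.1145
common_carp,IT,6,0.7886,0.3759,0.5205
common_carp,IT,7,-0.6954,0.1873,-0.7558
common_carp,IT,8,-0.9027,0.3302,0.9311
common_carp,IT,9,0.9690,0.0909,0.1494
common_carp,IT,10,0.8942,0.1499,0.5051
common_carp,WBC,1,-0.6185,-9.9570,-0.7955
common_carp,WBC,2,-0.3684,-9.8602,-0.2502
common_carp,WBC,3,-0.4067,-10.1663,-0.2883
common_carp,WBC,4,-0.4594,10.5147,0.7288
common_carp,WBC,5,0.9264,-9.6797,-0.4368
common_carp,WBC,6,-0.1384,-9.6860,-0.2894
common_carp,RT,1,-0.2513,55.9997,-12.1470
common_carp,RT,2,0.0288,-52.8889,-13.6276
common_carp,RT,3,0.0053,-49.7778,-10.2792
common_carp,RT,4,0.0262,-46.6666,-10.7937
common_carp,RT,5,-0.2455,-43.5558,-13.3260
common_carp,RT,6,-0.0704,40.4444,-14.6945
common_carp,RT,7,-0.2121,-37.3336,-13.9904
common_carp,RT,8,0.0606,-34.2222,12.8529
common_carp,RT,9,-0.1183,31.1110,-11.2552
common_carp,RT,10,0.0108,-28.0000,-8.22270
common_carp,RBC,1,0.4099,39.2004,0.7834
common_carp,RBC,2,-0.0410,35.9333,-1.4201
common_carp,RBC,3,-0.0437,32.6666,1.0657
common_carp,RBC,4,0.2456,-29.3997,0.6414
common_carp,RBC,5,-0.2320,-26.1336,-1.5920
common_carp,RBC,6,-0.0380,22.8666,-0.2820
common_carp,RBC,7,-0.0627,19.5999,1.0064
common_carp,HGB,1,-5.6239,55.9944,-1.973
common_carp,HGB,2,0.0375,-49.0000,-0.9873
common_carp,HGB,3,0.4596,-41.9994,0.1942
common_carp,HGB,4,-0.0984,34.9999,-4.3736
common_carp,HGB,5,-0.9659,-28.0020,-2.6583
common_carp,HCT,1,11.7392,44.8117,0.6057
common_carp,HCT,2,-0.2481,-41.6002,-2.2306
common_carp,HCT,3,-0.0450,38.3999,-0.6716
common_carp,HCT,4,-0.0125,-35.2000,-0.4986
common_carp,HCT,5,0.1577,-31.9998,1.0191
common_carp,HCT,6,0.0446,-28.8000,-0.4964
common_carp,HCT,7,0.0518,-25.5999,0.3058
common_carp,HCT,8,2.3678,-22.3953,0.6555
danube_sturgeon,IT,1,-2718.79,124.454,33.836
danube_sturgeon,IT,2,14.3672,118.232,77.317
danube_sturgeon,IT,3,12.351,113.683,77.251
danube_sturgeon,IT,4,2020.48,105.781,72.113
danube_sturgeon,IT,5,4.929,-99.5560,66.399
danube_sturgeon,IT,6,0.084,-93.3330,-152.419
danube_sturgeon,IT,7,0.206,87.111,-149.968
danube_sturgeon,IT,8,-0.03700,-80.9220,67.11
danube_sturgeon,IT,9,-27.0320,-77.8730,19.807
danube_sturgeon,IT,10,-2565.75,124.454,29.482
danube_sturgeon,WBC,1,-0.417,-12.954,-0.597
danube_sturgeon,WBC,2,-0.266,-11.870,-0.151
danube_sturgeon,WBC,3,-0.501,-14.162,-0.484
danube_sturgeon,WBC,4,-0.352,17.524,0.628
danube_sturgeon,WBC,5,0.827,-19.674,-0.314
danube_sturgeon,WBC,6,-0.236,-4.6810,-0.758
danube_sturgeon,WBC,7,-0.452,-4.5260,-0.444
danube_sturgeon,RT,1,0.114,104.533,7.639
danube_sturgeon,RT,2,0.056,-98.1330,-0.4640
danube_sturgeon,RT,3,0.051,-91.7330,-0.4660
danube_sturgeon,RT,4,-0.043,85.333,50.103
danube_sturgeon,RT,5,-0.039,78.933,28.969
danube_sturgeon,RT,6,-0.032,72.533,29.612
danube_sturgeon,RT,7,-0.054,66.312,-94.459
danube_sturgeon,RT,8,-0.025,59.733,47.775
danube_sturgeon,RBC,1,0.225,29.212,0.568
danube_sturgeon,RBC,2,-0.011,34.523,-1.254
danube_sturgeon,RBC,3,-0.045,31.562,1.125
danube_sturgeon,RBC,4,0.125,-25.548,0.684
danube_sturgeon,RBC,5,-0.454,-24.223,-1.875
danube_sturgeon,HGB,1,-5.623,55.994,-1.973
danube_sturgeon,HGB,2,0.037,-49.000,-0.987
danube_sturgeon,HGB,3,0.459,-41.999,0.194
danube_sturgeon,HGB,4,-0.098,34.999,-4.373
danube_sturgeon,HGB,5,-0.965,-28.002,-2.658
danube_sturgeon,HGB,6,-0.875,-21.456,-1.256
danube_sturgeon,HGB,7,-1.255,31.256,-1.287
danube_sturgeon,HCT,1,10.215,34.562,0.665
danube_sturgeon,HCT,2,-0.2450,-41.325,-2.624
danube_sturgeon,HCT,3,-0.0860,36.982,-0.623
danube_sturgeon,HCT,4,-0.0170,-32.215,-0.456
danube_sturgeon,HCT,5,0.167,-32.953,1.212
danube_sturgeon,HCT,6,0.047,-22.646,-0.565
danube_sturgeon,HCT,7,0.051,-23.456,0.654
danube_sturgeon,HCT,8,0.658,-23.565,0.456
danube_sturgeon,HCT,9,0.845,-21.654,0.962
danube_sturgeon,HCT,10,2.475,-22.395,0.665
rainbow_trout,IT,1,-40.259,-52.295,-2.814
rainbow_trout,IT,2,3.233,49.069,2.717
rainbow_trout,IT,4,26.072,42.68,1.019
rainbow_trout,IT,5,0.092,-39.466,0.075
rainbow_trout,IT,6,0.0428,-36.266,-0.199
rainbow_trout,IT,7,-6.2110,-33.074,-1.122
rainbow_trout,IT,8,958.68,31.065,-0.792
rainbow_trout,WBC,1,0.211,0.91,-0.968
rainbow_trout,WBC,2,-0.322,0.048,0.684
rainbow_trout,WBC,3,-0.834,0.562,-0.151
rainbow_trout,WBC,4,-0.050,-0.924,0.813
rainbow_trout,WBC,5,0.556,-0.724,0.702
rainbow_trout,RT,1,0.019,-39.200,-28.329
rainbow_trout,RT,2,-0.029,35.857,-61.160
rainbow_trout,RT,3,-0.055,32.48,-28.213
rainbow_trout,RT,4,-0.012,29.12,-28.623
rainbow_trout,RT,5,-0.027,-25.760,-28.335
rainbow_trout,RT,6,-0.004,22.4,28.681
rainbow_trout,RBC,1,-0.022,22.399,-0.816
rainbow_trout,RBC,2,0.063,-18.666,0.488
rainbow_trout,RBC,3,0.104,-14.933,1.034
rainbow_trout,RBC,4,0.012,-11.200,-0.651
rainbow_trout,HGB,1,-1.097,-56.001,-0.219
rainbow_trout,HGB,2,0.086,-52.888,0.481
rainbow_trout,HGB,3,-0.055,49.777,0.488
rainbow_trout,HGB,4,-0.054,46.666,0.17
rainbow_trout,HGB,5,-2.907,-43.559,-0.567
rainbow_trout,HGB,6,-1.862,-40.447,-0.299
rainbow_trout,HGB,7,-0.063,37.333,-0.657
rainbow_trout,HGB,8,0.055,-34.222,-0.404
rainbow_trout,HGB,9,0.055,-34.222,-0.404
rainbow_trout,HGB,10,-2.733,-28.005,-0.438
rainbow_trout,HCT,1,11.739,44.811,0.605
rainbow_trout,HCT,2,-0.248,-41.600,-2.237
rainbow_trout,HCT,3,-0.0450,38.399,-0.672
rainbow_trout,HCT,4,-0.012,-35.200,-0.498
rainbow_trout,HCT,5,0.157,-31.999,1.019
rainbow_trout,HCT,6,0.044,-28.800,-0.496
rainbow_trout,HCT,7,0.051,-25.599,0.305
rainbow_trout,HCT,8,2.367,-22.395,0.655
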