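subspecies,population,n,Ho,He,Ar,Pr,Fis,H,Hu,Ad,Pi
T. t. jeffersonii,TO,30,0.61,0.72,5.9,0.19,0.17,10,0,0.71,7.9
T. t. jeffersonii,EK,30,0.68,0.76,7.2,0.31,0.11,14,1,0.58,6.95
T. t. taxus,AB,39,0.71,0.79,7.6,0.15,0.12,16,2,0.54,7.39
T. t. taxus,SK,25,0.79,0.81,7.6,0.14,0.01,16,1,0.55,8.62
T. t. taxus,MB,48,0.75,0.81,7.9,0.24,0.07,14,1,0.57,8.63
T. t. taxus,UP,22,0.6,0.73,6.3,0.01,0.17,10,1,0.54,8.72
T. t. jacksoni,LP,23,0.55,0.7,6.3,0.26,0.22,8,0,0.62,5.58
T. t. jacksoni,ON,19,0.35,0.44,3.7,0.05,0.21,9,0,0.62,6.52
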