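# Reference mean HK parameter estimates (epsilon, sigma, c) per (alpha, rho)
# grid cell, with the majority-vote best single model (okrr) per cell.
alpha,rho,epsilon,sigma,c,okrr
0.1,1,0.01,0.17,1.00,K
1,1,0.01,0.26,1.92,K
10,1,0.01,0.29,12.84,RA
100,1,0.01,0.30,100.00,RA
0.1,5,0.10,0.21,1.25,K
1,5,0.36,0.16,5.61,RA
10,5,0.54,0.16,5.69,RI
100,5,0.52,0.13,6.38,RI
0.1,10,0.14,0.20,2.55,K
1,10,0.53,0.14,6.70,RI
10,10,0.60,0.11,40.26,RI
100,10,0.69,0.11,14.02,RI
0.1,50,0.01,0.25,6.82,RA
1,50,0.33,0.15,6.82,RI
10,50,0.01,0.26,2.51,K
100,50,0.11,0.16,1.10,K
0.1,100,0.24,0.26,100.00,RA
1,100,0.27,0.23,3.08,RA
10,100,0.10,0.24,1.27,K
100,100,0.09,0.20,1.10,K
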