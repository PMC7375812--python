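capsid,sample,n_dyes,n_nls,a,i_max,tau,j,delta_g
MS2^S37P,1,23,0,0.24,0.39,0.022,0.01,6.34
MS2^S37P,2,15,14,0.65,0.94,0.054,0.05,4.54
MS2^S37P,3,30,19,1.12,12.44,0.041,0.49,2.01
MS2^S37P,4,34,23,0.64,16.63,0.053,0.88,1.25
MS2^S37P,5,25,29,0.33,28.91,0.022,0.64,1.51
MS2^S37P,6,38,38,1.45,43.59,0.037,1.60,-0.02
MS2^S37P,7,10,54,2.33,49.76,0.029,1.37,0.32
I53-47,8,24,0,0.18,1.58,0.018,0.03,5.27
I53-47,9,30,15,0.80,3.71,0.085,0.32,3.19
I53-47,10,31,18,3.81,3.89,0.056,0.22,3.29
I53-47,11,36,22,2.34,2.95,0.080,0.23,3.36
I53-47,12,16,22,2.01,5.35,0.060,0.32,3.04
I53-47,13,31,25,1.83,2.91,0.094,0.27,3.15
I53-47,14,6,30,2.27,7.22,0.063,0.45,2.41
I53-47,15,3,35,1.18,16.82,0.048,0.81,1.49
I53-47,16,8,37,1.21,6.67,0.053,0.35,2.28
I53-47,17,3,37,2.16,13.80,0.059,0.81,1.52
I53-47,18,10,41,1.13,13.92,0.057,0.79,1.54
I53-47,19,8,44,0.31,11.78,0.038,0.45,2.00
MS2,20,50,0,0.07,0.18,0.038,0.01,6.88
MS2,21,38,42,0.47,0.52,0.106,0.05,4.94
MS2,22,58,54,0.19,1.07,0.241,0.26,2.95
MS2,23,44,57,0.07,1.83,0.074,0.13,3.49
MS2,24,52,77,0.47,1.31,0.072,0.09,3.96
MS2,25,61,86,0.55,2.67,0.042,0.11,3.72
MS2,26,57,93,0.38,2.04,0.051,0.10,3.88
MS2,27,54,98,0.27,3.82,0.033,0.12,3.49
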