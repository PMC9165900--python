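# Published precision statistics of the prEN 17658 international ring trial
# (main wash: conditions A water / B detergent / C detergent+bleach disinfectant;
#  rinse: D water / E 0.04% DDAC / F 0.4% DDAC).
# ratio_class is the class printed in the published report, which was derived
# from unrounded statistics and occasionally differs from the class implied by
# the rounded s_R/s_r columns; it is authoritative here.
cycle,condition,endpoint,mean,ci_low,ci_high,s_R,s_r,rsd_percent,ratio_class
main_wash,A,LR-PA,2.37,2.026,2.714,0.77,0.58,32.07,minor
main_wash,A,LR-EC,1.79,1.534,2.048,0.59,0.31,31.28,minor
main_wash,A,LR-SA,1.31,1.097,1.527,0.48,0.36,35.88,minor
main_wash,A,LR-EH,1.84,1.65,2.029,0.42,0.42,22.83,minor
main_wash,A,LR-CA,1.80,1.564,2.035,0.53,0.36,28.89,minor
main_wash,A,RI-TSA,3.35,3.275,3.418,0.23,0.20,5.69,minor
main_wash,A,RI-MEA,3.20,3.078,3.313,0.39,0.29,11.88,minor
main_wash,A,WW-TSA,4.58,4.378,4.775,0.61,0.26,12.88,clear
main_wash,A,WW-MEA,4.40,4.189,4.615,0.63,0.56,14.32,minor
main_wash,B,LR-PA,3.13,2.518,3.746,1.40,0.68,43.13,clear
main_wash,B,LR-EC,3.61,3.037,4.187,1.32,0.49,34.90,clear
main_wash,B,LR-SA,2.27,1.772,2.758,1.04,0.69,44.93,minor
main_wash,B,LR-EH,2.61,2.135,3.083,1.07,0.70,39.85,minor
main_wash,B,LR-CA,2.13,1.839,2.427,0.67,0.36,30.05,minor
main_wash,B,RI-TSA,2.95,2.751,3.139,0.65,0.32,22.45,clear
main_wash,B,RI-MEA,2.71,2.542,2.877,0.56,0.29,19.93,minor
main_wash,B,WW-TSA,3.29,3.11,3.469,0.41,0.19,11.85,clear
main_wash,B,WW-MEA,3.37,3.206,3.531,0.38,0.04,10.68,considerable
main_wash,C,LR-PA,5.51,5.238,5.779,0.61,0.64,10.71,minor
main_wash,C,LR-EC,4.91,4.615,5.204,0.68,0.24,13.27,clear
main_wash,C,LR-SA,5.05,4.829,5.273,0.51,0.13,9.70,clear
main_wash,C,LR-EH,4.85,4.541,5.162,0.71,0.43,13.20,minor
main_wash,C,LR-CA,2.97,2.633,3.315,0.76,0.65,24.92,minor
main_wash,C,RI-TSA,1.72,1.615,1.828,0.35,0.24,20.35,minor
main_wash,C,RI-MEA,1.76,1.637,1.886,0.41,0.31,22.73,minor
main_wash,C,WW-TSA,1.92,1.592,2.245,0.74,0.38,22.22,minor
main_wash,C,WW-MEA,2.31,2.013,2.615,0.68,0.40,28.57,minor
rinse,D,LR-PA,1.86,1.699,2.029,0.33,0.31,17.47,minor
rinse,D,LR-EC,1.50,1.267,1.736,0.48,0.39,31.33,minor
rinse,D,LR-SA,0.92,0.692,1.147,0.46,0.46,50.00,minor
rinse,D,LR-EH,1.38,1.182,1.576,0.40,0.38,28.99,minor
rinse,D,LR-CA,1.64,1.335,1.953,0.62,0.62,37.80,minor
rinse,D,RI-TSA,3.60,3.466,3.723,0.40,0.21,9.58,minor
rinse,D,RI-MEA,2.91,2.683,3.141,0.71,0.45,23.35,minor
rinse,D,WW-TSA,4.84,4.627,5.045,0.78,0.20,12.19,clear
rinse,D,WW-MEA,4.29,4.037,4.539,0.85,0.18,16.55,clear
rinse,E,LR-PA,2.63,2.189,3.07,0.91,0.71,33.84,minor
rinse,E,LR-EC,3.13,2.629,3.645,1.07,0.55,32.48,minor
rinse,E,LR-SA,3.06,2.533,3.589,1.12,0.44,34.64,clear
rinse,E,LR-EH,2.94,2.349,3.523,1.23,0.66,40.14,minor
rinse,E,LR-CA,3.14,2.661,3.624,1.00,0.73,30.89,minor
rinse,E,RI-TSA,2.02,1.789,2.246,0.70,0.50,31.22,minor
rinse,E,RI-MEA,1.88,1.68,2.071,0.60,0.41,30.85,clear
rinse,E,WW-TSA,1.45,1.154,1.748,0.60,0.57,41.35,clear
rinse,E,WW-MEA,1.38,1.086,1.672,0.60,0.54,42.75,clear
rinse,F,LR-PA,5.16,4.729,5.595,0.78,0.78,15.12,minor
rinse,F,LR-EC,5.06,4.738,5.376,0.58,0.58,11.46,minor
rinse,F,LR-SA,5.11,4.605,5.619,0.91,0.91,17.81,minor
rinse,F,LR-EH,5.00,4.482,5.514,0.94,0.87,18.60,minor
rinse,F,LR-CA,4.27,4.001,4.539,0.49,0.49,11.48,minor
rinse,F,RI-TSA,1.61,1.527,1.695,0.23,0.19,15.53,minor
rinse,F,RI-MEA,1.55,1.533,1.56,0.04,0.04,2.59,minor
rinse,F,WW-TSA,1.15,1.15,1.15,0.00,0.00,0.00,minor
rinse,F,WW-MEA,1.15,1.15,1.15,0.00,0.00,0.00,minor
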