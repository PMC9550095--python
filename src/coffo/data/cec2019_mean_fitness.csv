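problem,EHOI,EHO,SCA,SSA,GOA,WOA,BBO,MFO,PSO,COPSO,FFO,COFFO
CEC1,4.76e4,1.35e7,9.83e9,3.21e9,1.61e10,1.03e10,3.52e10,7.17e9,6.75e11,4.17e10,1.46e3,1.19e2
CEC2,1.70e1,1.72e1,1.75e1,1.73e1,1.74e1,1.73e1,8.87e1,1.74e1,8.56e1,1.64e2,2.79e0,2.43e0
CEC3,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,9.71e0,5.29e0
CEC4,1.28e1,1.55e1,8.32e2,3.25e1,1.51e2,2.65e2,6.95e1,1.38e2,6.92e1,2.83e1,3.99e0,1.00e0
CEC5,1.05e0,1.07e0,2.23e0,1.35e0,1.33e0,1.67e0,1.31e0,1.13e0,1.55e0,1.33e0,1.02e0,1.00e0
CEC6,8.334e0,9.45e0,1.04e1,3.79e0,6.19e0,9.14e0,5.78e0,4.92e0,1.03e1,6.56e0,1.61e0,1.87e0
CEC7,1.42e2,1.81e2,6.38e2,2.89e2,2.87e2,4.53e2,4.92e0,3.19e2,6.97e2,3.93e2,5.91e0,2.33e0
CEC8,2.69e0,3.15e0,5.77e0,5.08e0,5.49e0,5.75e0,4.81e0,5.45e0,5.10e0,5.22e0,1.15e0,1.02e0
CEC9,2.29e0,2.41e0,9.75e1,2.38e0,2.45e0,5.16e0,3.75e0,2.46e0,2.65e0,2.54e0,3.91e0,2.15e0
CEC10,1.92e1,2.11e1,2.08e1,2.03e1,2.00e1,2.05e1,2.07e1,2.02e1,2.06e1,2.06e1,2.10e1,1.95e1
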