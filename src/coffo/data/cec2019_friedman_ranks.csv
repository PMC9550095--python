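problem,EHOI,EHO,SCA,SSA,GOA,WOA,BBO,MFO,PSO,COPSO,FFO,COFFO
CEC1,3,4,7,5,9,8,10,6,12,11,2,1
CEC2,3,4,9,5.5,7.5,5.5,10,7.5,12,11,2,1
CEC3,7.5,7.5,7.5,7.5,7.5,7.5,7.5,7.5,7.5,7.5,2,1
CEC4,3,4,12,6,10,11,8,9,7,5,2,1
CEC5,3,4,12,9,7.5,11,6,5,10,7.5,2,1
CEC6,8,10,12,3,6,9,5,4,11,7,1,2
CEC7,4,5,12,7,6,10,2,8,11,9,3,1
CEC8,3,4,12,6,10,11,5,9,7,8,2,1
CEC9,2,4,12,3,5,11,9,6,8,7,10,1
CEC10,1,12,10,5,3,6,9,4,7.5,7.5,11,2
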