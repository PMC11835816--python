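cultivar,treatment,daw,variable,mean,se,n
Z/B,WW,1,A,13.63,1.43,4
Z/D,WW,1,A,10.05,1.52,4
Z/H,WW,1,A,12.58,1.10,4
Z/B,WL,1,A,8.25,0.72,4
Z/D,WL,1,A,7.72,0.71,4
Z/H,WL,1,A,8.63,1.49,4
Z/B,WW,2,A,12.79,1.46,4
Z/D,WW,2,A,13.41,1.55,4
Z/H,WW,2,A,14.69,1.28,4
Z/B,WL,2,A,11.61,1.09,4
Z/D,WL,2,A,5.32,0.94,4
Z/H,WL,2,A,7.46,1.25,4
Z/B,WW,3,A,14.25,1.62,4
Z/D,WW,3,A,15.48,1.50,4
Z/H,WW,3,A,13.61,0.82,4
Z/B,WL,3,A,15.12,0.64,4
Z/D,WL,3,A,3.96,0.76,4
Z/H,WL,3,A,6.17,0.69,4
Z/B,WW,4,A,14.04,1.60,4
Z/D,WW,4,A,11.62,0.94,4
Z/H,WW,4,A,11.99,1.36,4
Z/B,WL,4,A,11.95,2.30,4
Z/D,WL,4,A,1.30,0.64,4
Z/H,WL,4,A,5.71,0.85,4
Z/B,WW,1,WUEi,62.28,4.79,4
Z/D,WW,1,WUEi,81.86,2.20,4
Z/H,WW,1,WUEi,76.50,4.66,4
Z/B,WL,1,WUEi,77.40,6.11,4
Z/D,WL,1,WUEi,93.68,3.48,4
Z/H,WL,1,WUEi,92.76,4.62,4
Z/B,WW,2,WUEi,90.81,24.91,4
Z/D,WW,2,WUEi,80.51,4.45,4
Z/H,WW,2,WUEi,65.96,6.12,4
Z/B,WL,2,WUEi,62.06,3.84,4
Z/D,WL,2,WUEi,109.06,7.69,4
Z/H,WL,2,WUEi,113.08,14.62,4
Z/B,WW,3,WUEi,60.52,3.04,4
Z/D,WW,3,WUEi,68.06,7.85,4
Z/H,WW,3,WUEi,64.10,7.53,4
Z/B,WL,3,WUEi,58.22,3.29,4
Z/D,WL,3,WUEi,95.65,8.56,4
Z/H,WL,3,WUEi,87.95,11.03,4
Z/B,WW,4,WUEi,62.29,5.90,4
Z/D,WW,4,WUEi,82.94,5.88,4
Z/H,WW,4,WUEi,79.21,5.87,4
Z/B,WL,4,WUEi,74.60,7.48,4
Z/D,WL,4,WUEi,50.23,14.68,4
Z/H,WL,4,WUEi,102.00,7.66,4
Z/B,WW,1,Ci,284.96,6.14,4
Z/D,WW,1,Ci,259.02,4.54,4
Z/H,WW,1,Ci,263.45,7.92,4
Z/B,WL,1,Ci,267.84,9.27,4
Z/D,WL,1,Ci,241.47,6.39,4
Z/H,WL,1,Ci,243.04,5.59,4
Z/B,WW,2,Ci,245.23,38.35,4
Z/D,WW,2,Ci,260.34,6.63,4
Z/H,WW,2,Ci,281.11,9.18,4
Z/B,WL,2,Ci,285.92,7.35,4
Z/D,WL,2,Ci,225.25,13.02,4
Z/H,WL,2,Ci,216.29,22.48,4
Z/B,WW,3,Ci,293.59,4.27,4
Z/D,WW,3,Ci,277.18,10.75,4
Z/H,WW,3,Ci,285.97,12.12,4
Z/B,WL,3,Ci,293.78,5.13,4
Z/D,WL,3,Ci,256.50,10.89,4
Z/H,WL,3,Ci,254.25,15.28,4
Z/B,WW,4,Ci,284.13,8.31,4
Z/D,WW,4,Ci,253.97,8.15,4
Z/H,WW,4,Ci,259.44,8.19,4
Z/B,WL,4,Ci,266.88,9.81,4
Z/D,WL,4,Ci,315.88,23.51,4
Z/H,WL,4,Ci,230.97,11.83,4
Z/B,WW,1,Tleaf,32.10,0.27,4
Z/D,WW,1,Tleaf,32.29,0.13,4
Z/H,WW,1,Tleaf,32.39,0.14,4
Z/B,WL,1,Tleaf,32.44,0.25,4
Z/D,WL,1,Tleaf,32.79,0.09,4
Z/H,WL,1,Tleaf,32.52,0.14,4
Z/B,WW,2,Tleaf,31.66,0.11,4
Z/D,WW,2,Tleaf,31.90,0.07,4
Z/H,WW,2,Tleaf,31.88,0.25,4
Z/B,WL,2,Tleaf,31.30,0.14,4
Z/D,WL,2,Tleaf,32.57,0.20,4
Z/H,WL,2,Tleaf,32.46,0.14,4
Z/B,WW,3,Tleaf,31.57,0.16,4
Z/D,WW,3,Tleaf,31.93,0.23,4
Z/H,WW,3,Tleaf,31.87,0.11,4
Z/B,WL,3,Tleaf,31.69,0.08,4
Z/D,WL,3,Tleaf,33.17,0.35,4
Z/H,WL,3,Tleaf,32.56,0.18,4
Z/B,WW,4,Tleaf,32.01,0.18,4
Z/D,WW,4,Tleaf,32.43,0.10,4
Z/H,WW,4,Tleaf,32.65,0.16,4
Z/B,WL,4,Tleaf,32.31,0.17,4
Z/D,WL,4,Tleaf,33.82,0.25,4
Z/H,WL,4,Tleaf,33.19,0.18,4
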