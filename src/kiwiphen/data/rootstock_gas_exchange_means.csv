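cultivar,treatment,daw,variable,mean,se,n
B,WW,1,A,10.55,0.34,4
D,WW,1,A,8.46,0.56,4
H,WW,1,A,10.09,1.19,4
B,WL,1,A,8.01,1.45,4
D,WL,1,A,7.03,1.72,4
H,WL,1,A,8.43,1.31,4
B,WW,2,A,9.73,1.03,4
D,WW,2,A,9.47,1.23,4
H,WW,2,A,7.96,0.73,4
B,WL,2,A,11.44,1.78,4
D,WL,2,A,4.65,0.89,4
H,WL,2,A,6.14,1.37,4
B,WW,3,A,9.76,1.10,4
D,WW,3,A,9.51,0.38,4
H,WW,3,A,9.38,1.04,4
B,WL,3,A,10.67,0.76,4
D,WL,3,A,7.64,0.84,4
H,WL,3,A,5.29,1.60,4
B,WW,4,A,11.43,1.26,4
D,WW,4,A,8.58,1.12,4
H,WW,4,A,8.48,0.40,4
B,WL,4,A,11.78,1.16,4
D,WL,4,A,3.16,0.59,4
H,WL,4,A,4.48,0.85,4
B,WW,1,WUEi,79.44,2.06,4
D,WW,1,WUEi,85.69,6.39,4
H,WW,1,WUEi,81.04,7.90,4
B,WL,1,WUEi,74.43,3.05,4
D,WL,1,WUEi,92.93,3.86,4
H,WL,1,WUEi,90.58,5.04,4
B,WW,2,WUEi,75.69,6.54,4
D,WW,2,WUEi,80.46,3.69,4
H,WW,2,WUEi,74.02,7.51,4
B,WL,2,WUEi,63.03,3.56,4
D,WL,2,WUEi,86.82,7.61,4
H,WL,2,WUEi,74.74,6.81,4
B,WW,3,WUEi,72.12,7.40,4
D,WW,3,WUEi,81.34,2.74,4
H,WW,3,WUEi,78.43,4.39,4
B,WL,3,WUEi,61.81,1.64,4
D,WL,3,WUEi,93.46,8.33,4
H,WL,3,WUEi,66.10,6.15,4
B,WW,4,WUEi,70.84,6.87,4
D,WW,4,WUEi,91.73,3.97,4
H,WW,4,WUEi,85.18,3.42,4
B,WL,4,WUEi,70.00,3.57,4
D,WL,4,WUEi,89.24,7.97,4
H,WL,4,WUEi,82.52,6.87,4
B,WW,1,Ci,260.92,3.56,4
D,WW,1,Ci,253.60,9.44,4
H,WW,1,Ci,258.74,13.26,4
B,WL,1,Ci,271.91,3.75,4
D,WL,1,Ci,243.81,4.20,4
H,WL,1,Ci,245.61,8.14,4
B,WW,2,Ci,272.33,9.54,4
D,WW,2,Ci,264.71,5.02,4
H,WW,2,Ci,277.02,12.44,4
B,WL,2,Ci,289.96,4.96,4
D,WL,2,Ci,260.60,13.06,4
H,WL,2,Ci,278.00,12.05,4
B,WW,3,Ci,277.25,10.72,4
D,WW,3,Ci,262.75,4.66,4
H,WW,3,Ci,267.71,7.82,4
B,WL,3,Ci,292.33,1.83,4
D,WL,3,Ci,245.65,12.69,4
H,WL,3,Ci,292.35,10.33,4
B,WW,4,Ci,272.39,9.82,4
D,WW,4,Ci,242.75,6.09,4
H,WW,4,Ci,253.49,5.45,4
B,WL,4,Ci,288.45,6.15,4
D,WL,4,Ci,252.79,13.08,4
H,WL,4,Ci,262.44,11.35,4
B,WW,1,Tleaf,32.45,0.03,4
D,WW,1,Tleaf,32.88,0.13,4
H,WW,1,Tleaf,32.59,0.07,4
B,WL,1,Tleaf,32.61,0.21,4
D,WL,1,Tleaf,33.03,0.11,4
H,WL,1,Tleaf,32.91,0.18,4
B,WW,2,Tleaf,32.34,0.09,4
D,WW,2,Tleaf,32.59,0.17,4
H,WW,2,Tleaf,32.48,0.18,4
B,WL,2,Tleaf,32.24,0.18,4
D,WL,2,Tleaf,33.07,0.16,4
H,WL,2,Tleaf,32.73,0.21,4
B,WW,3,Tleaf,32.50,0.09,4
D,WW,3,Tleaf,32.65,0.21,4
H,WW,3,Tleaf,32.47,0.09,4
B,WL,3,Tleaf,32.41,0.05,4
D,WL,3,Tleaf,32.93,0.04,4
H,WL,3,Tleaf,32.41,0.24,4
B,WW,4,Tleaf,33.06,0.12,4
D,WW,4,Tleaf,33.74,0.19,4
H,WW,4,Tleaf,33.46,0.08,4
B,WL,4,Tleaf,32.98,0.07,4
D,WL,4,Tleaf,34.31,0.08,4
H,WL,4,Tleaf,33.77,0.17,4
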