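table,metric,class,printed
arrhythmia,acc,,98.57
arrhythmia,se,A,95.09
arrhythmia,se,L,98.54
arrhythmia,se,N,99.34
arrhythmia,se,R,98.08
arrhythmia,se,V,98.85
arrhythmia,pr,A,96.16
arrhythmia,pr,L,96.71
arrhythmia,pr,N,99.66
arrhythmia,pr,R,97.46
arrhythmia,pr,V,97.74
supraventricular,acc,,97.59
supraventricular,se,A,89.55
supraventricular,se,L,94.87
supraventricular,se,N,99.17
supraventricular,se,R,92.32
supraventricular,se,V,93.64
supraventricular,pr,A,91.60
supraventricular,pr,L,92.43
supraventricular,pr,N,98.97
supraventricular,pr,R,97.15
supraventricular,pr,V,92.43
no_preprocessing,acc,,90.83
no_preprocessing,se,A,61.96
no_preprocessing,se,L,75.36
no_preprocessing,se,N,96.75
no_preprocessing,se,R,74.58
no_preprocessing,se,V,82.87
no_preprocessing,pr,A,65.27
no_preprocessing,pr,L,73.86
no_preprocessing,pr,N,94.16
no_preprocessing,pr,R,92.02
no_preprocessing,pr,V,85.67
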