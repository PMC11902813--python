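true,A,L,N,R,V
A,171,26,28,23,14
L,32,517,98,32,21
N,58,121,5932,129,60
R,7,8,20,581,15
V,8,14,53,14,532
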