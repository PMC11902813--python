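true,A,L,N,R,V
A,252,1,8,0,1
L,5,677,14,4,0
N,5,5,6279,6,5
R,2,3,10,615,1
V,1,1,10,2,607
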