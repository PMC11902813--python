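true,A,L,N,R,V
A,240,5,5,8,4
L,10,647,20,13,10
N,7,18,6235,20,20
R,5,4,4,613,5
V,6,8,23,10,574
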