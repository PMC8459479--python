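residue,ges_score,increment,midi_pitch
F,-3.7,0.0,50
M,-3.4,0.3,51
I,-3.1,0.3,52
L,-2.8,0.3,53
V,-2.6,0.2,54
C,-2.0,0.6,55
W,-1.9,0.1,56
A,-1.6,0.3,57
T,-1.2,0.4,58
G,-1.0,0.2,59
S,-0.6,0.4,60
P,0.2,0.8,61
Y,0.7,0.5,62
H,3.0,2.3,65
Q,4.1,1.1,66
N,4.8,0.7,67
E,8.2,3.4,71
K,8.8,0.6,72
D,9.2,0.4,73
R,12.3,3.1,77
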