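# Side-chain pKa values of the ionizable amino acids and the sign of the
# charge the group carries when protonated(+1) / deprotonated(-1).
resname,pka,charge_sign
ASP,3.65,-1
GLU,4.25,-1
CYS,8.50,-1
TYR,10.07,-1
LYS,10.53,1
ARG,12.50,1
HIS,6.00,1
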