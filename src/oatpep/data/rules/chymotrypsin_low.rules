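# Chymotrypsin, low specificity (PeptideCutter): adds L, M and H to the P1 set
# with their blocking residues at P1'.
NAME chymotrypsin_low
RULE P1={F,L,Y} P1'=!{P}
RULE P1={W} P1'=!{M,P}
RULE P1={M} P1'=!{P,Y}
RULE P1={H} P1'=!{D,M,P,W}
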