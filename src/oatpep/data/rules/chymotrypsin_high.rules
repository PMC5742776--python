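# Chymotrypsin, high specificity (PeptideCutter): F/Y not before P; W not
# before M or P.
NAME chymotrypsin_high
RULE P1={F,Y} P1'=!{P}
RULE P1={W} P1'=!{M,P}
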