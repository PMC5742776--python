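# Pepsin at pH > 2: as the pH 1.3 table with the P1/P1' preference extended to
# Trp and Tyr.
NAME pepsin_ph2
RULE P1={F,L,W,Y} P1'=!{P}
RULE P1=!{P,H} P1'={F,L,W,Y}
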