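# Trypsin, per the ExPASy PeptideCutter convention: cleaves C-terminal to K/R
# unless P1' is proline, with the Keil positive exceptions W-K|P and M-R|P.
NAME trypsin
RULE P1={K,R} P1'=!{P}
RULE P2={W} P1={K} P1'={P}
RULE P2={M} P1={R} P1'={P}
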