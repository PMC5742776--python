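# Pepsin at pH 1.3, Keil-style P1/P1' preference: cleaves bonds with Phe or Leu
# on either side of the scissile bond; proline at P1' and proline/histidine at
# P1 block cleavage.
NAME pepsin_ph1_3
RULE P1={F,L} P1'=!{P}
RULE P1=!{P,H} P1'={F,L}
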