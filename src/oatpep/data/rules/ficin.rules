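# Ficin (EC 3.4.22.3) release specificity table.
# Like papain.rules this is a CALIBRATED STARTING POINT, not a literature table:
# ficin's positional preferences are broad and the digestion service's exact
# table is not public.  Re-check edits with `oatpep validate-rules`.
NAME ficin
RULE P2={F} P1={L} P1'={A}
RULE P2={L} P1={I} P1'={F}
RULE P1={E,L,R} P1'={F,Q,R}
RULE P1={A,G,K,M,Q,V} P1'={F,G,I,L,M,Q}
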