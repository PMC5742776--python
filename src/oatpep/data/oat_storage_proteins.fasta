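>Q38780|globulin_11S 11S globulin
MATTSFPSMLFYFCIFLLFHGSMAQLFGQSSTPWQSSRQGGLRGCRFDRLQAFEPLRQVR
SQAGITEYFDEQNEQFRCTGVSVIRRVIEPQGLVLPQYHNAPALVYILQGRGFTGLTFPG
CPATFQQQFQPFDQSQFAQGQRQSQTIKDEHQRVQRFKQGDVVALPAGIVHWCYNDGDAP
IVAIYVFDVNNNANQLEPRQKEFLLAGNNKREQQSGNNIFSGLSVQLLSEALGISQQAAQ
RIQSQNDQRGEIIRVSQGLQFLKPIVSQQVPGEQQVYQPIQTQEGQATQYQVGQSTQYQV
GKSTPYQGGQSSQYQAGQSWDQSFNGLEENFCSLEARKNIENPQHADTYNPRAGRITRLN
SKNFPILNIVQMSATRVNLYQNAILSPFWNINAHSVIYMIQGHARVQVVNNNGQTVFNDI
LRRGQLLIVPQHFVVLKKAEREGCQYISFKTNPNSMVSHIAGKSSILRALPIDVLANAYR
ISRQEARNLKNNRGEEFGAFTPKLTQKGFQSYQDIEEGSSSPVRASE
>P12615|globulin_12S 12S globulin
MATTRFPSLLFYSCIFLLCNGSMAQLFGQSFTPWQSSRQGGLRGCKFDRLQAFEPLRQVR
SQAGITEYFDEQNEQFRCAGVSVIRRVIEPQGLLLPQYHNAPGLVYILQGRGFTGLTFPG
CPATFQQQFQQFDQARFAQGQSKSQNLKDEHQRVHHIKQGDVVALPAGIVHWCYNDGDAP
IVAVYVFDVNNNANQLEPRQKEFLLAGNNKREQQFGQNIFSGFSVQLLSEALGISQQAAQ
KIQSQNDQRGEIIRVSQGLQFLKPFVSQQGPVEHQAYQPIQSQQEQSTQYQVGQSPQYQE
GQSTQYQSGQSWDQSFNGLEENFCSLEARQNIENPKRADTYNPRAGRITHLNSKNFPTLN
LVQMSATRVNLYQNAILSPYWNINAHSVMHMIQGRARVQVVNNHGQTVFNDILRRGQLLI
IPQHYVVLKKAEREGCQYISFKTTPNSMVSYIAGKTSILRALPVDVLANAYRISRQESQN
LKNNRGEEFGAFTPKFAQTGSQSYQDEGESSSTEKASE
>P80356|avenin_3 Avenin-3
MKTFLIFALLAMAATMATAQFDPSEQYQPYPEQQQPILQQQQMLLQQQQQMLLQQQPLLQ
VLQQQLNPCRQFLVQQCSPVAVVPFLRSQILQQSSCQVMRQQCCRQLEQIPEQLRCPAIH
SVVQAIIMQQQQFFQPQMQQQFFQPQMQQVTQGIFQPQMQQVTQGIFQPQLQQVTQGIFQ
PQMQGQIEGMRAFALQALPAMCDVYVPPHCPVATAPLGGF
>Q09114|avenin_E Avenin-E
TTTVQYNPSEQYQPYPEQQEPFVQQQPFVQQQQQPFVQQQQMFLQPLLQQQLNPCKQFLV
QQCSPVAVVPFLRSQILRQAICQVARQQCCRQLAQIPEQLRCPAIHSVVQAIILQQQQQQ
QFFQPQLQQQVFQPQLQQVFNQPQQQAQFEGMRAFALQALPAMCDVYVPPQCPVATAPLG
GF
>Q09097|avenin_F Avenin-F
TTTVQYDPSEQYQPYPEQQEPFVQQQPPFVQQQQPFVQQQEPF
>Q09095|avenin_A Avenin-A
PSEQYQPYPEQQQPFLQQQPLELQQQQXXLVLFLQK
>P27919|avenin Avenin
MKIFFFLALLALVVSATFAQYAESDGSYEEVEGSHDRCQQHQMKLDSCREYVAERCTTMR
DFPITWPWKWWKGGCEELRNECCQLLGQMPSECRCDAIWRSIQRELGGFFGTQQGLIGKR
LKIAKSLPTQSTWALSAISPNSMVSHIAGKSSILRALPVDVLANAYRISRQEARNLKNNR
GQESGVFTPKFTQTSFQPYPEGEDESSLINKASE
>A7U440|tryptophanin Tryptophanin/2S albumin
MKALFLLAFLALAASAAFAQQYADTGVGGWDGCMPEKARLNSCKDYVVERCLTLKDIPIT
WPWKWWKGGCESEVRSQCCMELNQIAPHCRCKAIWRAVQGELGGFLGFQQSEIMKQVHVA
QSLPSRCNMGPNCNFPTNLGYY
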