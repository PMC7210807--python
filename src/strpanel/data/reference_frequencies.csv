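# Reference captive tiger population (n = 31 unrelated individuals, 62 chromosomes per locus).
# count: chromosomes carrying the allele, reconstructed as round(frequency x 62);
# frequency: published 4-decimal rounding of count/62.
locus,allele,count,frequency
DA3S1123,11.2,13,0.2097
DA3S1123,12.2,16,0.2581
DA3S1123,13.2,26,0.4194
DA3S1123,14.2,1,0.0161
DA3S1123,15.2,6,0.0968
DA2S1059,8,27,0.4355
DA2S1059,9,19,0.3065
DA2S1059,10,9,0.1452
DA2S1059,11,2,0.0323
DA2S1059,12,5,0.0806
DB1S1259,18.1,3,0.0484
DB1S1259,19.2,8,0.1290
DB1S1259,20.1,9,0.1452
DB1S1259,20.2,5,0.0806
DB1S1259,21.1,7,0.1129
DB1S1259,22.1,10,0.1613
DB1S1259,22.2,3,0.0484
DB1S1259,23.2,2,0.0323
DB1S1259,25.1,3,0.0484
DB1S1259,25.3,6,0.0968
DB1S1259,26.3,6,0.0968
DD3S86,13,2,0.0323
DD3S86,14,28,0.4516
DD3S86,15,3,0.0484
DD3S86,16,5,0.0806
DD3S86,17,13,0.2097
DD3S86,18,6,0.0968
DD3S86,19,5,0.0806
DE1S613,11,6,0.0968
DE1S613,12,1,0.0161
DE1S613,13.2,10,0.1613
DE1S613,14.2,1,0.0161
DE1S613,14.3,7,0.1129
DE1S613,15.2,1,0.0161
DE1S613,15.3,5,0.0806
DE1S613,16.2,2,0.0323
DE1S613,17,1,0.0161
DE1S613,18,11,0.1774
DE1S613,19.1,17,0.2741
DF1S579,9.1,12,0.1935
DF1S579,11.1,7,0.1129
DF1S579,12.1,11,0.1774
DF1S579,13.1,7,0.1129
DF1S579,14.1,6,0.0968
DF1S579,15,10,0.1613
DF1S579,16,2,0.0323
DF1S579,17,4,0.0645
DF1S579,18,3,0.0484
DA2S1575,7.1,1,0.0161
DA2S1575,8.1,12,0.1935
DA2S1575,9.1,5,0.0806
DA2S1575,10,10,0.1613
DA2S1575,11,6,0.0968
DA2S1575,12,19,0.3065
DA2S1575,13,7,0.1129
DA2S1575,14,2,0.0323
DF2S497,10,28,0.4516
DF2S497,11,17,0.2742
DF2S497,12,10,0.1613
DF2S497,13,6,0.0968
DF2S497,14,1,0.0161
DA3S1145,15,14,0.2258
DA3S1145,16,21,0.3387
DA3S1145,17,13,0.2097
DA3S1145,18,5,0.0806
DA3S1145,19,9,0.1452
DD2S793,9,10,0.1613
DD2S793,10,20,0.3226
DD2S793,11,14,0.2258
DD2S793,12,4,0.0645
DD2S793,13,14,0.2258
DD4S705,17.3,8,0.1290
DD4S705,18,9,0.1452
DD4S705,18.2,4,0.0645
DD4S705,19.2,4,0.0645
DD4S705,19.3,12,0.1935
DD4S705,20.2,4,0.0645
DD4S705,20.3,9,0.1452
DD4S705,22,6,0.0968
DD4S705,22.2,1,0.0161
DD4S705,22.3,2,0.0323
DD4S705,24.3,3,0.0484
DB1S542,11,1,0.0161
DB1S542,12,27,0.4355
DB1S542,13,1,0.0161
DB1S542,14,17,0.2742
DB1S542,15,10,0.1613
DB1S542,16,6,0.0968
DA1S1290,7,5,0.0806
DA1S1290,10,11,0.1774
DA1S1290,11,4,0.0645
DA1S1290,12,12,0.1935
DA1S1290,13,15,0.2419
DA1S1290,14,7,0.1129
DA1S1290,15,8,0.1290
DA1S1470,9,21,0.3387
DA1S1470,10,14,0.2258
DA1S1470,11,1,0.0161
DA1S1470,12,3,0.0484
DA1S1470,13,8,0.1290
DA1S1470,14,11,0.1774
DA1S1470,15,4,0.0645
DC1S1364,12.2,10,0.1613
DC1S1364,13.2,4,0.0645
DC1S1364,14,1,0.0161
DC1S1364,14.2,1,0.0161
DC1S1364,15.2,13,0.2097
DC1S1364,16.2,24,0.3871
DC1S1364,17.2,7,0.1129
DC1S1364,18.2,2,0.0323
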