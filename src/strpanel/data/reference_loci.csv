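# Panel marker metadata for the 15-locus reference captive tiger panel.
name,motif,scaffold,position,size_min,size_max
DA3S1123,AAAAC,scaffold94140,28202,206,276
DA2S1059,AGAT,scaffold67413,66413,332,380
DB1S1259,AAAG,scaffold87533,4877,388,448
DD3S86,AAAG,scaffold62023,14317,157,205
DE1S613,AAGG,scaffold91793,6047,222,270
DF1S579,AAAG,scaffold79,17437,307,355
DA2S1575,AAAAG,scaffold88063,10431,368,428
DF2S497,AAAG,scaffold72035,19788,132,178
DA3S1145,AAAG,scaffold74228,13337,215,263
DD2S793,AGAT,scaffold140970,2179,317,365
DD4S705,AAAG,scaffold96585,34146,377,425
DB1S542,AAGG,scaffold96253,30364,159,207
DA1S1290,AAAG,scaffold89346,24116,212,272
DA1S1470,AAAG,scaffold74155,15379,314,362
DC1S1364,AAAG,scaffold80644,19735,378,426
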