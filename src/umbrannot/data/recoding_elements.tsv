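virus	group	slippery_raw	pk1_pair	pk2_pair	ca_placement
CMoV	UV	*GGAUUUU*UGCUAG	ACGC-GCGU	None	In HC
PasUV	UV	*GGAUUUU*UGCUAG	AUACCA-UGGUAU	None	In HC
WCMoV	UV	*GGAUUUU*UGCUAG	None	CUCGU-ACGAG	HC base
CMoMV	UV	*GGAUUUU*UGCUAG	AGAUU-AAUCU	None	In HC
CUV	UV	*GGAUUUU*UGCUAG	None	CUCG-CGAG	HC base
PicUV	UV	*GGGUUUU*CUGCUAG	CCCAA-UUGGG	CUCGU-ACGAG	HC base
IxYMoV2	UV	*GGGUUUU*UGCUAG	CCCCA-UGGGG	None	HC base
PMMoV	UV	*GGGUUUU*UGCUAG	CGAUG-CAUCG	AACA-UUGU	HC base
WSVA	UV	*GGAUUUU*UGCUAG	GACGC-GCGUC	UCGUU-AACGA	HC base
PEMV2	UV	*GGAUUUU*UGGUAG	CCAAA-UUUGG	CCUAGC-GCUAGG	HC base
RCUV	UV	*GGAUUUU*UGGUAG	CCAAA-UUUGG	CCUGGC-GCCAGG	HC base
CJUV	UV	*GGGUUUU*CACUAG	ACCA-UGGU	None	HC base
ETBTV	UV	*AAAUUUU* UAG	UGUGGAC-GUCCACA	CUCAUU-AAUGAG	HC base
GRV	UV	*AAAUUUU* UAG	UGUGGAC-GUCCACA	CUCAUU-AAUGAG	HC base
PaeUV	UV	*GGAUUUU* UGA	AUUGAUGC-GCAUCAAU	None	HC base
OPMV	UV	*GGAUUUU* UAA	AUCG-GCAU	UCAUUA-UAAUGA	HC base
TBTV	UV	*GGAUUUU*UGCUAG	CCAAA-UUUGG	None	HC base
AgULV	Group1	*GGGUUUU* UGA	None	None	HC base
ArULV	Group1	*GGGUUUU*CGGUAA	AUGCAC-GUGCAU	UUGC-GCAA	None
PaULV1	Group1	*GGAUUUU* UAA	CCAUAG-CUAUGG	UUGCG-CGCAA	HC base
SgULV1	Group1	*GGGUUUU*CGGUAG	GCCAUA-UAUGGC	None	HC base
GULV2	Group1	*GGGAAAC* UAA	UGUGG-CCACA	None	None
GULV3	Group1	*GGGUUUU* UAG	GUUGUG-CACAAC	None	HC base
GULV4	Group1	*GGGUUUC* UAG	UGUGG-CCACA	None	HC base?
GULV5	Group1	*GGGUUUC* UAG	UGUGG-CCACA	None	HC base?
CY1	Group2	*GGGUUUU*CGCGAUUUGCAGUGA	None	None	None
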