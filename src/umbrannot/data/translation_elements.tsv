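virus	group	psi1	tss	cite_type	ldi_pair	cas	cas_kl	entry_status
CMoV	UV	yes	yes	UTE	GAUCA-UGAUC	yes	no	FL
PasUV	UV	yes	yes	UTE	GAUCA-UGAUC	yes	yes	FL
WCMoV	UV	yes	no	UTE	CUCUGG-CCAGAG	yes	no	FL
CMoMV	UV	yes	no	UTE-like	UAACCAG-CUGGUUA	yes	no	FL
CUV	UV	yes	no	UTE	UCACC-GGUGA	yes	no	FL
PicUV	UV	?	yes	BTE-B	UGAC-GUCA	yes	yes	FL
IxYMoV2	UV	?	?	BTE-B	?	yes	yes	FL
PMMoV	UV	yes	yes	BTE-B	UGACU-AGUCA	yes	yes	FL
WSVA	UV	yes	yes	BTE-B	GACUA-UAGUC	yes	yes	FL
PEMV2	UV	yes	yes	KL-TSS+PTE	UGGCGA-UCGCCA	yes	yes	FL
RCUV	UV	yes	yes	New-unique	UGGCG-CGCCA	yes	yes	PS
CJUV	UV	yes	yes	UTE	UGGCA-UGCCA	yes	yes	PS
ETBTV	UV	yes	yes	BTE-A	UCAACA-UGUUGA	yes	yes	FL
GRV	UV	yes	yes	BTE-A	GUUCA-UGAAC	yes	yes	FL
PaeUV	UV	yes	yes	BTE-A	GCCAAC-GUUGGC	yes	yes	FL
OPMV	UV	yes	yes	BTE-A	UGGCA-UGCCA	yes	yes	FL
TBTV	UV	yes	yes	BTE-A	GGUUA-UAACC	yes	yes	FL
AgULV	Group1	yes	yes	ISS	GGCCAA-UUGGCC	yes	yes	FL
ArULV	Group1	yes	no	New-unique	?	yes	yes	FL
PaULV1	Group1	yes	no	ISS	GGGCCAG-CUGGCCC	no	no	PS
SgULV1	Group1	yes	no	ISS	GCCAA-UUGGC	no	no	FL
GULV2	Group1	?	no	ISS	UGGCAGC-GCUGCCA	no	no	FL
GULV3	Group1	?	no	ISS	UUGGCUA-UAGCCAA	no	no	FL
GULV4	Group1	yes	no	ISS	UGGCGA-UCGCCA	no	no	FL
GULV5	Group1	?	no	ISS	UUGGCU-AGCCAA	no	no	PS
CY1	Group2	yes	no	ISS-like	?	no	no	FL
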