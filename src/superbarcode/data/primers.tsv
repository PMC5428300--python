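# Barcode primer pairs used for marker excision.
# rbcLa-F/rbcLa-R, matK-xf/matK-MALP, ITS1/ITS4 as printed in the study's methods.
# trnHf_05 (Tate & Simpson 2003) and psbA3_f (Sang, Crawford & Stuessy 1997) are
# EXTERNALLY SOURCED from the cited primer literature (not printed in the study);
# override via --primers with your own table if needed.
marker	name	sequence	orientation
rbcL	rbcLa-F	ATGTCACCACAAACAGAGACTAAAGC	forward
rbcL	rbcLa-R	GTAAAATCAAGTCCACCRCG	reverse
matK	matK-xf	TAATTTACGATCAATTCATTC	forward
matK	matK-MALP	ACAAGAAAGTCGAAGTAT	reverse
trnH-psbA	trnHf_05	CGCGCATGGTGGATTCACAATCC	forward
trnH-psbA	psbA3_f	GTTATGCATGAACGTAATGCTC	reverse
ITS	ITS1	TCCGTAGGTGAACCTGCGG	forward
ITS	ITS4	TCCTCCGCTTATTGATATGC	reverse
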