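symbol	mark	role	txn
KMT2A	H3K4	writer	act
KMT2B	H3K4	writer	act
KMT2F	H3K4	writer	act
KMT2G	H3K4	writer	act
KMT3C	H3K4	writer	act
KMT3E	H3K4	writer	act
PRDM9	H3K4	writer	act
SETMAR	H3K4	writer	act
KDM1A	H3K4	eraser	rep
KDM5A	H3K4	eraser	rep
KDM5B	H3K4	eraser	rep
KDM5C	H3K4	eraser	rep
KMT1C	H3K9	writer	rep
KMT1D	H3K9	writer	rep
KMT1E	H3K9	writer	rep
KMT6A	H3K9	writer	rep
KMT8	H3K9	writer	rep
KDM1A	H3K9	eraser	act
KDM3A	H3K9	eraser	act
KDM3B	H3K9	eraser	act
KDM4A	H3K9	eraser	act
KDM4B	H3K9	eraser	act
KDM4C	H3K9	eraser	act
KDM4D	H3K9	eraser	act
KDM7A	H3K9	eraser	act
MINA	H3K9	eraser	act
KMT1C	H3K27	writer	rep
KMT1D	H3K27	writer	rep
KMT6A	H3K27	writer	rep
KMT6B	H3K27	writer	rep
WHSC1	H3K27	writer	rep
KDM6A	H3K27	eraser	act
KDM6B	H3K27	eraser	act
KDM7A	H3K27	eraser	act
KDM2A	H3K36	eraser	unknown
KDM4A	H3K36	eraser	rep
KDM4C	H3K36	eraser	rep
KDM8	H3K36	eraser	rep
KMT2H	H3K36	writer	act
KMT3A	H3K36	writer	act
KMT3B	H3K36	writer	unknown
KMT3C	H3K36	writer	act
SETMAR	H3K36	writer	act
KMT4	H3K79	writer	act
DNMT1	DNA	writer	rep
DNMT3A	DNA	writer	rep
DNMT3B	DNA	writer	rep
DNMT3L	DNA	writer	rep
TET3	DNA	eraser	act
MBD2	DNA	reader	unknown
MBD2	DNA	eraser	unknown
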