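gene	transcript	total_alus	subfamilies	lengths	directions	biotype
CEP76	ENST00000593250	6	AluSx;AluSx;AluSp;AluSp;Alu;AluSz6	149;292;293;303;49;115	a;s;s;s;s;s	Nonsense-mediated decay
TSPAN31	ENST00000547992	5	AluSx;AluSx;FLAM_C;AluSc;FRAM	296;310;111;289;198	a;a;s;s;s	Protein coding
THOC5	ENST00000490103	4	AluSz;AluJr;AluJo;AluSx	297;303;296;275	s;s;a;s	Protein coding
RSPH3	ENST00000367069	4	AluSp;AluJb;AluSc;AluSc	306;315;291;284	s;a;s;s	Protein coding
TMEM170A	ENST00000357613	4	AluSg4;AluJb;AluY;AluSx1	303;272;288;300	a;s;a;a	Protein coding
TMEM170A	ENST00000568559	4	AluSg4;AluJb;AluY;AluSx1	216;241;288;308	a;s;a;a	Nonsense-mediated decay
FUT2	ENST00000425340	3	AluSz;AluSg;FAM	311;307;156	s;a;s	Protein coding
CTD-3088G3.8	ENST00000595170	3	AluSz6;AluSg;AluSx1	100;75;311	s;a;s	Nonsense-mediated decay
HLA-DOA	ENST00000229829	2	AluJr;AluSc	313;283	s;a	Protein coding
CSNK2B-LY6G5B-1181	ENST00000409691	2	AluSx3;AluSz	292;290	a;s	Protein coding
CSNK2B-LY6G5B-1181	ENST00000375880	2	AluSx3;AluSz	292;290	a;s	Protein coding (Major isoform)
LY6G5B	ENST00000375864	2	AluSx3;AluSz	292;290	a;s	Protein coding
SUOX	ENST00000550065	2	AluSq;AluSx	216;200	s;a	Nonsense-mediated decay
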