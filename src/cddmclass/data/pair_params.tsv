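group1	group2	metric	k
CAD2	LVH3	Manhattan	3
MVD_M	CAD3	Manhattan	7
MVD_F	CAD3	Manhattan	4
CAD2	CAD3	Manhattan	5
CAD2	NORM2	Manhattan	11
NONCOR	NORM2	Manhattan	5
CAD3	NONCOR	Manhattan	3
CAD1	NORM2	Eucledian	5
MVD_F	CAD2	Manhattan	10
MVD_M	NORM1	Manhattan	12
CAD1	CAD2	Chebyshev	7
LVH2	NORM1	Manhattan	3
CAD2	NONCOR	Manhattan	3
LVH1	LVH3	Manhattan	3
CAD3	NORM1	Manhattan	3
LVH3	NORM1	Manhattan	3
NORM1	NORM2	Manhattan	7
CAD2	CAD4	Manhattan	4
CAD4	CAD5	Chebyshev	5
CAD2	NORM1	Manhattan	5
LVH1	CAD3	Manhattan	3
LVH1	MDAM	Manhattan	3
MDAM	NONCOR	Manhattan	5
OTHER_PAIRS		Cityblock	1
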