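rule_type	key_label	candidate_label
low_precision	LVH1	MDAM
low_precision	LVH1	LVH2
low_precision	LVH1	MVD_M
low_precision	LVH1	NORM2
low_precision	LVH2	NORM1
low_precision	LVH2	LVH1
low_precision	LVH2	MVD_F
low_precision	LVH3	CAD2
low_precision	LVH3	MVD_M
low_precision	LVH3	CAD3
low_precision	LVH3	NORM2
low_precision	CAD3	NONCOR
low_precision	CAD3	CAD2
low_precision	CAD3	MVD_M
low_precision	CAD3	MVD_F
low_precision	NORM1	CAD1
low_precision	NORM1	LVH2
low_precision	NORM1	NORM2
low_precision	NORM1	NONCOR
low_sensitivity	NORM2	LVH1
low_sensitivity	NORM2	LVH3
low_sensitivity	NORM2	NORM1
low_sensitivity	MVD_F	CAD4
low_sensitivity	MVD_F	LVH2
low_sensitivity	MVD_M	CAD1
low_sensitivity	MVD_M	CAD3
low_sensitivity	MVD_M	NORM2
low_sensitivity	NONCOR	CAD1
low_sensitivity	NONCOR	CAD3
low_sensitivity	NONCOR	NORM1
low_sensitivity	LVH2	LVH1
low_sensitivity	LVH2	NORM1
low_sensitivity	CAD2	LVH2
low_sensitivity	CAD2	LVH3
low_sensitivity	CAD2	CAD3
low_sensitivity	CAD2	CAD5
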