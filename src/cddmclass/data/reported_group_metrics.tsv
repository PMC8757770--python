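# Published per-group one-vs-all characteristics of the two-stage classifier
# on the original clinical cohort (2,142 maps, 14 groups).  Used as a worked
# example for the macro-averaging routine; not reproducible from synthetic data.
group	accuracy	precision	sensitivity	specificity
LVH1	0.955	0.629	0.900	0.959
LVH3	0.960	0.666	0.873	0.966
MDAM	0.979	0.848	0.863	0.988
CAD3	0.947	0.605	0.755	0.962
MVD_M	0.938	0.629	0.310	0.986
CAD5	0.967	0.760	0.790	0.981
NORM2	0.958	0.724	0.655	0.981
MVD_F	0.952	0.753	0.488	0.988
CAD2	0.956	0.742	0.590	0.984
CAD1	0.965	0.811	0.665	0.988
NONCOR	0.957	0.722	0.650	0.981
CAD4	0.971	0.758	0.875	0.978
LVH2	0.949	0.633	0.695	0.969
NORM1	0.943	0.589	0.673	0.964
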