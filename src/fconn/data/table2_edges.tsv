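region_a	region_b	mean_t2d	mean_control	p
ROL.R	SMA.L	0.1478	-0.0721	0.0045
ROL.R	SMA.R	0.1872	-0.0005	0.0057
SMA.R	INS.L	0.1095	-0.0489	0.0093
SMA.L	HIP.L	0.0639	-0.1647	0.0040
SMA.R	HIP.L	0.0644	-0.1481	0.0040
SMA.R	PHG.L	0.0006	-0.2130	0.0040
SMA.R	PHG.R	-0.0242	-0.2229	0.0041
CAL.L	PoCG.R	0.0889	-0.1174	0.0044
ORBinf.R	PCL.L	-0.0328	-0.2496	0.0033
ROL.R	PCL.L	0.1763	0.0061	0.0096
INS.L	PCL.L	0.0881	-0.0859	0.0064
PHG.L	PCL.L	0.0228	-0.1634	0.0094
ROL.R	PCL.R	0.0716	-0.1131	0.0098
SMA.L	HES.L	0.0895	-0.0758	0.0083
PCL.L	HES.L	0.2112	-0.0099	0.0004
PCL.R	HES.L	0.1180	-0.0850	0.0020
PreCG.R	HES.R	0.2606	0.0683	0.0081
SMA.L	HES.R	0.1233	-0.0942	0.0063
SMA.R	HES.R	0.1701	-0.0495	0.0024
PoCG.R	HES.R	0.3351	0.0998	0.0048
PCL.L	HES.R	0.1962	-0.0025	0.0053
PCL.R	HES.R	0.1319	-0.0627	0.0090
SMA.L	STG.L	0.1554	-0.0598	0.0094
PCL.L	STG.L	0.2069	0.0264	0.0098
SMA.L	STG.R	0.0893	-0.1603	0.0029
SMA.R	STG.R	0.1404	-0.0816	0.0032
SMA.L	TPOsup.R	0.1096	-0.1357	0.0031
SMA.R	TPOsup.R	0.1445	-0.1117	0.0034
SMA.R	MTG.R	-0.1319	-0.3170	0.0097
SMA.L	TPOmid.L	-0.0268	-0.2348	0.0089
SMA.L	TPOmid.R	0.0020	-0.1901	0.0087
SMA.R	C45.L	-0.0311	-0.2690	0.0040
SMA.R	C45.L	0.0151	-0.2065	0.0063
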