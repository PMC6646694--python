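variable	mean_t2d	sd_t2d	n_t2d	mean_control	sd_control	n_control	p_printed
Age (years)	49.11	9.68	33	52.50	9.66	24	0.194
Education (years)	13.03	3.53	33	11.88	3.30	24	0.215
BMI (kg/m^2)	25.42	2.83	33	24.19	3.33	24	0.135
Systolic BP (mmHg)	122.78	11.51	33	122.92	15.66	24	0.969
Diastolic BP (mmHg)	77.17	11.13	33	75.42	7.99	24	0.513
Total cholesterol (mmol/l)	5.36	0.97	33	5.18	0.91	24	0.478
HDL cholesterol (mmol/l)	1.52	0.46	33	1.68	0.54	24	0.230
LDL cholesterol (mmol/l)	2.79	2.91	33	2.91	0.67	24	0.844
Cr (umol/L)	68.21	14.82	33	68.79	13.46	24	0.878
FPG (mmol/L)	8.48	3.22	33	5.20	0.40	24	0.001
2hPG (mmol/l)	12.31	5.37	33	5.71	1.06	24	0.001
Fasting insulin (uU/ml)	12.86	9.62	33	10.44	6.02	24	0.281
Fasting C-peptide (ng/ml)	2.38	1.09	33	1.97	0.68	24	0.109
HbA1c (%)	7.30	1.97	33	5.60	0.25	24	0.001
HOMA-beta (%)	64.06	50.11	33	109.37	48.43	24	0.001
HOMA-IR	2.02	1.30	33	1.25	0.76	24	0.012
MoCA	26.32	2.42	33	24.38	3.99	24	0.058
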