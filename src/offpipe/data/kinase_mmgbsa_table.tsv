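target	ligand	dH	dTS	dG
ARK	HPM	-41.50	-26.70	-14.80
ARK	1UN	-41.62	-20.36	-21.26
ABL	P16	-30.14	-14.09	-16.05
ABL	1UN	-31.22	-20.41	-10.81
AKT2	I5S	-35.67	-24.38	-19.25
AKT2	1UN	-43.64	-35.67	-18.53
CDK2	1CD	-52.68	-10.10	-42.58
CDK2	1UN	-49.54	-21.67	-27.87
EGFR	AEE	-34.73	-14.16	-20.57
EGFR	1UN	-33.72	-18.12	-15.60
EPHB4	7X4	-39.61	-17.64	-21.96
EPHB4	1UN	-21.40	-19.86	-1.54
FAK	BI9	-50.02	-18.82	-31.20
FAK	1UN	-44.73	-16.20	-28.53
FGFR	SU1	-35.88	-18.44	-17.44
FGFR	1UN	-26.86	-21.24	-5.62
IGF-1R	BMI	-38.26	-17.28	-20.98
IGF-1R	1UN	-31.43	-21.37	-10.05
PDK1	BI1	-35.39	-13.65	-21.74
PDK1	1UN	-30.32	-17.76	-12.56
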