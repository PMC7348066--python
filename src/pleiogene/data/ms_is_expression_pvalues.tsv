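gene	GSE21942	GSE43591	GSE16561	GSE58294
B4GALNT1	8.53E-02	9.83E-02	3.48E-01	2.03E-02
BRAP	4.87E-01	1.44E-02	4.13E-01	1.71E-20
CAMK2G	4.15E-04	3.09E-06	5.81E-01	5.14E-07
CLEC2D	9.11E-04	7.91E-02	2.68E-07	1.78E-01
CLECL1	7.42E-01	4.19E-01	2.94E-01	6.30E-06
FOXP1	2.35E-09	1.17E-02	4.27E-02	1.55E-05
HECTD4	7.59E-02	1.34E-02	NA	8.83E-05
IL6	1.27E-02	4.99E-01	9.05E-01	1.02E-01
LBH	3.52E-02	5.60E-04	5.45E-06	7.92E-01
LIME1	3.35E-02	9.94E-03	2.33E-07	1.16E-09
MICB	6.07E-01	2.05E-01	8.59E-01	2.45E-04
NAA25	2.09E-01	5.01E-02	9.57E-01	3.92E-08
NFKBIL1	3.63E-01	6.31E-01	2.21E-01	3.33E-06
NUDT14	1.51E-04	8.09E-01	9.00E-03	2.53E-02
OS9	2.99E-01	8.58E-01	1.41E-04	1.24E-12
PDE4C	2.52E-02	2.01E-01	2.40E-01	8.74E-02
RTEL1	1.43E-01	1.73E-01	2.53E-01	8.01E-01
RTEL1-TNFRSF6B	2.20E-03	9.24E-03	NA	5.42E-01
SLC2A4RG	7.21E-02	1.29E-03	5.07E-05	3.18E-01
SLC44A2	4.03E-02	9.87E-02	4.73E-04	1.27E-03
STAT4	1.47E-01	7.80E-01	3.93E-03	9.05E-01
TEC	7.27E-01	5.51E-01	4.71E-01	9.03E-02
ZBTB46	5.81E-01	7.17E-01	7.52E-01	1.06E-02
ZGPAT	5.70E-02	6.93E-04	6.20E-03	8.85E-03
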