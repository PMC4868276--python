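# Default window-averaged physicochemical property tables, spanning
# hydropathy, hydrophilicity, polarity, volume and bulkiness:
#   KYTJ820101  Kyte & Doolittle (1982) hydropathy index
#   HOPT810101  Hopp & Woods (1981) hydrophilicity value
#   GRAR740102  Grantham (1974) polarity
#   GRAR740103  Grantham (1974) volume
#   ZIMJ680102  Zimmerman et al. (1968) bulkiness
aa	KYTJ820101	HOPT810101	GRAR740102	GRAR740103	ZIMJ680102
A	1.8	-0.5	8.1	31.0	11.50
C	2.5	-1.0	5.5	55.0	13.46
D	-3.5	3.0	13.0	54.0	11.68
E	-3.5	3.0	12.3	83.0	13.57
F	2.8	-2.5	5.2	132.0	19.80
G	-0.4	0.0	9.0	3.0	3.40
H	-3.2	-0.5	10.4	96.0	13.69
I	4.5	-1.8	5.2	111.0	21.40
K	-3.9	3.0	11.3	119.0	15.71
L	3.8	-1.8	4.9	111.0	21.40
M	1.9	-1.3	5.7	105.0	16.25
N	-3.5	0.2	11.6	56.0	12.82
P	-1.6	0.0	8.0	32.5	17.43
Q	-3.5	0.2	10.5	85.0	14.45
R	-4.5	3.0	10.5	124.0	14.28
S	-0.8	0.3	9.2	32.0	9.47
T	-0.7	-0.4	8.6	61.0	15.77
V	4.2	-1.5	5.9	84.0	21.57
W	-0.9	-3.4	5.4	170.0	21.67
Y	-1.3	-2.3	6.2	136.0	18.03
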