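Fp1	-0.309017	0.904508	0.293893
Fpz	0.000000	0.951057	0.309017
Fp2	0.309017	0.904508	0.293893
AF7	-0.587785	0.654508	0.475528
AF3	-0.309017	0.769421	0.559017
AFz	0.000000	0.809017	0.587785
AF4	0.309017	0.769421	0.559017
AF8	0.587785	0.654508	0.475528
F7	-0.809017	0.345492	0.475528
F5	-0.649448	0.446955	0.615181
F3	-0.453990	0.523720	0.720839
F1	-0.233445	0.571545	0.786664
Fz	0.000000	0.587785	0.809017
F2	0.233445	0.571545	0.786664
F4	0.453990	0.523720	0.720839
F6	0.649448	0.446955	0.615181
F8	0.809017	0.345492	0.475528
FT7	-0.951057	0.095492	0.293893
FC5	-0.809017	0.181636	0.559017
FC3	-0.587785	0.250000	0.769421
FC1	-0.309017	0.293893	0.904508
FCz	0.000000	0.309017	0.951057
FC2	0.309017	0.293893	0.904508
FC4	0.587785	0.250000	0.769421
FC6	0.809017	0.181636	0.559017
FT8	0.951057	0.095492	0.293893
T7	-0.951057	0.000000	0.309017
C5	-0.809017	0.000000	0.587785
C3	-0.587785	0.000000	0.809017
C1	-0.309017	0.000000	0.951057
Cz	0.000000	0.000000	1.000000
C2	0.309017	0.000000	0.951057
C4	0.587785	0.000000	0.809017
C6	0.809017	0.000000	0.587785
T8	0.951057	0.000000	0.309017
TP7	-0.951057	-0.095492	0.293893
CP5	-0.809017	-0.181636	0.559017
CP3	-0.587785	-0.250000	0.769421
CP1	-0.309017	-0.293893	0.904508
CPz	0.000000	-0.309017	0.951057
CP2	0.309017	-0.293893	0.904508
CP4	0.587785	-0.250000	0.769421
CP6	0.809017	-0.181636	0.559017
TP8	0.951057	-0.095492	0.293893
P9	-0.951057	-0.181636	0.250000
P7	-0.809017	-0.345492	0.475528
P5	-0.649448	-0.446955	0.615181
P3	-0.453990	-0.523720	0.720839
P1	-0.233445	-0.571545	0.786664
Pz	0.000000	-0.587785	0.809017
P2	0.233445	-0.571545	0.786664
P4	0.453990	-0.523720	0.720839
P6	0.649448	-0.446955	0.615181
P8	0.809017	-0.345492	0.475528
P10	0.951057	-0.181636	0.250000
PO7	-0.587785	-0.654508	0.475528
PO3	-0.309017	-0.769421	0.559017
POz	0.000000	-0.809017	0.587785
PO4	0.309017	-0.769421	0.559017
PO8	0.587785	-0.654508	0.475528
O1	-0.309017	-0.904508	0.293893
Oz	0.000000	-0.951057	0.309017
O2	0.309017	-0.904508	0.293893
Iz	0.000000	-1.000000	0.000000
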