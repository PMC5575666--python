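lincRNA_id	n_deptg	n_up	n_down
TCONS_00000089	41	34	7
TCONS_00000134	4	4	0
TCONS_00000742	53	37	16
TCONS_00005771	7	7	0
TCONS_00006963	31	26	5
TCONS_00007946	46	42	4
TCONS_00013076	3	2	1
TCONS_00021480	12	11	1
TCONS_00021915	71	27	44
TCONS_00034774	4	4	0
TCONS_00044733	80	76	4
TCONS_00056305	5	5	0
TCONS_00059011	14	3	11
TCONS_00061360	110	79	31
TCONS_00061633	13	13	0
TCONS_00064940	11	10	1
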