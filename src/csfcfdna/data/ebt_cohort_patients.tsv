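patient_id	entity
1	ATRT
2	ATRT
3	ATRT
4	MB_NOS
5	MB_WNT
6	MB_NOS
7	MB_NOS
8	MB_NOS
9	MB_NOS
10	MB_NOS
11	MB_SHH
12	MB_WNT
13	MB_NOS
14	MB_NOS
15	MB_NOS
16	MB_NOS
17	MB_NOS
18	MB_NOS
19	MB_NOS
20	MB_WNT
21	MB_NOS
22	MB_NOS
23	ETMR
24	CNS_NB_FOXR2
25	EBT_NOS
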