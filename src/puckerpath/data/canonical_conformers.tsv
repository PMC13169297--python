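name	ring_class	theta_deg	phi_deg
4C1	C	0.000000	0.000000
1C4	C	180.000000	0.000000
3OB	B	90.000000	0.000000
B3O	B	90.000000	180.000000
14B	B	90.000000	240.000000
B14	B	90.000000	60.000000
25B	B	90.000000	120.000000
B25	B	90.000000	300.000000
3S1	S	90.000000	30.000000
5S1	S	90.000000	90.000000
2SO	S	90.000000	150.000000
1S3	S	90.000000	210.000000
1S5	S	90.000000	270.000000
OS2	S	90.000000	330.000000
OE	E	54.735610	0.000000
EO	E	125.264390	180.000000
1E	E	125.264390	240.000000
E1	E	54.735610	60.000000
2E	E	54.735610	120.000000
E2	E	125.264390	300.000000
3E	E	125.264390	0.000000
E3	E	54.735610	180.000000
4E	E	54.735610	240.000000
E4	E	125.264390	60.000000
5E	E	125.264390	120.000000
E5	E	54.735610	300.000000
OH1	H	50.768480	30.000000
1HO	H	129.231520	210.000000
1H2	H	129.231520	270.000000
2H1	H	50.768480	90.000000
2H3	H	50.768480	150.000000
3H2	H	129.231520	330.000000
3H4	H	129.231520	30.000000
4H3	H	50.768480	210.000000
4H5	H	50.768480	270.000000
5H4	H	129.231520	90.000000
5HO	H	129.231520	150.000000
OH5	H	50.768480	330.000000
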