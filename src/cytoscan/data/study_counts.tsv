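study	event	stage	events	total
Klatte09	-3p	S1	77	121
Klatte09	-3p	S2	17	25
Klatte09	-3p	S3	53	97
Klatte09	-3p	S4	0	3
Klatte09	-3p	all	147	246
Beroud96	-3p	S1	52	77
Beroud96	-3p	S2	10	14
Beroud96	-3p	S3	15	22
Beroud96	-3p	S4	2	5
Beroud96	-3p	all	79	118
Gunawan01	-3p	S1	48	49
Gunawan01	-3p	S2	12	12
Gunawan01	-3p	S3	33	34
Gunawan01	-3p	S4	23	23
Gunawan01	-3p	all	116	118
Toma08	-3p	all	20	22
Yoshimoto07	-3p	all	21	26
Current	-3p	S1	19	22
Current	-3p	S2	2	2
Current	-3p	S3	14	15
Current	-3p	S4	1	1
Current	-3p	all	36	40
Gunawan01	+5q	S1	28	49
Gunawan01	+5q	S2	6	12
Gunawan01	+5q	S3	23	34
Gunawan01	+5q	S4	10	23
Gunawan01	+5q	all	67	118
Current	+5q	S1	10	22
Current	+5q	S2	2	2
Current	+5q	S3	7	15
Current	+5q	S4	0	1
Current	+5q	all	19	40
Klatte09	+5q	all	82	246
Toma08	+5q	all	10	22
Yoshimoto07	+5q	all	15	26
Klatte09	-14q	S1	24	121
Klatte09	-14q	S2	8	25
Klatte09	-14q	S3	36	97
Klatte09	-14q	S4	0	3
Klatte09	-14q	all	68	246
Beroud96	-14q	S1	19	77
Beroud96	-14q	S2	4	14
Beroud96	-14q	S3	8	22
Beroud96	-14q	S4	3	5
Beroud96	-14q	all	34	118
Gunawan01	-14q	S1	29	49
Gunawan01	-14q	S2	9	12
Gunawan01	-14q	S3	22	34
Gunawan01	-14q	S4	14	23
Gunawan01	-14q	all	74	118
Toma08	-14q	all	8	22
Yoshimoto07	-14q	all	9	26
Current	-14q	S1	5	22
Current	-14q	S2	0	2
Current	-14q	S3	7	15
Current	-14q	S4	0	1
Current	-14q	all	12	40
Klatte09	+7	all	64	246
Gunawan01	+7	all	22	118
Toma08	+7	all	7	22
Yoshimoto07	+7	all	9	26
Current	+7	all	17	40
Klatte09	-8p	all	49	246
Gunawan01	-8p	all	39	118
Current	-8p	all	10	40
Klatte09	-6q	all	42	246
Gunawan01	-6q	all	28	118
Toma08	-6q	all	6	22
Yoshimoto07	-6q	all	8	26
Current	-6q	all	7	40
Klatte09	-9p	all	40	246
Gunawan01	-9p	all	28	118
Toma08	-9p	all	7	22
Yoshimoto07	-9p	all	5	26
Current	-9p	all	7	40
Klatte09	-4p	all	32	246
Gunawan01	-4p	all	17	118
Current	-4p	all	2	40
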