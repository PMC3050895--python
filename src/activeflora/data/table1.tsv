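row	A	B	C	D	E	F	K	L	N	O
total	57300	48150	34849	19625	17891	22748	69100	75059	35276	29505
SSU	11528	4524	7726	6663	5585	3221	12707	8024	6482	6057
LSU	43622	41888	25359	11896	10948	16494	52981	59935	24587	21353
non_rRNA	2150	1738	1764	1066	1358	3033	3412	7100	4207	2095
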