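canonical_string	count	K_bits
0	2000	0.605968358841
00	508	2.58306795673
01	508	2.58306795673
000	4	9.5717526435
001	6	8.98679014278
010	4	9.5717526435
011	6	8.98679014278
0000	2	10.5717526435
0010	2	10.5717526435
0100	2	10.5717526435
0110	2	10.5717526435
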