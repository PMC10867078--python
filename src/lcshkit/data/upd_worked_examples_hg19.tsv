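# Published worked examples of UPD-suggestive LCSH patterns (GRCh37/hg19).
# One row per LCSH segment; a case may span several rows.  Coordinates are
# 1-based inclusive as printed in the source segment tables.
# columns: case, chromosome, band_span, start, end, printed_case_total_mbp
case	chromosome	band_span	start	end	printed_case_total_mbp
25	1	q25.3q31.3	182537598	197949082	15.4
129	1	p31.3p31.1	61620929	76755163	15.1
147	2	p12p11.2	79211952	89129064	88.8
147	2	q11.1q14.3	95341387	128342675	88.8
147	2	p24.1p14	22170065	68067589	88.8
944	2	q24.1q31.1	155368924	174708199	19.3
113	3	q26.32q28	176695771	189044675	12.3
947	3	p13p12.3	72016624	77325155	20.8
947	3	q22.2q25.1	133992740	149438082	20.8
1101	5	q14.1q15	77967561	94997034	17.0
169	7	q21.13q31.1	90678991	109653423	19.0
346	7	p14.3p14.1	29374797	40699189	10.6
833	8	q13.3q22.1	70942228	94406882	23.4
505	9	q31.2q33.1	108394893	122047673	13.6
76	10	q25.2q26.13	112544654	124513498	12.0
776	10	q22.1q23.31	72616063	91065521	18.5
569	11	q14.1q21	83339664	95895139	12.6
633	11	p15.3p13	11473107	32068176	20.6
628	11	p11.2p11.12	45853773	51550787	10.9
628	11	q13.4q13.5	71543708	76752248	10.9
674	12	p13.33p12.1	257936	22766988	22.5
284	12	q15q21.31	69859080	84755083	14.9
430	12	q21.2q21.33	78736693	92566637	13.8
407	13	q22.1q31.3	75078803	92192744	17.1
312	14	q13.2q23.2	36397727	64565981	28.1
204	16	p13.3p13.13	89560	12548052	12.5
47	17	q22q24.2	53332043	65633600	12.3
584	18	p11.22p11.21	9990161	15143714	22.7
584	18	q11.1q12.2	18540834	36061962	22.7
907	20	q11.21q13.11	29510307	42027093	21.3
907	20	p12.1p11.1	17489413	26266313	21.3
209	22	q12.1q13.1	26504838	40021614	13.5
443	22	q13.1q13.33	37977281	51157531	13.2
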