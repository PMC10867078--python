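# Published worked examples of LCSH-based consanguinity estimates.
# sum_mbp is the printed per-sample sum of autosomal LCSH >= 3 Mbp;
# f_printed is the printed inbreeding coefficient (precision varies by row);
# degree_printed is the printed degree-of-kinship label.
case	sum_mbp	f_printed	degree_printed
194	760	0.264	first
8	1053	0.37	first
271	334	0.116	second
1068	403	0.14	second
918	285	0.10	second
297	314	0.109	second
380	346	0.121	second
220	402	0.139	second
187	196	0.068	third
275	225	0.078	third
395	136	0.047	third
412	123	0.043	third
413	162	0.056	third
419	181	0.063	third
354	193	0.067	third
364	165	0.057	third
540	196	0.068	third
645	238	0.082	third
730	137	0.047	third
754	204	0.070	third
766	136	0.04	third
823	183	0.063	third
910	248	0.086	third
1088	227	0.079	third
1103	239	0.082	third
157	62	0.022	fourth
273	110	0.038	fourth
287	96	0.033	fourth
311	82	0.028	fourth
378	93	0.032	fourth
506	68	0.023	fourth
546	73	0.025	fourth
612	88	0.030	fourth
614	81	0.028	fourth
663	90	0.031	fourth
676	106	0.036	fourth
770	75	0.026	fourth
789	123	0.042	fourth
806	74	0.025	fourth
905	66	0.023	fourth
1011	79	0.027	fourth
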