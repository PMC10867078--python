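# Reference list of recurrent (common) LCSH regions in a South-Brazilian
# clinical cohort, GRCh37/hg19, median-delineated boundaries (1-based inclusive).
# Used by annotate_common_membership when no cohort-derived regions are given.
chromosome	band_span	start	end
16	p11.2	31609107	35220544
11	p11.2-p11.11	47885574	51550787
3	p21.31-p21.1	48597552	52514732
1	p33-p32.3	49149495	53138197
15	q15.1-q21.1	42335561	45773925
10	q22.2-q22.3	73953260	77200441
2	q11.1-q11.2	95550958	98905554
1	q21.1-q21.2	145673186	149664902
19	q13.2-q13.31	40357663	44200928
5	q23.3-q31.1	128694241	132201418
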