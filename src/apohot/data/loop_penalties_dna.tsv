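loop_type	size	dg37
hairpin	3	3.5
hairpin	4	3.5
hairpin	5	3.3
hairpin	6	4.0
hairpin	7	4.4
hairpin	8	4.3
hairpin	9	4.5
hairpin	10	5.0
hairpin	12	5.5
hairpin	14	6.0
hairpin	16	6.3
hairpin	18	6.5
hairpin	20	6.7
hairpin	25	7.0
hairpin	30	7.4
bulge	1	4.0
bulge	2	2.9
bulge	3	3.1
bulge	4	3.2
bulge	5	3.3
bulge	6	3.5
bulge	7	3.7
bulge	8	3.9
internal	2	3.2
internal	3	3.2
internal	4	3.6
internal	5	4.0
internal	6	4.4
internal	7	4.6
internal	8	4.8
internal	9	4.9
internal	10	4.9
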