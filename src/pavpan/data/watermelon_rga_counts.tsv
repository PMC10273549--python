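subfamily	location	variable	core
CN	reference	0	2
CN	additional_contig	3	0
CNL	reference	0	10
CNL	additional_contig	2	0
NBS	reference	0	6
NBS	additional_contig	9	0
NL	reference	0	10
NL	additional_contig	6	0
RLK	reference	9	379
RLK	additional_contig	28	1
RLP	reference	2	32
RLP	additional_contig	10	0
TMCC	reference	2	98
TMCC	additional_contig	20	0
TN	reference	0	2
TN	additional_contig	0	0
TNL	reference	1	6
TNL	additional_contig	3	0
TX	reference	3	4
TX	additional_contig	8	0
OTHER	reference	0	5
OTHER	additional_contig	0	0
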