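# Synthetic stand-in intervals for the three gummy stem blight resistance QTLs.
# Published coordinates are not available here; the three spans are chosen to
# reproduce the reported totals (18.5 Mb across three chromosomes).
chr3	2000000	6600000	ClGSB3.1
chr5	1500000	7900000	ClGSB5.1
chr7	3000000	10500000	ClGSB7.1
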