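modification	sample	flag
m3U	mRNA #1	bdl
Um	mRNA #1	bdl
I	28S rRNA #2	bdl
I	18S rRNA #2	bdl
I	mRNA #1	bdl
t6A	mRNA #1	bdl
m2G	mRNA #1	bdl
m5U	mRNA #1	bdl
Am	Input #1	above_range
Gm	Input #1	above_range
m5C	Input #1	above_range
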