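# stage: absolute_percent_A
# provenance: packaged reference matrix of absolutely quantified modification content (% of adenosine UV signal); bdl cells stored as 0, see table2_flags.tsv
modification	tRNA #2	tRNA #1	mRNA #1	28S rRNA #2	28S rRNA #1	18S rRNA #2	18S rRNA #1	Input #2	Input #1
m3U	0.044	0.035	0	0.273	0.214	0.015	0.024	0.050	0.055
Um	2.349	1.913	0	3.102	5.258	2.600	2.603	1.587	1.594
m6,6A	0.013	0.010	0.006	0.154	0.490	0.950	1.469	0.278	0.451
Cm	0.523	0.426	0.017	0.887	0.594	0.585	0.444	0.684	1.533
Am	0.034	0.024	0.043	2.754	2.070	2.555	2.017	1.915	2.949
Gm	1.335	1.066	0.069	2.949	1.829	1.907	1.539	1.876	2.328
m6A	0.649	0.498	0.229	0.230	0.240	0.173	0.319	0.306	0.304
m3C	0.602	0.466	0.0002	0.006	0.032	0.006	0.057	0.090	0.202
I	0.884	0.670	0	0	0.057	0	0.096	0.217	0.167
i6A	0.204	0.149	0.00015	0.002	0.011	0.002	0.020	0.031	0.036
m5C	7.484	6.279	0.011	0.354	0.632	0.114	0.783	1.355	2.273
m7G	4.664	4.070	0.149	0.097	0.349	0.358	0.666	0.880	1.026
t6A	0.703	0.590	0	0.008	0.046	0.008	0.075	0.121	0.138
m1G	2.975	2.500	0.001	0.032	0.170	0.034	0.297	0.486	0.565
m2G	6.193	5.077	0	0.059	0.328	0.054	0.583	0.987	1.135
m2,2G	2.293	1.890	0.00049	0.020	0.125	0.020	0.222	0.360	0.454
m5U	3.083	2.529	0	0.041	0.195	0.038	0.303	0.482	0.609
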