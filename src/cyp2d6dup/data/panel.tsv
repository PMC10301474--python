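assay_id	legacy_name	ref_allele	alt_allele	segment	panel_index
c.-1584C>G	-1584C>G	G	C	early	1
c.31G>A	31G>A	C	T	early	2
c.100C>T	100C>T	G	A	early	3
c.320C>T	1023C>T	G	A	mid	4
c.454delT	1707delT	A	del	mid	5
c.506-1G>A	1846G>A	C	T	mid	6
c.775delA	2549delA	T	del	mid	7
c.841_843delAAG	2615_2617delAAG	CTT	del	mid	8
c.886C>T	2850C>T	G	A	mid	9
c.980G>A	2939G>A	C	T	mid	10
c.985+39G>A	2988G>A	C	T	mid	11
c.1012G>A	3183G>A	C	T	mid	12
c.1320G>A	3854G>A	C	T	mid	13
c.1457G>C	4180G>C	C	G	late	14
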