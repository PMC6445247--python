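# 48 ancestry-informative SNPs: ancestral-allele frequencies in four continental
# reference groups, pooled over 25 CEPH-HGDP training populations.
# alleles column is ancestral/derived; positions are 1-based (dbSNP build 152).
#sample_sizes	African=97	American=57	European=158	East Asian=177
rs_id	alleles	chromosome	position_bp	intronic	African	American	European	East Asian
rs10918196	C/T	1	165478920	1	0.8351	0.3947	0.6108	0.2429
rs2801178	G/T	1	14881716	1	0.8608	0.2368	0.7753	0.4774
rs4652825	A/G	1	183824189	1	0.7320	0.4737	0.8101	0.6215
rs10779958	A/C	2	74528651	1	0.3763	0.5000	0.8481	0.1921
rs1161474	C/T	2	239209361	1	0.7320	0.6053	0.3829	0.5424
rs7570426	A/C	2	3325638	1	0.5567	0.8947	0.9051	0.4915
rs11716005	C/T	3	18394010	1	0.9742	0.9474	0.8101	0.5621
rs301927	A/G	3	97627774	1	0.7423	0.8947	0.0918	0.6638
rs4533619	A/G	3	42248320	1	0.2835	0.3246	0.1456	0.7345
rs4894436	G/T	3	171401588	1	0.6649	0.0789	0.6551	0.0847
rs6446081	C/T	3	59723035	1	0.8866	0.8070	0.7532	0.5480
rs12650562	C/T	4	23799564	1	0.4897	0.7456	0.5032	0.5593
rs3762894	C/T	4	99144933	1	0.7268	1.0000	0.8291	0.3757
rs2400219	C/T	5	146472334	1	0.1546	0.2193	0.2057	0.7994
rs277329	A/C	5	54158354	1	0.8351	0.8158	0.8133	0.3814
rs35414	C/T	5	33969523	1	1.0000	0.8509	0.3956	0.8644
rs4704322	C/T	5	76526649	1	0.9639	0.5175	0.7880	0.1299
rs871722	A/G	5	17437385	1	0.8918	0.2368	0.1361	0.0876
rs1857859	A/G	6	100446711	1	0.8557	0.4123	0.7025	0.5678
rs4711760	C/T	6	44027931	1	0.7990	0.7018	0.3291	0.9379
rs947612	A/G	6	73028938	1	0.8608	0.7018	0.2500	0.7655
rs2373177	C/T	7	147717307	1	0.6031	0.6053	0.7152	0.7386
rs4646437	G/A	7	99767460	1	0.8505	0.2456	0.1108	0.1243
rs7795646	A/G	7	120683673	1	0.5773	0.7632	0.2057	0.4774
rs2595599	A/G	8	92646120	1	0.4124	0.3947	0.7962	0.2542
rs351554	A/C	8	16149886	1	0.7680	0.5439	0.1329	0.4972
rs4738110	A/C	8	71193716	1	0.9588	0.3509	0.7342	0.3136
rs10965206	A/G	9	229826	1	0.4845	0.5877	0.8766	0.5791
rs4743923	C/T	9	93488779	1	0.0361	0.3333	0.4019	0.4096
rs16917217	A/G	10	18370276	1	0.2938	0.2456	0.3513	0.6441
rs4933165	C/T	10	89903145	1	0.8557	0.5439	0.8956	0.2147
rs11218323	C/T	11	99080380	1	0.6856	0.8070	0.8734	0.5256
rs1470253	A/G	11	20099911	1	0.7732	0.2018	0.7437	0.1384
rs1032332	T/C	12	72568351	1	0.5825	0.2632	0.1361	0.5311
rs17650122	A/G	13	29010756	1	0.5052	0.5877	0.5696	0.3220
rs3782972	C/T	13	94450792	1	0.9330	0.2544	0.7468	0.3220
rs7325443	C/T	13	111238209	1	0.7938	0.3246	0.8070	0.3079
rs10148212	A/C	14	66628895	1	0.2917	0.5357	0.9209	0.5028
rs10852189	C/T	15	93163645	1	0.5158	0.2281	0.3228	0.5141
rs9806693	A/G	15	78892045	1	0.6495	0.5439	0.2437	0.6780
rs170359	A/G	16	57361752	1	0.6649	0.3333	0.0316	0.1412
rs7219900	C/T	17	15471179	1	0.7474	0.2105	0.1076	0.3475
rs11152349	A/G	18	62566413	1	0.7062	0.6316	0.7057	0.3023
rs528438	T/C	18	28093911	1	0.2165	0.7632	0.3038	0.8079
rs1205357	C/T	20	34289960	1	0.8711	0.0088	0.1076	0.2147
rs162315	A/G	20	57233824	1	0.2268	0.6667	0.7025	0.6864
rs2178832	G/A	21	35449600	1	0.2010	0.4737	0.5443	0.2288
rs361557	A/G	22	18128456	1	0.9330	0.7456	0.1835	0.5650
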