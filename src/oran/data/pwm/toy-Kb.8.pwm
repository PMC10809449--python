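# surrogate pMHC position weight matrix (synthetic toy allele)
allele	toy-Kb
length	8
aa	p1	p2	p3	p4	p5	p6	p7	p8
A	10.000	0.133	0.350	0.219	10.000	10.000	0.557	0.365
C	0.651	0.986	0.927	0.195	0.704	0.407	0.434	0.575
D	0.123	0.581	0.166	0.824	0.760	0.100	0.163	0.742
E	0.154	0.603	0.423	0.624	0.545	0.490	0.878	0.233
F	0.535	0.317	0.216	0.722	0.624	0.108	0.746	0.128
G	0.317	0.795	10.000	0.801	0.461	0.428	0.918	0.823
H	0.297	0.585	0.242	0.154	0.436	0.663	0.725	0.285
I	0.789	0.691	0.409	0.226	0.741	0.589	0.321	0.741
K	0.549	0.245	0.311	0.502	0.246	0.076	0.726	0.410
L	0.589	0.087	0.104	0.666	0.758	0.685	0.708	0.914
M	0.368	0.673	0.812	0.344	0.158	0.856	0.762	0.948
N	0.793	0.421	0.570	0.838	0.193	0.195	0.986	0.542
P	0.374	0.687	0.920	0.231	0.138	0.433	0.721	0.087
Q	0.062	0.350	0.099	10.000	0.942	0.538	0.661	0.866
R	0.717	0.044	0.317	0.754	0.897	0.027	0.293	0.734
S	0.016	0.496	0.046	0.639	0.390	0.180	0.801	0.785
T	0.711	0.240	0.347	0.491	0.402	0.486	10.000	10.000
V	0.439	10.000	0.265	0.511	0.960	0.142	0.886	0.549
W	0.799	0.539	0.126	0.241	0.421	0.272	0.475	0.772
Y	0.541	0.282	0.396	0.704	0.253	0.386	0.238	0.994
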