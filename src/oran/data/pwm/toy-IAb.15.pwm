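# surrogate pMHC position weight matrix (synthetic toy allele)
allele	toy-IAb
length	15
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	p11	p12	p13	p14	p15
A	10.000	0.342	0.376	0.858	10.000	0.682	0.713	0.677	0.568	0.097	0.848	0.196	0.838	0.517	0.397
C	0.314	0.851	0.418	0.419	0.867	0.582	0.645	0.827	0.884	0.118	0.784	0.228	0.001	0.827	0.496
D	0.038	0.242	0.958	0.643	0.253	0.378	0.904	0.689	0.228	0.757	0.678	0.612	0.592	0.848	0.668
E	0.344	0.881	0.013	0.508	0.474	0.890	0.367	0.268	10.000	0.820	0.853	0.509	0.670	0.416	0.002
F	0.370	0.808	0.066	0.836	0.231	0.138	0.352	0.518	0.343	0.499	0.456	0.837	0.466	0.724	0.517
G	0.233	0.625	0.430	0.068	0.205	0.039	0.038	0.929	0.358	0.755	0.642	0.356	0.328	0.886	0.856
H	0.883	0.303	0.556	0.479	0.940	0.197	0.062	0.103	0.040	0.175	0.420	0.756	0.598	0.074	0.680
I	0.002	0.075	0.762	0.445	0.331	0.917	0.159	0.785	0.579	0.923	0.134	0.920	0.170	10.000	0.172
K	0.737	0.456	0.504	0.541	0.770	0.969	0.591	0.925	0.363	0.658	0.740	0.701	0.789	0.042	0.635
L	0.003	0.350	0.443	0.144	0.175	0.865	0.503	0.279	0.250	0.002	0.880	0.240	0.833	0.272	0.432
M	0.739	10.000	0.273	0.771	0.529	0.273	0.097	0.461	0.086	0.948	10.000	0.126	0.077	0.664	0.259
N	0.939	0.280	0.673	0.335	0.527	0.254	0.196	0.998	0.820	0.535	0.202	0.217	0.515	0.648	0.623
P	0.740	0.919	0.086	0.282	0.017	0.472	0.636	0.233	0.133	0.070	0.349	10.000	0.720	0.483	10.000
Q	0.177	0.128	10.000	10.000	0.868	0.399	0.998	10.000	0.129	0.797	0.769	0.792	0.265	0.536	0.776
R	0.773	0.490	0.057	0.702	0.521	0.674	0.982	0.021	0.948	10.000	0.572	0.275	0.630	0.443	0.374
S	0.238	0.465	0.648	0.422	0.851	0.711	0.937	0.241	0.973	0.462	0.918	0.939	0.802	0.825	0.430
T	0.514	0.567	0.916	0.999	0.135	10.000	0.974	0.119	0.632	0.107	0.818	0.080	10.000	0.399	0.496
V	0.984	0.512	0.053	0.608	0.313	0.968	10.000	0.277	0.794	0.919	0.586	0.085	0.050	0.681	0.397
W	0.994	0.411	0.229	0.561	0.563	0.745	0.425	0.312	0.850	0.608	0.019	0.272	0.976	0.498	0.899
Y	0.355	0.112	0.537	0.865	0.758	0.902	0.580	0.299	0.597	0.713	0.100	0.212	0.271	0.502	0.325
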