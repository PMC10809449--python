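# surrogate pMHC position weight matrix (synthetic toy allele)
allele	toy-Kb
length	11
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	p11
A	0.755	0.427	0.985	0.421	0.341	0.163	0.766	0.752	0.153	0.639	0.927
C	0.770	0.781	0.554	0.732	0.921	0.580	0.178	10.000	0.613	0.599	0.040
D	0.361	0.336	0.116	0.493	0.051	0.461	0.414	0.112	0.861	0.097	0.865
E	0.969	0.618	0.996	0.828	0.374	0.516	0.269	0.802	0.473	0.374	0.782
F	0.525	0.278	0.535	0.649	0.525	0.568	0.452	0.931	0.566	0.175	0.214
G	0.234	0.771	0.062	0.324	0.718	0.154	0.614	0.320	0.484	0.560	0.291
H	0.277	0.414	0.851	0.318	0.063	0.227	0.699	0.114	0.608	10.000	0.338
I	0.967	0.527	0.741	0.128	0.071	0.503	0.209	0.528	0.401	0.668	0.220
K	0.292	0.238	0.209	0.933	0.985	0.949	10.000	0.516	0.661	0.242	0.329
L	0.915	0.473	0.307	0.254	0.808	10.000	0.221	0.403	0.375	0.903	0.211
M	0.225	0.583	0.002	0.873	0.438	0.997	0.109	0.701	0.499	0.296	0.303
N	10.000	0.728	0.371	0.782	0.488	0.890	0.680	0.851	0.827	0.838	0.592
P	0.222	0.288	0.517	0.129	0.976	0.012	0.587	0.314	0.351	0.257	0.903
Q	0.158	0.300	0.976	0.804	10.000	0.818	0.461	0.906	0.199	0.653	0.364
R	0.292	0.100	0.971	0.283	0.643	0.453	0.094	0.288	0.630	0.640	0.065
S	0.168	10.000	0.219	0.464	0.269	0.583	0.209	0.019	0.796	0.931	0.689
T	0.880	0.496	0.484	0.349	0.184	0.562	0.033	0.934	0.236	0.582	0.693
V	0.304	0.043	0.424	10.000	0.638	0.576	0.185	0.964	10.000	0.912	10.000
W	0.040	0.479	0.634	0.624	0.378	0.543	0.941	0.827	0.433	0.387	0.379
Y	0.464	0.998	10.000	0.332	0.856	0.107	0.975	0.142	0.752	0.450	0.287
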