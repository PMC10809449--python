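# surrogate pMHC position weight matrix (synthetic toy allele)
allele	toy-Kb
length	9
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9
A	0.343	0.314	0.842	0.152	0.989	0.061	0.569	0.082	0.560
C	0.482	0.939	0.421	0.567	0.838	0.847	0.291	0.706	0.070
D	0.751	0.890	0.880	0.636	0.586	0.788	0.579	0.968	0.836
E	0.210	0.271	0.186	0.643	0.161	0.920	0.645	0.292	0.996
F	0.849	0.289	0.999	0.559	0.800	0.124	0.518	10.000	0.717
G	10.000	0.815	10.000	0.127	0.217	0.028	10.000	0.605	0.836
H	0.133	0.314	0.284	0.343	0.177	0.177	0.014	0.363	0.019
I	0.178	0.183	0.394	0.833	0.674	0.727	0.356	0.304	0.839
K	0.790	0.807	0.617	0.794	0.894	0.511	0.705	0.207	0.634
L	0.557	0.923	0.738	0.362	0.105	0.883	0.848	0.247	0.728
M	0.558	0.184	0.601	0.911	0.235	0.198	0.646	0.183	0.680
N	0.860	0.869	0.987	10.000	0.483	0.076	0.881	0.560	0.184
P	0.243	0.676	0.254	0.477	0.394	0.061	0.054	0.211	0.519
Q	0.631	0.931	0.513	0.444	0.100	0.284	0.475	0.369	0.650
R	0.095	10.000	0.167	0.197	0.808	0.130	0.904	0.738	0.600
S	0.462	0.993	0.135	0.278	0.022	0.207	0.656	0.186	0.874
T	0.944	0.870	0.567	0.280	10.000	0.599	0.980	0.825	10.000
V	0.594	0.478	0.784	0.011	0.351	0.212	0.347	0.393	0.132
W	0.536	0.112	0.435	0.786	0.473	10.000	0.603	0.724	0.766
Y	0.598	0.667	0.997	0.307	0.522	0.728	0.815	0.283	0.593
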