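# surrogate pMHC position weight matrix (synthetic toy allele)
allele	toy-Kb
length	10
aa	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10
A	0.780	0.908	0.754	0.812	0.742	0.195	0.139	0.918	0.146	0.457
C	0.696	0.700	0.209	0.805	0.545	0.271	10.000	0.991	0.597	0.242
D	0.376	0.150	0.353	0.869	0.370	0.262	0.596	0.029	0.873	0.798
E	0.848	0.703	0.348	0.189	0.066	0.619	0.711	0.123	0.484	0.408
F	0.079	0.712	0.386	0.889	10.000	0.091	0.328	0.783	0.051	10.000
G	0.797	0.160	0.633	0.364	0.013	10.000	0.915	0.661	0.609	0.851
H	0.999	0.464	0.908	0.557	0.442	0.359	0.384	0.585	0.135	0.031
I	0.463	0.145	0.099	0.862	0.733	0.020	0.422	0.728	0.976	0.950
K	0.564	0.069	0.108	0.048	0.353	0.443	0.601	0.314	0.799	0.100
L	10.000	0.791	0.559	0.965	0.641	0.042	0.759	0.280	10.000	0.139
M	0.940	0.866	0.827	0.329	0.801	0.833	0.926	0.970	0.896	0.667
N	0.738	0.813	0.321	0.928	0.739	0.161	0.170	10.000	0.887	0.617
P	0.899	0.113	0.589	0.179	0.753	0.807	0.941	0.490	0.097	0.401
Q	0.504	10.000	0.081	0.145	0.847	0.360	0.423	0.454	0.806	0.151
R	0.784	0.668	0.872	0.412	0.203	0.362	0.003	0.064	0.811	0.803
S	0.237	0.153	0.517	0.729	0.190	0.882	0.356	0.171	0.410	0.106
T	0.522	0.795	0.486	0.053	0.295	0.874	0.860	0.828	0.863	0.524
V	0.036	0.141	10.000	0.784	0.930	0.890	0.350	0.366	0.665	0.025
W	0.520	0.627	0.888	0.031	0.156	0.014	0.474	0.998	0.247	0.865
Y	0.733	0.714	0.371	10.000	0.311	0.092	0.375	0.362	0.785	0.012
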