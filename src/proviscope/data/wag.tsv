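aa	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	        0	 0.551571	 0.509848	 0.738998	  1.02704	 0.908598	  1.58285	  1.41672	 0.316954	 0.193335	 0.397915	 0.906265	 0.893496	 0.210494	  1.43855	  3.37079	  2.12111	 0.113133	 0.240735	  2.00601
R	 0.551571	        0	 0.635346	 0.147304	 0.528191	   3.0355	 0.439157	 0.584665	  2.13715	 0.186979	 0.497671	  5.35142	 0.683162	 0.102711	 0.679489	  1.22419	 0.554413	  1.16392	 0.381533	 0.251849
N	 0.509848	 0.635346	        0	  5.42942	 0.265256	  1.54364	 0.947198	  1.12556	  3.95629	 0.554236	 0.131528	  3.01201	 0.198221	0.0961621	 0.195081	  3.97423	  2.03006	0.0719167	    1.086	 0.196246
D	 0.738998	 0.147304	  5.42942	        0	0.0302949	 0.616783	  6.17416	 0.865584	 0.930676	 0.039437	0.0848047	 0.479855	 0.103754	0.0467304	 0.423984	  1.07176	 0.374866	 0.129767	 0.325711	 0.152335
C	  1.02704	 0.528191	 0.265256	0.0302949	        0	0.0988179	 0.021352	 0.306674	 0.248972	 0.170135	 0.384287	0.0740339	 0.390482	  0.39802	 0.109404	  1.40766	 0.512984	  0.71707	 0.543833	  1.00214
Q	 0.908598	   3.0355	  1.54364	 0.616783	0.0988179	        0	  5.46947	 0.330052	  4.29411	 0.113917	 0.869489	   3.8949	  1.54526	0.0999208	 0.933372	  1.02887	 0.857928	 0.215737	  0.22771	 0.301281
E	  1.58285	 0.439157	 0.947198	  6.17416	 0.021352	  5.46947	        0	 0.567717	 0.570025	 0.127395	 0.154263	  2.58443	 0.315124	0.0811339	 0.682355	 0.704939	 0.822765	 0.156557	 0.196303	 0.588731
G	  1.41672	 0.584665	  1.12556	 0.865584	 0.306674	 0.330052	 0.567717	        0	  0.24941	0.0304501	0.0613037	 0.373558	   0.1741	 0.049931	  0.24357	  1.34182	 0.225833	 0.336983	 0.103604	 0.187247
H	 0.316954	  2.13715	  3.95629	 0.930676	 0.248972	  4.29411	 0.570025	  0.24941	        0	  0.13819	 0.499462	 0.890432	 0.404141	 0.679371	 0.696198	 0.740169	 0.473307	 0.262569	  3.87344	 0.118358
I	 0.193335	 0.186979	 0.554236	 0.039437	 0.170135	 0.113917	 0.127395	0.0304501	  0.13819	        0	  3.17097	 0.323832	  4.25746	  1.05947	0.0999288	  0.31944	  1.45816	 0.212483	  0.42017	   7.8213
L	 0.397915	 0.497671	 0.131528	0.0848047	 0.384287	 0.869489	 0.154263	0.0613037	 0.499462	  3.17097	        0	 0.257555	  4.85402	  2.11517	 0.415844	 0.344739	 0.326622	 0.665309	 0.398618	  1.80034
K	 0.906265	  5.35142	  3.01201	 0.479855	0.0740339	   3.8949	  2.58443	 0.373558	 0.890432	 0.323832	 0.257555	        0	 0.934276	 0.088836	 0.556896	  0.96713	  1.38698	 0.137505	 0.133264	 0.305434
M	 0.893496	 0.683162	 0.198221	 0.103754	 0.390482	  1.54526	 0.315124	   0.1741	 0.404141	  4.25746	  4.85402	 0.934276	        0	  1.19063	 0.171329	 0.493905	  1.51612	 0.515706	 0.428437	  2.05845
F	 0.210494	 0.102711	0.0961621	0.0467304	  0.39802	0.0999208	0.0811339	 0.049931	 0.679371	  1.05947	  2.11517	 0.088836	  1.19063	        0	 0.161444	 0.545931	 0.171903	  1.52964	  6.45428	 0.649892
P	  1.43855	 0.679489	 0.195081	 0.423984	 0.109404	 0.933372	 0.682355	  0.24357	 0.696198	0.0999288	 0.415844	 0.556896	 0.171329	 0.161444	        0	  1.61328	 0.795384	 0.139405	 0.216046	 0.314887
S	  3.37079	  1.22419	  3.97423	  1.07176	  1.40766	  1.02887	 0.704939	  1.34182	 0.740169	  0.31944	 0.344739	  0.96713	 0.493905	 0.545931	  1.61328	        0	  4.37802	 0.523742	 0.786993	 0.232739
T	  2.12111	 0.554413	  2.03006	 0.374866	 0.512984	 0.857928	 0.822765	 0.225833	 0.473307	  1.45816	 0.326622	  1.38698	  1.51612	 0.171903	 0.795384	  4.37802	        0	 0.110864	 0.291148	  1.38823
W	 0.113133	  1.16392	0.0719167	 0.129767	  0.71707	 0.215737	 0.156557	 0.336983	 0.262569	 0.212483	 0.665309	 0.137505	 0.515706	  1.52964	 0.139405	 0.523742	 0.110864	        0	  2.48539	 0.365369
Y	 0.240735	 0.381533	    1.086	 0.325711	 0.543833	  0.22771	 0.196303	 0.103604	  3.87344	  0.42017	 0.398618	 0.133264	 0.428437	  6.45428	 0.216046	 0.786993	 0.291148	  2.48539	        0	  0.31473
V	  2.00601	 0.251849	 0.196246	 0.152335	  1.00214	 0.301281	 0.588731	 0.187247	 0.118358	   7.8213	  1.80034	 0.305434	  2.05845	 0.649892	 0.314887	 0.232739	  1.38823	 0.365369	  0.31473	        0

freq	0.086627909	0.043972004	0.039089404	0.057045106	0.019307802	0.036728104	0.058058906	0.083251808	0.024431302	0.048466005	0.086209009	0.062028606	0.019502702	0.038431904	0.045763105	0.069517907	0.061012706	0.014385901	0.035274204	0.070895607
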