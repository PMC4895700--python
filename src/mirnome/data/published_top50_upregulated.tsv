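name	rpm_kapb_cmyc	rpm_kapb	fold_cmyc_kapb_vs_vec	fold_kapb_vs_vec
hsa-miR-5010-5p	2.56436	0.728448	34.99103515	9.93977038
hsa-miR-616-3p	1.08273	0.463558	14.77399565	6.325310904
hsa-miR-3121-3p	0.854786	0.596003	11.66366929	8.132540642
hsa-miR-6851-5p	0.683829	0.52978	9.330938158	7.228918951
hsa-miR-193b-5p	2.56436	1.05956	8.747752819	3.614457009
hsa-miR-6894-5p	1.25369	0.596003	8.553407199	4.066281418
hsa-miR-3163	0.626843	1.25823	8.553356566	17.16871662
hsa-miR-3168	0.626843	0.331113	8.553356566	4.518081167
hsa-miR-30b-3p	1.76656	1.05956	8.034967866	4.819270532
hsa-miR-3607-3p	0.569857	0.26489	7.775774975	3.614459475
hsa-miR-4804-5p	0.569857	0.26489	7.775774975	3.614459475
hsa-miR-483-5p	1.13971	0.993338	7.775768905	6.777133422
hsa-miR-4647	1.02574	0.927115	6.998198837	6.325321344
hsa-miR-7854-3p	1.02574	0.331113	6.998198837	2.259046748
hsa-miR-6735-5p	2.7923	1.58934	6.35022071	3.614461119
hsa-miR-3188	0.455886	0.198668	6.220625438	2.710851429
hsa-let-7e-5p	2636.49	1690.55	6.098609794	3.910504036
hsa-miR-197-5p	3.53312	2.58268	6.026232752	4.405123744
hsa-miR-210-5p	7.1802	6.15869	5.763201618	4.943284612
hsa-miR-3651	1.25369	0.860893	5.70224553	3.915659582
hsa-miR-1909-3p	0.3989	0.397335	5.443043847	5.421689213
hsa-miR-483-3p	1.9945	1.4569	5.443043847	3.975919068
hsa-miR-3173-5p	4.3879	1.78801	5.443038446	2.217964669
hsa-miR-3197	1.1967	0.79467	5.443033944	3.614452899
hsa-miR-139-3p	3.87503	2.31779	5.287530258	3.162655452
hsa-miR-423-5p	5484.82	3592.57	5.221947179	3.420387684
hsa-let-7f-5p	29803.4	20292.6	4.887141234	3.327566727
hsa-miR-1284	1.42464	0.52978	4.859847516	1.807228505
hsa-miR-3613-5p	3.47613	1.72179	4.743225873	2.349405482
hsa-miR-3120-3p	0.341914	0.132445	4.665462256	1.807229738
hsa-miR-4436b-3p	1.70957	1.12578	4.665462256	3.072283731
hsa-miR-4501	0.341914	0.728448	4.665462256	9.93977038
hsa-miR-497-3p	0.341914	0.331113	4.665462256	4.518081167
hsa-miR-544a	0.341914	0.132445	4.665462256	1.807229738
hsa-miR-664b-5p	0.341914	0.331113	4.665462256	4.518081167
hsa-miR-6862-5p	0.341914	0.26489	4.665462256	3.614459475
hsa-miR-7107-3p	0.341914	0.26489	4.665462256	3.614459475
hsa-miR-6816-3p	1.02574	0.596003	4.665444671	2.710841949
hsa-let-7a-5p	29230.6	20145.4	4.632835878	3.19289826
hsa-miR-210-3p	66.5023	47.8789	4.606251818	3.316310416
hsa-miR-3145-3p	0.626843	0.397335	4.276689954	2.710852004
hsa-miR-3675-5p	0.626843	0.596003	4.276689954	4.066281418
hsa-miR-6515-5p	1.1967	0.662225	4.0822801	2.259035631
hsa-miR-6797-5p	0.569857	0.397335	3.887898098	2.710852004
hsa-miR-3183	0.284929	0.26489	3.88789431	3.614459475
hsa-miR-372-3p	0.284929	0.728448	3.88789431	9.93977038
hsa-miR-4488	0.284929	0.198668	3.88789431	2.710851429
hsa-miR-6797-3p	0.284929	0.198668	3.88789431	2.710851429
hsa-miR-548ar-3p	0.142464	0.132445	3.887880665	3.614459475
hsa-miR-6511b-3p	2.29842	1.2803	3.763465686	2.096381478
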