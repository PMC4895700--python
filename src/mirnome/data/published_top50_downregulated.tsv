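name	rpm_kapb_cmyc	rpm_kapb	fold_cmyc_kapb_vs_vec	fold_kapb_vs_vec
hsa-miR-3614-5p	25.7006	35.6277	0.117247798	0.162535869
hsa-miR-548f-5p	0.0121636	0.0245914	0.124207975	0.251113814
hsa-miR-4723-5p	0.0569857	0.0662225	0.129596309	0.150602547
hsa-miR-9-5p	2.10847	7.9467	0.139661522	0.526376101
hsa-miR-412-3p	0.170957	0.728448	0.145795596	0.621235225
hsa-miR-4484	0.0569857	0.0662225	0.1555155	0.180722974
hsa-miR-7844-5p	0.0569857	0.0662225	0.1555155	0.180722974
hsa-miR-3679-5p	0.0569857	0.198668	0.1555155	0.542170286
hsa-miR-4523	0.0569857	0.198668	0.1555155	0.542170286
hsa-miR-489-3p	0.170957	0.331113	0.155515833	0.301206233
hsa-miR-610	0.113971	0.198668	0.172794341	0.301205623
hsa-miR-548c-3p	0.07978	0.158934	0.209347972	0.417053279
hsa-miR-676-5p	0.170957	0.463558	0.212066256	0.575027693
hsa-miR-4485-3p	10.7703	26.3566	0.218044778	0.5335895
hsa-miR-570-3p	0.341914	0.596003	0.222164898	0.38726389
hsa-miR-891a-5p	0.455886	0.331113	0.222165584	0.161360325
hsa-miR-1271-5p	7.29417	17.2179	0.230927551	0.545104855
hsa-miR-3917	0.170957	0.397335	0.233273113	0.542168921
hsa-miR-5582-3p	0.455886	0.662225	0.239254975	0.347544399
hsa-miR-4284	2.84929	5.56269	0.241483672	0.471450365
hsa-miR-5091	0.113971	0.132445	0.259191707	0.301205093
hsa-miR-4720-5p	0.113971	0.198668	0.259191707	0.451808777
hsa-miR-144-3p	0.0569857	0.0662225	0.259192028	0.301204408
hsa-miR-3126-5p	0.0569857	0.132445	0.259192028	0.602408817
hsa-miR-3192-3p	0.0569857	0.132445	0.259192028	0.602408817
hsa-miR-4485-5p	0.0569857	0.132445	0.259192028	0.602408817
hsa-miR-1296-3p	0.227943	0.331113	0.25919255	0.376506507
hsa-miR-4521	3.47613	5.82758	0.269500868	0.451806426
hsa-miR-146a-3p	1.65259	2.78135	0.285440643	0.480403689
hsa-miR-7-5p	1.88053	2.45023	0.309157356	0.402815498
hsa-miR-4477b	0.0569857	0.0331113	0.31103015	0.180722753
hsa-miR-6733-5p	0.170957	0.132445	0.333246914	0.258175375
hsa-miR-548ab	0.372501	0.727659	0.335290464	0.654970387
hsa-miR-548 h-3p	0.487736	0.725844	0.337793045	0.502700344
hsa-miR-548z	0.487736	0.725844	0.337793045	0.502700344
hsa-miR-548b-5p	0.250673	0.433284	0.341223938	0.589799749
hsa-miR-200c-3p	0.227943	0.364224	0.345590197	0.552209298
hsa-miR-134-3p	0.7978	0.728448	0.351164459	0.320638065
hsa-miR-7705	10.0295	11.9863	0.372897929	0.445651972
hsa-miR-663a	0.113971	0.0662225	0.388787119	0.225903563
hsa-miR-301b-5p	0.170957	0.26489	0.388788698	0.602410187
hsa-miR-942-3p	0.284929	0.331113	0.388789431	0.451808117
hsa-miR-34b-3p	0.0569857	0.0662225	0.38878981	0.451808667
hsa-miR-6508-5p	0.0569857	0.0662225	0.38878981	0.451808667
hsa-miR-6510-3p	0.0569857	0.0662225	0.38878981	0.451808667
hsa-miR-548aj-5p	0.155689	0.149897	0.390962282	0.376417558
hsa-miR-548 g-5p	0.155689	0.149897	0.390962282	0.376417558
hsa-miR-548x-5p	0.155689	0.149897	0.390962282	0.376417558
hsa-miR-3944-3p	0.683829	0.728448	0.405693589	0.432164596
hsa-miR-153-3p	0.3989	0.0662225	0.418695505	0.069508807
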