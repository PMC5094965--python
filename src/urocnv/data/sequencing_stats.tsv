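sample_id	raw_reads	mappable_reads	percent_mapped	reads_per_60kb
1001U2	8559863	7780937	90.90	151
1002U1	5834360	5359747	91.87	104
1002U2	6905307	6218374	90.05	120
1003U1	8466006	6717216	79.34	130
1003U2	8249703	6668418	80.83	129
1004U1	5695192	5239912	92.01	101
1004U2	6523691	6056921	92.85	117
1005U1	8028779	7146997	89.02	138
1010U1	6941555	6376244	91.86	123
1010U2	8066311	7392163	91.64	143
1014U1	5925269	5434275	91.71	105
1014U2	5709509	5264081	92.20	102
1015U1	6757096	6173896	91.37	119
1015U2	5082468	4680443	92.09	91
1017U1	7268083	6383512	87.83	124
1017U2	8751507	7962944	90.99	154
1028U1	4366638	3758949	86.08	73
1028U2	6505105	5927164	91.12	115
1040U1	7715099	6887111	89.27	133
1040U2	8481528	7888688	93.01	153
1050U1	6635918	6006158	90.51	116
1043U1	7398308	6791284	91.80	131
1050U2	10320989	9167473	88.82	177
1059U1	15250498	14061397	92.20	272
1059U2	6303913	5865752	93.05	114
1060U1	10515071	9691459	92.17	188
1060U2	7294862	6713772	92.03	130
1080U1	9525919	8793277	92.31	170
1080U2	8771271	7816538	89.12	151
1084U1	10930339	10145924	92.82	196
1098U2	7507997	5835747	77.73	113
1104U1	5670174	5231642	92.27	101
1104U2	7542611	6868682	91.07	133
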