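symbol	pathway_entries	pathway_description	count
1a	hsa01100	Metabolic pathways	57
1b	hsa04151	PI3K-Akt signaling pathway	16
1c	hsa05200	Pathways in cancer	16
1d	hsa05010	Alzheimer's disease	13
1e	hsa04010	MAPK signaling pathway	13
1f	hsa05016	Huntington's disease	12
1g	hsa04510	Focal adhesion	12
1h	hsa00280	Valine, leucine, and isoleucine degradation	11
1i	hsa05012	Parkinson's disease	11
1j	hsa00190	Oxidative phosphorylation	11
1k	hsa04974	Protein digestion and absorption	10
1l	hsa03010	Ribosome	9
1m	hsa04810	Regulation of actin cytoskeleton	9
2a	hsa05012;hsa05016	Parkinson's disease and Huntington's disease	11
2b	hsa05010;hsa05012	Alzheimer's disease and Parkinson's disease	11
2c	hsa00190;hsa05010	Oxidative phosphorylation and Alzheimer's disease	11
2d	hsa00190;hsa05012	Oxidative phosphorylation and Parkinson's disease	11
2e	hsa05010;hsa05016	Alzheimer's disease and Huntington's disease	11
2f	hsa00190;hsa05016	Oxidative phosphorylation and Huntington's disease	11
3a	hsa00190;hsa05012;hsa05016	Oxidative phosphorylation, Parkinson's disease, and Huntington's disease	11
3b	hsa00190;hsa05010;hsa05016	Oxidative phosphorylation, Alzheimer's disease, and Huntington's disease	11
3c	hsa00190;hsa05010;hsa05012	Oxidative phosphorylation, Alzheimer's disease, and Parkinson's disease	11
3d	hsa05010;hsa05012;hsa05016	Alzheimer's disease, Parkinson's disease, and Huntington's disease	11
4a	hsa00190;hsa05010;hsa05012;hsa05016	Oxidative phosphorylation, Alzheimer's disease, Parkinson's disease, and Huntington's disease	11
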