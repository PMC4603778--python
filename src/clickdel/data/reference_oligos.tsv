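# Reference oligonucleotide set used to characterize polymerase read-through
# of triazole backbone junctions (vendor-style notation; reported average MW, Da).
# Oligo 1's reported mass corresponds to the 18-residue segment that appears in
# the ligated products (rows 3/7/8) rather than to its listed 17-residue
# sequence; masses here are always computed from the listed sequence.
id	sequence	reported_mw	notes
1	5'-NH2-C6-TCG AAT GAC TCC GTA TrG-3'-Propargyl	5732	aldehyde-side fragment; amino linker for labelling
2	5'-azido-TAT AGC GCG ATA TAC ACA CTG GCG AGC TTG CGT ACT G	11414	37-mer azide-side fragment
3	5'-Biotin-PEG4-CONH-C6-TCG AAT GAC TCC GAT ATrG^tr^ TAT AGC GCG ATA TAC ACA CTG GCG AGC TTG CGT ACT G	17619	single-triazole template, biotin-labelled
4	5'-Cy5-CAG TAC GCA AGC TCG	5095	labelled extension primer
5	5'-Cy5-CAG TAC GCA AGC TCG CCA GTG TGT ATA TCG CGC TAT A	11882	stalled extension product (stops at the triazole)
6	5'-Cy5-CAG TAC GCA AGC TCG CCA GTG TGT ATA TCG CGC TAT ACA TAT CGG AGT CAT TCG A	17443	full-length extension product
7	5'-Biotin-PEG4-CONH-C6-TCG AAT GAC TCC GAT ATrG TAT AGC GCG ATA TAC ACA CTG GCG AGC TTG CGT ACT G	17811	all-phosphodiester control template
8	5'-Biotin-PEG4-CONH-C6-TCG AAT GAC TCC GAT AT rG^tr^TAC ACA CTG GCG AGC TTG CGT ACT G	13463	short-run-up single-triazole template
9	5'-Biotin-TEG-spacerC3-spacerC3-TCG AAT GAC TCC GAT AT rG^tr^T ATG CGT ACA GTC C U^tr^T ATA GCG CGA TAT ACA CAC TGG CGA GCT TGC GTA CTG	22235	double-triazole template
10	5'-Biotin-TEG-spacerC3-spacerC3-TCG AAT GAC TCC GAT AT rG^tr^T ATG CGT ACA GTC C U^tr^T ATG CGT ACA GTC C U^tr^T ATA GCG CGA TAT ACA CAC TGG CGA GCT TGC GTA CTG	26848	triple-triazole template
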