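# Curation overrides for the 26 Quercus chloroplast RefSeq genomes.
# One override per line: accession  action  payload
#
# Q. rubra: the feature annotated "psi" is the psbB gene.
NC_020152.1	rename_gene	psi	psbB
# Q. coccinea: ndhJ is misannotated at 61,506..62,009 (inside rbcL);
# the real gene sits at 54,531..55,007 on the minus strand (the conserved
# ndhC-ndhK-ndhJ operon orientation).
NC_047481.1	replace_coordinates	ndhJ	54531..55007:-1
# Q. wutaishanica (NC_043857.1): only one rps12 copy is annotated; no
# override is needed because downstream filtering keeps a single copy of
# the IR-duplicated genes anyway.
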