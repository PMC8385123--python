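# Example immune-epitope list for wheat prolamin peptides.
# Columns: sequence <TAB> category <TAB> source_id
# The WDEIA entry is the omega-5-gliadin-derived anaphylaxis epitope;
# the remaining rows are literature defaults (Sollid-nomenclature DQ2.5
# 9-mer cores and the R5/G12 ELISA antibody recognition motifs), NOT a
# study-specific list: supply your own IEDB export for real analyses.
sequence	category	source_id
QILQQQLIPC	WDEIA	omega-5 gliadin
PFPQPQLPY	CD_HLA_DQ	DQ2.5-glia-alpha1a
PQPQLPYPQ	CD_HLA_DQ	DQ2.5-glia-alpha2
PQQSFPQQQ	CD_HLA_DQ	DQ2.5-glia-gamma1
QQPFP	R5	R5 mAb motif
QPQLPY	G12	G12 mAb motif
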