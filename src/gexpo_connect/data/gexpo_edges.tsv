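# GEXPO reference ontology, transcribed as a flat edge list.
# One edge per line: subject<TAB>relation<TAB>object. Lines starting with '#'
# are comments. Every concept other than the root `thing` carries at least
# one is_a edge, so the whole concept set is recoverable from the edges.
#
# -- gene expression process --
biological_process	is_a	thing
gene_expression	is_a	biological_process
transcription	is_a	biological_process
rna_processing	is_a	biological_process
translation	is_a	biological_process
protein_maturation	is_a	biological_process
transcription	part_of	gene_expression
rna_processing	part_of	gene_expression
translation	part_of	gene_expression
protein_maturation	part_of	gene_expression
rna_processing	preceded_by	transcription
translation	preceded_by	rna_processing
protein_maturation	preceded_by	translation
gene	is_a	thing
dna	is_a	thing
primary_transcript	is_a	thing
mature_transcript	is_a	thing
protein	is_a	thing
ncrna	is_a	mature_transcript
mrna	is_a	mature_transcript
primary_transcript	produced_by	transcription
transcription	has_participant	gene
rna_processing	has_participant	primary_transcript
mature_transcript	produced_by	rna_processing
protein	produced_by	translation
translation	has_participant	mrna
protein_maturation	has_participant	protein
#
# -- gene expression measurement process --
biological_experimental_process	is_a	thing
experimental_condition	is_a	thing
biological_experimental_process	affected_by	experimental_condition
gene_expression_measurement	is_a	biological_experimental_process
hybridization_based_gene_expression_measurement	is_a	gene_expression_measurement
sequencing_based_gene_expression_measurement	is_a	gene_expression_measurement
dna_microarray_experimental_process	is_a	hybridization_based_gene_expression_measurement
one_color_microarray_experimental_process	is_a	dna_microarray_experimental_process
two_color_microarray_experimental_process	is_a	dna_microarray_experimental_process
rna_seq_experimental_process	is_a	sequencing_based_gene_expression_measurement
gene_expression_value	is_a	thing
gene_expression_value	quantifies	gene
fluorescence_intensity_based_value	is_a	gene_expression_value
sequence_counting_based_value	is_a	gene_expression_value
absolute_intensity_based_value	is_a	fluorescence_intensity_based_value
ratio_intensity_based_value	is_a	fluorescence_intensity_based_value
absolute_intensity_based_value	produced_by	one_color_microarray_experimental_process
ratio_intensity_based_value	produced_by	two_color_microarray_experimental_process
cdna_reads_counting_based_value	is_a	sequence_counting_based_value
cdna_reads_counting_based_value	produced_by	rna_seq_experimental_process
absolute_cdna_reads_counting_based_value	is_a	cdna_reads_counting_based_value
relative_cdna_reads_counting_based_value	is_a	cdna_reads_counting_based_value
#
# -- DNA microarray experimental process --
microarray_manufacturing	is_a	biological_experimental_process
microarray_washing	is_a	biological_experimental_process
microarray_image_acquisition	is_a	biological_experimental_process
microarray_gene_expression_profiling	is_a	biological_experimental_process
rna_extraction	is_a	biological_experimental_process
reverse_transcription	is_a	biological_process
cdna_labeling	is_a	biological_experimental_process
hybridization	is_a	biological_process
microarray_manufacturing	part_of	dna_microarray_experimental_process
microarray_washing	part_of	dna_microarray_experimental_process
microarray_image_acquisition	part_of	dna_microarray_experimental_process
microarray_gene_expression_profiling	part_of	dna_microarray_experimental_process
dna_microarray_experimental_process	has_part	rna_extraction
dna_microarray_experimental_process	has_part	reverse_transcription
dna_microarray_experimental_process	has_part	cdna_labeling
dna_microarray_experimental_process	has_part	hybridization
probe	is_a	dna
cdna	is_a	dna
microarray_image	is_a	thing
microarray_manufacturing	has_participant	probe
rna_extraction	has_participant	mature_transcript
cdna	produced_by	reverse_transcription
reverse_transcription	has_participant	mature_transcript
cdna_labeling	has_participant	cdna
microarray_gene_expression_profiling	has_participant	microarray_image
cdna_labeling	preceded_by	reverse_transcription
microarray_washing	preceded_by	hybridization
microarray_image_acquisition	preceded_by	microarray_washing
microarray_gene_expression_profiling	preceded_by	microarray_image_acquisition
#
# -- RNA-Seq experimental process --
rna_seq_gene_expression_profiling	is_a	biological_experimental_process
cdna_library_with_adaptors_preparation	is_a	biological_experimental_process
cdna_next_generation_sequencing	is_a	biological_experimental_process
alignment_of_cdna_read_to_a_reference_genome	is_a	biological_experimental_process
de_novo_assembly_of_cdna_reads	is_a	biological_experimental_process
cdna_read	is_a	thing
reference_genome	is_a	thing
rna_seq_gene_expression_profiling	part_of	rna_seq_experimental_process
rna_seq_experimental_process	has_part	rna_extraction
rna_seq_experimental_process	has_part	reverse_transcription
rna_seq_experimental_process	has_part	cdna_library_with_adaptors_preparation
rna_seq_experimental_process	has_part	cdna_next_generation_sequencing
rna_seq_experimental_process	has_part	alignment_of_cdna_read_to_a_reference_genome
rna_seq_experimental_process	has_part	de_novo_assembly_of_cdna_reads
cdna_library_with_adaptors_preparation	has_participant	cdna
cdna_next_generation_sequencing	has_participant	cdna
cdna_read	produced_by	cdna_next_generation_sequencing
cdna_read	derives_from	cdna
alignment_of_cdna_read_to_a_reference_genome	has_participant	cdna_read
alignment_of_cdna_read_to_a_reference_genome	has_participant	reference_genome
de_novo_assembly_of_cdna_reads	has_participant	cdna_read
rna_seq_gene_expression_profiling	has_participant	cdna_read
cdna_library_with_adaptors_preparation	preceded_by	reverse_transcription
# The two preceded_by edges below are mutually exclusive alternatives
# (alignment-to-reference XOR de novo assembly); see CHOICE_GROUPS in the
# ontology module.
rna_seq_gene_expression_profiling	preceded_by	alignment_of_cdna_read_to_a_reference_genome
rna_seq_gene_expression_profiling	preceded_by	de_novo_assembly_of_cdna_reads
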