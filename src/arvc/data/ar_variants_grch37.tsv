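# Androgen receptor (AR) splice-variant definition table, GRCh37.
# The reference row is the canonical AR exon 1 -> exon 2 splice junction
# (intron-anchored, 1-based: donor = first intronic base, acceptor = last).
# Variant rows are PLACEHOLDERS: the distinctive cryptic-exon junction
# coordinates differ between annotation sources and must be filled in by
# the user for a real-data run (role=defining-primary with coordinates).
# Rows with role=none declare a variant with no usable distinctive
# junction; such variants are carried in the compendium but exempt from
# quantification (AR-V11 has no distinctive junction by construction).
name	chrom	donor	acceptor	strand	genome_build	role
AR	chrX	66766605	66863097	+	GRCh37	reference
AR-V1	chrX			+	GRCh37	none
AR-V3	chrX			+	GRCh37	none
AR-V7	chrX			+	GRCh37	none
AR-V9	chrX			+	GRCh37	none
AR23	chrX			+	GRCh37	none
AR45	chrX			+	GRCh37	none
AR-V11	chrX			+	GRCh37	none
AR-V2	chrX			+	GRCh37	none
AR-V4	chrX			+	GRCh37	none
AR-V5	chrX			+	GRCh37	none
AR-V6	chrX			+	GRCh37	none
AR-V8	chrX			+	GRCh37	none
AR-V10	chrX			+	GRCh37	none
AR-V12	chrX			+	GRCh37	none
AR-V13	chrX			+	GRCh37	none
AR-V14	chrX			+	GRCh37	none
AR-V567es	chrX			+	GRCh37	none
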