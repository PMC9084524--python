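# Synthetic donor -> TSS-class map for mouse Mbnl3 (stand-in annotation).
# Numbered donors upstream of the shared reference acceptor (acceptor 11),
# coordinates on chrX, 1-based.  Only donor 3 (chrX:132413583, the
# eutherian-specific TSS donor) carries a published coordinate; the other
# coordinates are invented placeholders keeping realistic spacing.
# columns: donor_id  chrom  pos  class
0	chrX	132398210	ancestral_long
1	chrX	132399544	ancestral_short_skip
2	chrX	132410992	lineage_specific
3	chrX	132413583	eutherian_specific
4	chrX	132414871	eutherian_specific
5	chrX	132416230	lineage_specific
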