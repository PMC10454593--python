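# hg38 gene-body coordinates (1-based inclusive) for default gene-level event calling
chrom	start	end	name
chr10	87863625	87971930	PTEN
chr13	48303748	48599436	RB1
chr17	7668402	7687550	TP53
chrX	67544021	67730619	AR
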