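# Reference census for the LHE-encoding group II intron study system.
# section	category	count
dataset	total_introns	753
dataset	families	13
orf_status	intact_double	410
orf_status	intact_single	69
orf_status	degenerated	274
lineage	green_alga	78
lineage	fungus	613
lineage	bacterium	62
query_panel	total	100
query_panel	green_alga	66
query_panel	fungus	33
query_panel	bacterium	1
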