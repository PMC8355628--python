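# Example chimera junction-label table (synthetic intervals for the bundled
# 6 kb reference pair -- replace with locus-specific intervals from the
# literature for real assays, e.g. the CH1-CH9 convention for CYP21A2).
# Coordinates are gene-reference space, 0-based half-open.
#
# Assay fixture note: the single primer pair used for co-amplifying a
# gene/pseudogene locus in the motivating assay was
#   forward 5'-CAGAAAGCTGACTCTGGATGCAGG-3'
#   reverse 3'-AACTGCCACTACGCCAACCTCAAC-5'
# (documented here for provenance only; primers play no role in this tool).
label	ref_region	start	end
CH1	gene	0	1000
CH2	gene	1000	2000
CH3	gene	2000	3000
CH4	gene	3000	4000
CH5	gene	4000	5000
CH6	gene	5000	6000
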