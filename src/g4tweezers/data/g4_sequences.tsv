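# Reference panel of parallel G4-forming designs with a thymine bulge.
# Columns: name <TAB> sequence 5'->3' with space-separated G-tracts.
T30695	TTGGGT GGGT GGGT GGGT
TB-1	TTGTGGT GGGT GGGT GGGT
TB-2	TTGGTGT GGGT GGGT GGGT
TB-3	TTGGGT GTGGT GGGT GGGT
TB-4	TTGGGT GGTGT GGGT GGGT
TB-5	TTGGGT GGGT GTGGT GGGT
TB-6	TTGGGT GGGT GGTGT GGGT
TB-7	TTGGGT GGGT GGGT GTGGT
TB-8	TTGGGT GGGT GGGT GGTGT
T3B-1	TTGTTTGGT GGGT GGGT GGGT
T5B-1	TTGTTTTTGGT GGGT GGGT GGGT
T7B-1	TTGTTTTTTTGGT GGGT GGGT GGGT
T3B-8	TTGGGT GGGT GGGT GGTTTGT
T5B-8	TTGGGT GGGT GGGT GGTTTTTGT
T7B-8	TTGGGT GGGT GGGT GGTTTTTTTGT
T2B-2	TTGGTTGT GGGT GGGT GGGT
T3B-2	TTGGTTTGT GGGT GGGT GGGT
T5B-2	TTGGTTTTTGT GGGT GGGT GGGT
T7B-2	TTGGTTTTTTTGT GGGT GGGT GGGT
T2B-3	TTGGGT GTTGGT GGGT GGGT
T3B-3	TTGGGT GTTTGGT GGGT GGGT
T5B-3	TTGGGT GTTTTTGGT GGGT GGGT
T7B-3	TTGGGT GTTTTTTTGGT GGGT GGGT
T2B-4	TTGGGT GGTTGT GGGT GGGT
T2B-5	TTGGGT GGGT GTTGGT GGGT
T2B-6	TTGGGT GGGT GGTTGT GGGT
T2B-7	TTGGGT GGGT GGGT GTTGGT
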