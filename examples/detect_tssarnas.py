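"""Call TSSaRNAs on a synthetic genome and compare against the planted truth.

A TSSaRNA leaves a two-population signature at a gene's transcription start
site: many identical full-length small-RNA reads plus cognate-gene reads
truncated at assorted lengths, all sharing one 5' coordinate.  Detection
finds the dominant 5'-start near each start codon and splits the two
populations.
"""

from tssarna import calls_to_frame, default_plants, detect_all, emit_reads, make_genome

genes, _ = make_genome(n_genes=20, replicon_length=50_000, seed=1)
plants = default_plants(genes, seed=2)
reads, truth = emit_reads(genes, plants, noise_rate=2.0, seed=3)

result = detect_all(genes, reads)
table = calls_to_frame(result.calls)

print(table.head(8).to_string(index=False))
print(f"\n{len(result.calls)} TSSaRNAs called on {len(genes)} genes "
      f"from {len(reads)} reads (noise 2 reads/kb).")
print("Each row: the shared TSS, the TSSaRNA 3' end and length, how many "
      "identical full-length copies (tssarna_count) versus truncated "
      "cognate-gene reads (cognate_count) start there, and the signed "
      "distance of the TSS to the start codon (negative = upstream; near "
      "zero here because the planted transcripts are leaderless).")

recovered = sum(
    c.tss == truth.set_index("gene_id").loc[c.gene_id, "tss"] for c in result.calls
)
print(f"Planted TSS coordinates recovered exactly: {recovered}/{len(truth)}.")
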