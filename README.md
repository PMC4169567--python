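# tssarna

Detection, classification and modelling of **transcription-start-site-associated
small RNAs (TSSaRNAs)** from strand-specific small-RNA sequencing.

TSSaRNAs are small RNAs (tens of nucleotides) whose 5′ ends coincide with the
transcription start site (TSS) of an annotated gene — their *cognate gene*.
In libraries built from non-fragmented small RNA, a TSSaRNA leaves a
characteristic two-population signature at a single genomic coordinate: an
abundant species of *identical* reads (the full-length TSSaRNA) superimposed
on cognate-gene reads truncated at assorted lengths, all sharing the same
5′ start.  This package, written with leaderless archaeal transcriptomes in
mind but generic over any strand-specific alignment set, provides:

- **`tssarna.io`** — GFF3/CDS-table annotation and BED6/SAM/BAM read ingest
  (0-based half-open internally), and strand-aware read 5′-**start profiles**;
- **`tssarna.detect`** — TSSaRNA calling: in a window from 50 bp upstream of
  each start codon to 20 % of the CDS length, find the most frequent read
  5′ start (> 20 reads); the most abundant read species < 151 nt there is the
  TSSaRNA full-length sequence (kept if ≥ 10 copies), all other co-starting
  reads belong to the cognate gene;
- **`tssarna.primary`** — primary-transcript classification from a
  TEX+/TEX− dRNA-seq pair: with depth-normalized counts *n±* at the TSS, a
  call is primary when *n₊/(n₊+n₋) ≥ 0.95*;
- **`tssarna.diffexp`** — tiling-array differential expression: with
  *M = log₁₀(I_t/I_ref)*, the statistic *V(t) = M_TSSaRNA − M_cognate* must
  satisfy |V| ≥ 1 (10-fold) at the time point with the **second** largest
  |V|, plus a 2-fold criterion against an upstream control region;
- **`tssarna.polsim`** — a deterministic RNA-polymerase pausing/traffic
  model of TSSaRNA biogenesis: initiation every Δτ time units, site-specific
  stall times Δt, and immediate collision-triggered termination one bp
  behind a stalled polymerase, with exact closed-form steady-state rates,
  (Δτ, Δt) parameter scans and growth-curve rhythm simulation;
- **`tssarna.synth`** — seeded generators for toy genomes, planted TSSaRNA
  read populations, TEX pairs and probe matrices, each with a truth table.

## Worked example

`examples/` holds one narrative script per capability.  The biogenesis
model (`python examples/pausing_model.py`) prints:

```
Truncated-length bands: [26, 62, 90, 106]
Band counts: {26: 10615, 62: 590, 90: 197, 106: 65}
...
dt=250, dtau=4 vs dtau=84: full-length rates 0.003968 vs 0.003968 (equal),
truncated fold 31.0 (~2^5): TSSaRNA output varies ~32-fold while the
cognate gene is constant.
dt=46, dtau=12 vs dt=14, dtau=8: cognate fold 3.00 with truncated rates
0.0625 vs 0.0625: the cognate gene varies ~3-fold while TSSaRNA output is
constant.
```

Pauses at positions 27/63/91/107 with increasing retention times produce
truncated transcripts exactly one bp behind each pause — the multi-band
pattern seen on small-RNA northern blots — and varying only (Δτ, Δt)
decouples TSSaRNA output from cognate-gene output in either direction.
`examples/detect_tssarnas.py`, `examples/classify_primary.py` and
`examples/differential_expression.py` run the analysis pipeline on planted
synthetic data and report exact truth recovery (20/20 TSSaRNAs, 12/20
primary, 6/20 differentially expressed in the default scenes).

The same pipeline is scriptable from the shell:

```bash
tssarna synth reads --seed 1 --outdir fix
tssarna detect --annotation fix/genes.gff3 --reads fix/reads.bed --out calls.tsv
tssarna classify --calls calls.tsv --tex-plus plus.bed --tex-minus minus.bed --out primary.tsv
tssarna de --calls calls.tsv --probes probes.tsv --annotation fix/genes.gff3 --out de.tsv
tssarna polsim --config sim.yaml --out census.tsv
```

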