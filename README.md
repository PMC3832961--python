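# panelforge

Design and evaluate degenerate PCR primer panels for gene families, and
classify the amplicon sequences they recover.

The toolkit covers the full loop used in functional-gene amplicon
surveys of large, divergent gene families (the motivating use case is
reductive dehalogenase genes):

1. **`family_grouping`** — partition a gene-family phylogeny (Newick +
   master nucleotide alignment) into primer-design groups using
   branch-length (patristic) or percent-identity constraints. The
   partition is a deterministic post-order merge that returns the
   minimum number of constraint-satisfying clades.
2. **`primer_engine`** — per-group degenerate IUPAC consensus primers,
   screened with nearest-neighbor thermodynamics (unified NN table,
   entropic salt correction): annealing-temperature window 40–65 °C over
   all expansions, hairpin Tm ≤ 25 °C, and worst primer-dimer ΔG at most
   one third of the weaker primer's full-duplex ΔG.
3. **`insilico_pcr`** — binding-site search and amplicon prediction in
   perfect-match or mismatch-tolerant mode (IUPAC-vs-IUPAC set
   semantics, 3′-clamp rule), plus panel-wide screening matrices.
4. **`amplicon_pipeline`** — read trimming and complexity filtering,
   contig length gates (>250 / >500 bp), six-frame translation,
   best-hit classification into primer groups (in-repo affine-gap
   aligner standing in for BLAST), midpoint chimera screening, ≥90%-PID
   ortholog typing with novelty bins, and ordered cross-sample
   distribution tables.
5. **`synthetic_family`** — seeded simulators for gene families with
   conserved primer-able blocks, mixed samples with decoys and
   chimeras, and padded fixed-length reads, so everything above is
   testable offline.
6. **`seqio`** — FASTA/FASTQ/Newick/panel-TSV readers and writers with
   validated in-memory records.

## CLI

All stages are exposed via one `panelforge` entry point:

```sh
panelforge simulate --config family.yaml --seed 1 --outdir fixtures/
panelforge group    --alignment aln.fasta --tree tree.nwk \
                    --metric patristic --max-within 2.0 --out groups.tsv
panelforge design   --groups groups.tsv --alignment aln.fasta \
                    --config thermo.yaml --seed 1 --out panel.tsv
panelforge screen   --panel panel.tsv --targets seqs.fasta \
                    --mode tolerant --max-mm 2 --clamp 3 --out hits.tsv
panelforge classify --contigs S1.fasta --contigs S2.fasta \
                    --refdb refs.fasta --groups groups.tsv --out hits.tsv
panelforge cluster  --proteins p.fasta --labels labels.tsv \
                    --threshold 90 --out types.tsv
panelforge distribution --types types.tsv --samples S1,S2,S3 \
                    --genomes G1,G2 --out matrix.tsv
```

The panel TSV has the fixed header
`group_id  fwd_seq  rev_seq  tm_min_c  tm_max_c  expected_len_bp`
(floats to two decimals) and round-trips byte-identically. Identical
seeds give byte-identical outputs across the whole pipeline.

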