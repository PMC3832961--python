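Worked-example sequence data (plain FASTA, fetched from NCBI GenBank).

Expected files (nucleotide amplicon record + characterized reference
protein for the three homolog worked examples):

  KF138765.fasta   deposited amplicon (nucleotide)
  KF138603.fasta   deposited amplicon (nucleotide)
  KF138991.fasta   deposited amplicon (nucleotide)
  AAQ94119.fasta   VcrA protein, Dehalococcoides mccartyi VS
  AAT64888.fasta   BvcA protein, Dehalococcoides mccartyi BAV1
  AAF73916.fasta   TceA protein, Dehalococcoides mccartyi 195

These records could not be vendored at build time because the build
environment had no route to NCBI. To enable the worked examples, fetch
each accession as FASTA (e.g. via NCBI efetch) and drop the files here
under the names above; `scripts/acceptance.py` and the corresponding
acceptance test pick them up automatically.
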