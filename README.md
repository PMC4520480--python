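# mitoprofile

Comparative characterization of annotated insect mitochondrial genomes:

- **I/O** — GenBank flat files, FASTA, and plain TSV gene-organization
  tables, with a bundled gene-name synonym table (`CO1`/`COI`/`cox1` →
  `COX1`, `tRNA-Ser(AGN)` → `trnS1`, ...).
- **Annotation metrics** — gene order vs. the ancestral insect arrangement,
  overlap/spacer/abutting junction censuses, start/stop codon
  classification (including partial `T`/`TA` stops), ORF validation under
  the invertebrate mitochondrial code, and base-pair typing
  (Watson–Crick / G-U wobble / mismatch) for dot-bracket structures.
- **Composition statistics** — strand-, gene-class- and
  codon-position-resolved base composition, A+T/G+C percentages,
  AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), codon usage, and
  cross-species aggregation.
- **Supermatrix builder** — the four concatenation schemes PCG123,
  PCG123RNA, PCG12, PCG12RNA with per-codon-position/per-RNA-gene
  charsets, exported as FASTA, relaxed PHYLIP, NEXUS sets block, RAxML
  partition file and a PartitionFinder configuration stub.
- **Synthetic generator** — seeded, byte-reproducible 37-gene circular
  mitogenomes in the ancestral gene order with controlled per-class
  composition, exact junction structure (e.g. the 7-bp ATP8/ATP6 overlap
  and a 27-bp TA-repeat spacer), specified start/stop codons, clean ORFs,
  and ground-truth manifests — so the whole pipeline is testable offline.

## CLI

```sh
# synthetic genome + manifest (seed required for reproducibility)
mitoprofile simulate --seed 42 --out out/sim

# composition/skew profiles + cross-species aggregate
mitoprofile profile genome1.gb genome2.gb --out out/profiles

# feature-table input works too (TSV: name, start, end, strand; 1-based)
mitoprofile junctions --table genes.tsv --fasta genome.fasta --out out/qc

# partitioned supermatrix from per-gene aligned FASTA files
mitoprofile matrix alignments/*.fasta --scheme PCG123RNA --out out/matrix
```

Exit codes reflect parse/IO success only; biological QC anomalies
(partial stops, overlaps, anomalous gene termini) are report content.

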