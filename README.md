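# ibcrispr

Guide design and screen analysis for a type I-B CRISPR-Cas system whose
activity switches with crRNA spacer length: spacers of ≤26 nt direct
transcriptional repression (truncated guide RNAs, "tgRNAs") while spacers of
≥27 nt direct DNA cleavage. The toolkit covers:

- **Genome I/O** — GenBank or FASTA+GFF3 in, 0-based half-open internal
  coordinates, circular topologies with origin-wrapping intervals
  (`ibcrispr.genome_io`).
- **PAM engine** — scanning for the 3-nt TTA core PAM (permissive set
  TTA/CTA/TCA/TTG/TTT; the −5/−4 positions are unconstrained), saturation
  enumeration of PAM variants, position frequency matrices, and
  substitution-only spacer-vs-target matching (`ibcrispr.pam`).
- **Guide design** — genome-scale tgRNA libraries (20-mer spacers, template
  strand, one guide per positional third of each gene), truncation series,
  and editing designs (cleavage-length spacer + homology arms with a
  post-deletion immunity check) (`ibcrispr.design`).
- **Off-target search** — exhaustive both-strand Hamming scan with a
  PAM-class-aware pass/fail policy (`ibcrispr.offtarget`).
- **Construct assembly** — Golden-Gate oligos (BsaI/Esp3I), Type IIS
  digestion simulation, and multiplex repeat–spacer mini-CRISPR arrays
  (`ibcrispr.assembly`).
- **Screen analysis** — anchored tgRNA counting from FASTQ, exact binomial
  enrichment with BH-FDR, and top-k hit calling (`ibcrispr.screen`).
- **Synthetic data** — seeded annotated micro-genomes with planted PAM
  sites and spike-in screen FASTQs with per-read provenance
  (`ibcrispr.simulate`).

## CLI

```sh
ibcrispr --config config.yaml design genome.gb -o library/       # tgRNA library
ibcrispr scan genome.gb -o sites.tsv                             # PAM sites
ibcrispr edit genome.gb --gene LOCUS_TAG -o editing/             # deletion design
ibcrispr --config config.yaml assemble library/library.tsv -o oligos/
ibcrispr --config config.yaml assemble five.tsv --mode array -o array/
ibcrispr simulate screen -o sim/ --library-size 1000 --depth 1000000
ibcrispr count sim/baseline.fastq sim/library.tsv -o baseline.tsv
ibcrispr enrich baseline.tsv selected.tsv -o enrichment.tsv --top-k 6
```

The YAML config supplies sequences that are experiment-specific and have no
sensible defaults (the CRISPR repeat for arrays, priming flanks and
overhangs for oligos) plus model overrides:

```yaml
repeat: GTTGCAAACCTATGAGGAATTGAAAC     # your array repeat
flanks:
  prime5: ACCTGTTCGACAGTCAGTCA
  prime3: TGCTGACTGTCGAACAGGTT
  enzyme: BsaI
  overhang5: AACA
  overhang3: GTTT
pam: {core: TTA, permissive_set: [TTA, CTA, TCA, TTG, TTT]}
design: {repression_len: 20, cleavage_len: 30, bins: 3}
offtarget: {max_mm_reject: 1, pam_scope: permissive_set}
screen: {anchor5: ACCTCGTTCAGGATAC, pseudocount: 0.5, alpha: 0.05}
```

Every run writes a `<command>.run.json` with the resolved config and input
checksums; identical config + inputs give byte-identical outputs.

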