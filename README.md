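# epidrs

Differential epitranscriptome analysis for nanopore direct-RNA sequencing
(DRS) data, plus a seeded synthetic-data generator so the whole pipeline can
be exercised and validated at desk scale.

The pipeline takes per-position modification tables (coverage and
modified-read counts per sample, importable from Tombo-style coverage and
fraction tracks), transcript sequences, ORF annotations, per-read poly(A)
length tables (nanopolish-polya-style TSV), and transcript/protein abundance
matrices, and produces:

- **diffmod** — per-position differential modification calls between two
  conditions: replicates pooled into a 2x2 table per position, a coverage
  filter (>= 50 reads per condition by default), a two-sided Fisher exact
  test, and a pseudocounted log2 fold change; positions with p < 0.05 and
  |log2FC| > 0.5 are classified over/under-modified
  (Benjamini–Hochberg gating available behind `--bh`).
- **m6a** — RRACH (R=A/G, H=A/U/C) site scanning, kmer frequency tables,
  area-normalized metagene profiles over the full transcript and over the
  5'UTR/CDS/3'UTR three-region axis, and differential m6A deposition at
  RRACH adenosines.
- **polya** — poly(A) QC-tag filtering (PASS by default), per-transcript and
  per-condition length summaries, and histograms.
- **integrate** — CPM normalization and expression filtering (>= 2 cpm in
  >= 2 samples), a per-condition Pearson correlation suite across the
  modification, m6A, abundance, poly(A) and protein layers, and the
  three-way significant-set overlap report.
- **synthetic** — a generator with planted ground truth (negative-binomial
  coverage, per-transcript baseline modification rates, treatment effects
  placed preferentially in 3'UTR RRACH sites, truncated-gamma poly(A)
  lengths and log-normal abundances with calibrated couplings to the
  modification ratio) and a truth ledger for recovery testing.

## CLI

```sh
# generate a synthetic bundle with planted effects
epidrs simulate --seed 7 --outdir sim/

# per-position differential modification calling
epidrs diffmod --modcalls sim/modcalls.tsv --conditions sim/conditions.tsv \
    --min-cov 50 --alpha 0.05 --lfc 0.5 --out diffmod.tsv

# RRACH/m6A analyses
epidrs m6a --fasta sim/sequences.fasta --annotations sim/annotations.tsv \
    --modcalls sim/modcalls.tsv --conditions sim/conditions.tsv --outdir m6a/

# poly(A) summaries
epidrs polya --polya-tsv sim/polya.tsv --conditions sim/conditions.tsv \
    --outdir polya/

# everything at once, from a flat config file
epidrs run --config run.yaml
```

`run.yaml` is a flat `key: value` file naming the inputs
(`modcalls`, `conditions`, optionally `fasta`, `annotations`, `polya`,
`counts`, `proteins`, `id_map`) plus thresholds and `outdir`; every stage
writes TSV outputs and a `run_report.json` with filter arithmetic,
thresholds, version and seed. Exit codes: 0 success, 2 validation error,
1 runtime error.

All positions in files are 1-based; internally everything is 0-based
half-open. Sequences are RNA (T is mapped to U on input).

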