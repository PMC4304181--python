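# sectorscan

Identify **protein sectors** — groups of co-evolving residues — from a
multiple sequence alignment via statistical coupling analysis, map them onto
a protein structure, annotate disease-associated mutations by sector and
region, and export structure-coloring artifacts for Jmol/PyMOL.

The pipeline:

1. **Curation** (`sectorscan curate`) — read an aligned FASTA with a
   designated reference sequence; drop low-quality/partial entries by header
   pattern; collapse redundant sequences (greedy single-linkage at 85%
   identity / 100% coverage by default); remove gap-heavy rows; trim columns
   outside the reference span; drop gapped columns (keeping a column index
   map). The reference row is immune to every removal filter.
2. **Coupling analysis** (`sectorscan sca`) — regularized positional and
   pairwise amino-acid frequencies; per-position conservation (binary
   relative entropy against a background distribution); conservation-
   gradient weights φ; the weighted covariance tensor reduced per position
   pair by Frobenius norm to an L×L coupling matrix; eigenvalue significance
   against a within-column-shuffle null (permutation test on the null top
   eigenvalue); fixed-point ICA rotation of the significant eigenvectors;
   sector definition by a fitted t-distribution loading cutoff with a
   dominance requirement. Sectors are labeled red, blue, green, … in
   eigenvalue rank order.
3. **Structure mapping** (`sectorscan map`) — align the ungapped reference
   to one chain of a PDB file (coordinate records, author numbering with
   insertion codes) and report coverage.
4. **Mutation annotation** (`sectorscan annotate`) — join a substitution
   table (G56A, R70TER, …) against sectors and a region scheme
   (N-terminal / central / C-terminal, user-configurable) into a report
   table.
5. **Visualization export** (`sectorscan viz`) — Jmol `.spt` / PyMOL `.pml`
   coloring scripts and a PDB copy with sector ordinals encoded in the
   B-factor field.
6. **Simulation** (`sectorscan simulate`) — planted-sector alignments
   (two-state latent emission model), i.i.d. null alignments and toy PDB
   files, so the whole pipeline is testable without any downloads.

## CLI walk-through on simulated data

```bash
sectorscan simulate --preset two-sector --seed 42 --out sim/
sectorscan curate   --alignment sim/alignment.fasta --reference REFERENCE \
                    --out curated.fasta --report report.tsv
sectorscan sca      --alignment curated.fasta --reference REFERENCE \
                    --n-rand 100 --seed 42 --out results/
sectorscan map      --alignment curated.fasta --reference REFERENCE \
                    --pdb sim/structure.pdb --chain A --out map.tsv
sectorscan annotate --mutations muts.tsv --sectors results/sectors.tsv \
                    --map map.tsv --out table.tsv
sectorscan viz      --pdb sim/structure.pdb --chain A \
                    --sectors results/sectors.tsv --map map.tsv \
                    --dialect jmol --out sectors.spt --pdb-out sectors.pdb
```

`results/` holds the coupling matrix, eigenvalue spectra (true and null),
the sequence-correlation diagnostic matrix, a sector table
(column / reference position / label / loading) and a bundled
`results.json`.

Mutation tables are TSV with a `substitution` column (HGVS-like short form;
`TER` or `*` for stop gains) and optional `phenotype` / `domain_label`
columns. Region schemes are YAML:

```yaml
regions:
  - {name: N-terminal, start: 28, end: 172}
  - {name: C-terminal, start: 173, end: 366}
```

When no scheme is given, tertiles of the mapped residue range are used and
flagged as a default.

## Notable defaults (all configurable)

- background amino-acid frequencies: standard database composition
  (`sectorscan.background.BACKGROUND_FREQS`)
- frequency regularization λ = 0.03 toward the background
- redundancy clustering: identity ≥ 0.85 and coverage = 1.0
- row gap filter 0.25, column gap filter 0.2 (no published values exist for
  these; they are explicit repo defaults)
- significance: n_rand = 100 column-shuffle trials, permutation p ≤ 0.05
  against the null top-eigenvalue distribution; `--exclude-top` discards
  the largest eigenvalue first for families whose top mode is a global
  conservation/phylogeny signal
- sector cutoff: 0.95 quantile of a t location-scale fit per component,
  with a 2× dominance requirement across components

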