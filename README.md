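# famforge

A tested, reusable pipeline for gene-family analysis: iterative
profile-based family discovery, conserved-site and C-terminal
domain-architecture characterization, duplicate-gene/tandem/Ka-Ks
evolutionary analysis, reciprocal-best-hit ortholog pairing,
expression normalization/clustering/screening, and disease-index phenotype
scoring — exercised end-to-end on truth-tagged synthetic proteomes, genomes,
count matrices and grade tables.

## Modules

| module | what it does |
| --- | --- |
| `famforge.synthetic_data` | planted-domain proteomes, duplicate CDS pairs evolved at a known dN/dS, negative-binomial count matrices with planted clusters and size factors, multinomial grade tables — all deterministic per seed with truth tables |
| `famforge.profile_search` | Smith–Waterman / Needleman–Wunsch engines (numba-compiled), PSSM construction with pseudocounts, empirical Gumbel E-value calibration, PSI-BLAST-style iterative expansion, CD-HIT-style greedy identity clustering |
| `famforge.domain_annot` | progressive MSA (k-mer UPGMA guide tree + profile–profile NW), conserved-site statistics (two most abundant non-gap residues per column), C-terminal domain architecture annotation with the FBXU fallback, per-species domain census |
| `famforge.evolution` | duplicate groups at 90% identity, tandem vs dispersed classification (200 kb rule, inclusive), Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction, selection summaries, RBH orthologs |
| `famforge.expression` | median-of-ratios size factors, complete-linkage Euclidean hierarchical clustering with deterministic tie-breaks, expression-breadth categories (tau statistic), 2^-ddCt fold changes |
| `famforge.phenotype` | morbidity and disease index over 0–4 grade tables |
| `famforge.io_cli` | strict FASTA/GFF3 readers and writers (0-based half-open internally), run configuration, the full pipeline and the `famforge` CLI |

## CLI

```bash
famforge synth family --out data/ --seed 1          # also: dups | expr | grades
famforge search --seed-msa data/seed_msa.fasta --proteome data/proteome.fasta \
    --evalue 1e-2 --inclusion 1e-2 --max-iter 10
famforge cluster --fasta domains.fasta --c 0.8
famforge domains --library data/ --hits hits.tsv --proteome data/proteome.fasta
famforge conserved --msa aligned.fasta
famforge dups --proteins prot.fasta --cds cds.fasta --gff genes.gff3 \
    --identity 0.9 --tandem-kb 200
famforge orthologs --a speciesA.fasta --b speciesB.fasta
famforge expr --counts counts.tsv --k 10 --scale zscore
famforge ddct --ct ct.tsv --calibrator control --reference Cyclophilin
famforge disease --grades grades.tsv
famforge run --config run.cfg --out results/   # full synthetic pipeline
```

`famforge run` executes synth → search → cluster → domains → conserved →
duplicates/Ka-Ks → orthologs → expression → phenotype and writes per-stage
TSV/JSON plus a manifest; reruns with the same config and seed are
byte-identical.

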