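# baitscout

Prioritization of bait interactors from IP-MS peptide tables and downstream
evaluation of the interactor gene signature: iBAQ label-free quantification
with background imputation, a three-criterion interactor filter,
over-representation and preranked gene-set enrichment analysis, and a
per-gene multi-cohort Cox survival screen with a two-cohort concordance
rule. Simulators with planted ground truth make every stage testable
offline.

## Pipeline stages

1. **io_formats** — readers/writers for peptide TSVs, FASTA, GMT,
   expression/survival cohort pairs, plus packaged reference tables
   (ranked interactor ratios, HSC-vs-AML expression medians, xenograft
   tumor-mass summaries).
2. **ibaq_quant** — in-silico tryptic digestion (cleave after K/R, not
   before P), theoretical-peptide counting over a configurable observable
   length window (default 7–30), and the complete protein × run iBAQ grid
   with undetected cells imputed to a background intensity of 1000.
3. **interactor_selection** — criteria: (i) ≥2 unique peptides,
   (ii) detection in ≥4 of the 6 bait IP runs, (iii) bait/control iBAQ
   ratio strictly >30 in *every* cell line; ranked output ordered by the
   first cell line's ratio.
4. **enrichment** — upper-tail hypergeometric ORA with Benjamini–Hochberg
   FDR (α = 0.05) and preranked GSEA (weighted KS running sum, gene-label
   permutation null, sign-pooled NES/FDR, q < 0.25).
5. **clinical_outcomes** — signature scoring (mean per-gene z),
   median dichotomization, univariate Cox PH (Newton ascent, Efron ties),
   log-rank test, the ≥2-cohort same-sign concordance call, Mann–Whitney
   differential expression, and small worked-example statistics.
6. **synthetic_data** — IP-MS experiments with log-normal intensities,
   bait enrichment shifts, contaminants and logistic intensity-dependent
   dropout; survival cohorts with a planted log-linear hazard; gene-set
   collections with one planted set.
7. **cli_pipeline** — `baitscout` CLI and the `run-all` orchestrator with
   per-stage derived seeds and a checksum manifest.

## CLI

```sh
baitscout simulate-ipms --n-proteins 40 --n-true 8 --seed 1 \
    --out-peptides pep.tsv --out-fasta db.fasta --out-truth truth.tsv
baitscout quantify --peptides pep.tsv --fasta db.fasta --out ibaq.tsv
baitscout select --ibaq ibaq.tsv --min-ratio 30 --out interactors.tsv
baitscout gsea --ranking scores.rnk --sets sets.gmt --perms 1000 --seed 7 --out gsea.tsv
baitscout run-all --config config.yaml
```

A `run-all` YAML config needs `seed`, `outdir`, and either a `simulate`
section or `inputs: {peptides: ..., fasta: ...}`; optional sections
`quant`, `selection`, `enrichment`, `clinical` override stage defaults
(see `tests/test_cli_pipeline.py::DEMO_CONFIG` for a worked example).
Identical config + seed reproduces identical artifact checksums.

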