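# xenostroma

Tumor/stroma deconvolution for patient-derived xenografts (PDXs), for
computational biologists studying how tumors reshape their
microenvironment. In a subcutaneous PDX the tumor cells are human and the
infiltrating stroma is mouse, so species-resolved analysis of bulk RNA-seq
and TMT proteomics turns the stroma into a directly measurable compartment.
The package implements the full analysis chain:

* **Species assignment** — a canonical k-mer classifier labels mixed reads
  human / mouse / ambiguous / unassigned and produces per-species
  gene-level count matrices plus a stroma-content statistic (mouse share of
  assigned reads).
* **Expression & differential testing** — log2(CPM+1) with pseudo-count 1,
  low-expression filtering, zFPKM expressed-gene calls, top-500-variable
  PCA, TMM normalization and a negative-binomial quasi-likelihood F test;
  genes are significant at strict FDR < 0.05 and fold change > 2.
* **Stroma signatures C1–C4** — androgen-dependent stroma gene clusters
  extracted by z-score (> 1 in the reference state) plus significance
  rules across two PDX models (an androgen-dependent BM18-like and a
  castration-resistant LAPC9-like line), with confidence-1 ortholog mapping
  to human symbols and the packaged seven-gene Ob-BMST signature.
* **Single-sample scoring** — GSVA-style kernel-CDF/rank random-walk
  enrichment scores in [-1, 1], with Spearman/Gleason, Mann–Whitney
  sample-type and quartile-stratification statistics.
* **Proteomics** — in-silico tryptic digestion (cut after K/R, not before
  P, ≤ 2 missed cleavages, ≥ 7 residues), peptide species-uniqueness
  against a combined database, ≥ 2-unique-peptide protein inference,
  variance-stabilizing normalization and robust-z ratio statistics.
* **Survival** — Kaplan–Meier, log-rank with BH-adjusted pairwise tests,
  maximally-selected-rank cutpoints with permutation-adjusted p-values, and
  Cox proportional hazards, applied to a TMA-style cohort with the study's
  endpoint definitions (clinical progression = metastasis or local
  recurrence; disease progression = any recurrence).

A synthetic-data module generates every input — two-species references with
tunable homology, mixed reads, count matrices with planted
androgen-responsive stroma genes, contaminated proteomic fractions, and a
210-patient survival cohort — with known ground truth, so the whole
pipeline runs and is validated offline.

## Worked example

```bash
xenostroma run --seed 7 --outdir runs/demo
cat runs/demo/report.md
```

prints (abridged):

```
## Stroma content (mouse read share)
- BM18like_intact_1: 0.2943
- BM18like_castrated_1: 0.6672
...
## Signature extraction
- C1: 50 genes (truth Jaccard 1.0)
- C2: 30 genes (truth Jaccard 0.9)
- C3: 34 genes (truth Jaccard 0.8857)
- C4: 24 genes (truth Jaccard 1.0)
## Cohort survival
- maxstat cutpoint 46.53 (|z| = 5.699, adjusted p = 0.0005)
- log-rank chi2 32.474 (p = 0.0)
- Cox HR (high vs low marker) = 2.787
```

Reading the numbers: the intact BM18-like samples carry ~0.3 mouse reads
(the planted stroma fraction) rising to ~0.6 after castration — the
stroma-enrichment signal the read classifier recovers. The C1 rule returns
exactly the 50 planted androgen-responsive stroma genes (truth Jaccard
1.0); C2–C4 recover their planted sets up to a couple of boundary genes, as
expected from the rules' z-score margins (see `docs/methods.md`). On the
synthetic cohort the maxstat cutpoint splits patients at a marker level of
46.5 TNC-positive-like cells, and the high-marker group progresses with a
hazard ratio of 2.8 against a planted 2.5.

The same steps are available as library calls
(`xenostroma.run_pipeline(PipelineConfig(seed=7), "runs/demo")`) and as
individual subcommands (`simulate`, `assign`, `de`, `score`, `surv`,
`init`, `report`).

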