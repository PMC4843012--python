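# metaconcord

Cross-cohort reproducibility analysis of metastasis-associated molecular
signals in resected tumours, built around one clinical fact: routine TNM
staging misses micrometastases, so a "non-metastatic" (N0M0) label is an
unreliable readout of true metastasis status — but post-surgery
recurrence is a second, independent readout. `metaconcord` implements
the full comparison between two sample-grouping policies:

* **TNM-only** — non-metastasis = N0M0; metastasis = N+ and/or M+.
* **TNM + recurrence** — an N0M0 patient who recurred after curative
  resection is reclassified as metastatic (their recurrence is taken to
  reveal an occult metastasis); an N+M0 patient who did *not* recur is
  excluded as a possible staging false positive; and a non-recurrent
  N0M0 patient who received adjuvant therapy is excluded when treatment
  annotations exist, because therapy may have suppressed a real
  metastasis.

The question the pipeline answers is whether differentially expressed
genes (DEGs) between the two groups *replicate across independent
cohorts*, and the core statistic is the **concordance score**: if two
signed DEG lists share *k* genes and *s* of them have the same
up/down direction, the score is 100·*s*/*k* %, with significance from
the upper-tail cumulative binomial

P(X ≥ s), X ~ Binomial(k, P<sub>e</sub>), P<sub>e</sub> = 0.5,

i.e. the chance of at least *s* direction agreements if the lists were
unrelated. The same statistic scores the agreement between promoter
methylation and expression (hypermethylated genes vs down-regulation,
hypomethylated vs up-regulation).

## What is in the box

| module | role |
| --- | --- |
| `metaconcord.datatypes` / `io` | sample annotations, expression/beta/binary matrices, probe→gene collapsing, GMT gene sets, strict TSV round-trips |
| `metaconcord.grouping` | the two grouping policies above |
| `metaconcord.differential` | Wilcoxon rank-sum DE (exact for small samples), a simplified NB conditional exact test for counts, Fisher's exact test for binary alterations, BH-FDR, gene-level hyper/hypomethylation calls |
| `metaconcord.concordance` | concordance score + cumulative-binomial significance (log-space safe for extreme tails) |
| `metaconcord.enrichment` | hypergeometric gene-set enrichment, run separately on up- and down-regulated DEGs |
| `metaconcord.simulate` | multi-cohort synthetic generator with hidden ground truth (true metastasis status corrupted into observed staging; recurrence as a noisy readout; optional count and promoter-methylation arms) |
| `metaconcord.pipeline` / `cli` | one-command orchestration of the whole experiment |

## Worked example

Run the full synthetic replication experiment (two cohorts of 150
samples × 2000 genes, 30% of true metastases hidden by staging, 90% of
true DE genes shared between cohorts):

```sh
metaconcord run-all --out demo_run --seed 8
```

which prints the cross-cohort summary

```
cohort_a cohort_b              policy  n_deg_a  n_deg_b  k_shared  s_concordant  score_pct   p_binomial  log10_p
 cohort0  cohort1            tnm_only        3       16         0             0        NaN          NaN      NaN
 cohort0  cohort1 tnm_plus_recurrence      107       85        31            31      100.0 4.656613e-10 -9.33193
```

Read it row by row: under TNM-only grouping the two cohorts yield 3 and
16 DEGs (FDR < 20%) with **no** overlap — the signal does not
replicate, because each cohort's "non-metastasis" group is contaminated
with occult metastases. After recurrence-aware regrouping the same data
yield 107 and 85 DEGs, 31 shared, all 31 with the same direction
(score 100%, binomial p ≈ 4.7×10⁻¹⁰). The methylation arm
(`demo_run/methylation_concordance.tsv`) shows 37 hypermethylated DM
genes among the DEGs, all down-regulated (p ≈ 7.3×10⁻¹²), the classic
promoter-silencing pattern.

Every intermediate table (per-cohort matrices, group assignments,
per-feature DE/DM results, truth files for auditing) is written under
`demo_run/`, each with a `#` comment block echoing the full
configuration and seed; runs are byte-reproducible given the seed.

The same stages are available individually (`metaconcord simulate`,
`group`, `de`, `dm`, `alt`, `concordance`, `meth-concordance`,
`enrich`) and as plain library calls.

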