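# cnvprog

Copy-number instability and prognosis analysis for array-CGH tumor
cohorts, built around the question of whether the burden of somatic copy
number variation (CNV) predicts 5-year recurrence in pituitary
neuroendocrine tumors (PitNETs).

The package implements the complete analysis chain:

1. **Preprocessing** — median normalization of per-probe log2 ratios
   (L2R), the derivative log ratio spread (DLRS) quality metric with the
   exclusion gate DLRS > 0.47, and centralization of profiles carrying
   alterations longer than 5 Mb.
2. **Segmentation** — circular binary segmentation (CBS): per
   chromosome, the arc maximizing a two-sample t statistic is accepted as
   a pair of change-points when it is too extreme to arise by chance at
   significance 10⁻⁶, recursively; segment means beyond ±0.25 log2 are
   called gained/lost, and runs of homozygous SNP probes in copy-neutral
   territory (samples with DLRS < 0.3) are reported as copy-neutral LOH.
3. **Instability metrics** — altered-probe fraction per tumor
   (deleted + gained probes over total probes, optionally pooling cnLOH),
   whole-chromosome/arm event summaries, Wilcoxon/Kruskal–Wallis group
   comparisons.
4. **Clustering** — Jaccard distance between binarized alteration
   profiles, Ward-criterion agglomeration (ward.D2 convention), Fisher /
   Kruskal–Wallis cluster–clinical association tests.
5. **Prognosis** — logistic regression of recurrence on
   log2(altered probes + 1), so exp(β) is an odds ratio per *doubling* of
   altered probes; likelihood-ratio tests against the model without the
   burden term; genome-wide per-probe scans (three-state factor, reference
   "normal") with Benjamini–Yekutieli control; hg19-style gene mapping of
   CNVs and per-gene scans with Benjamini–Hochberg control.
6. **Expression integration** — fold-change + Student t differential
   expression (|FC| ≥ 2, p ≤ 0.05), signal-to-noise gene ranking
   (μ₁−μ₂)/(σ₁+σ₂), preranked GSEA with a seeded permutation null, and
   the intersection of CNV-prognostic genes with differentially expressed
   genes.

Because the original patient data live in controlled-access archives, the
package ships a first-class **synthetic cohort generator** that emulates
the study design: 195 tumors across five lineages (gonadotroph,
immunonegative, somatotroph, lactotroph, corticotroph) with per-type
burden distributions, an excess of gains over losses, cnLOH, clinical
covariates, and a planted lactotroph burden→recurrence effect of OR 1.3
per doubling. Every downstream stage is tested against this generator's
ground truth, including exact recovery of the alteration matrix from
noise-free profiles.

## Worked example

```python
from cnvprog import (PipelineConfig, run_pipeline)

bundle = run_pipeline(PipelineConfig(seed=1, n_probes=10_000, noise_sd=0.15))
inst = bundle.sections["instability"]["per_type"]
print({t: round(s["median_altered_percent"], 1) for t, s in inst.items()})
print("lactotroph burden OR:",
      round(bundle.sections["prognosis"]["lactotroph_burden_or"], 2))
print({c: s["n"] for c, s in bundle.sections["clustering"]["clusters"].items()})
```

prints (seed 1):

```
{'corticotroph': 10.3, 'gonadotroph': 0.0, 'immunonegative': 0.0, 'lactotroph': 28.7, 'somatotroph': 3.4}
lactotroph burden OR: 1.26
{'1': 77, '2': 81, '3': 37}
```

Read: the five lineages separate sharply by instability — the median
lactotroph tumor carries ~29% altered probes while gonadotroph and
immunonegative tumors are nearly quiet; the multivariate model recovers
an odds ratio of ≈1.3 per doubling of altered probes for lactotroph
recurrence (the planted effect); and Ward clustering of the Jaccard
distances splits the cohort into quiet (77), intermediate (81) and
disrupted (37) tiers.

The same stages are available from the shell:

```bash
cnvprog simulate --outdir sim --seed 1 --n-probes 10000
cnvprog preprocess --l2r sim/l2r.tsv --probes sim/probe_map.tsv --out qc.tsv
cnvprog segment --l2r sim/l2r.tsv --probes sim/probe_map.tsv --outdir seg --alpha 1e-6
cnvprog cluster --matrix seg/alteration_matrix.tsv --k 3 --out clusters.tsv
cnvprog prognosis --matrix seg/alteration_matrix.tsv --clinical sim/clinical.tsv \
    --scope lactotroph --out burden.tsv
cnvprog run --outdir full_run --seed 1 --report report.json
```

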