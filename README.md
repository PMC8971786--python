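# tcrtme

Quantitative analysis of how neoadjuvant chemotherapy (NAC) remodels the
tumor immune microenvironment, built for paired pre/post-treatment designs in
gastric cancer: T-cell-receptor (TCR) β-chain repertoire diversity, immune-cell
density from immunohistochemistry (IHC) and multiplex immunofluorescence (mIF),
and the paired / group / survival association layer that ties them to
treatment response and outcome.

It is aimed at translational tumor-immunology groups who have (a) bulk CDR3
clonotype tables from immunosequencing, (b) segmented per-cell or per-core
immune-marker calls, and (c) clinical covariates (regimen, tumor regression
grade, TMB, survival), and want the standard battery of repertoire metrics and
nonparametric comparisons in one reproducible pipeline. Because such patient
data are rarely public, the package ships a first-class synthetic-cohort
generator with the statistical structure this analysis assumes, so every stage
is exercised end-to-end without any download.

## The statistics at the core

For a repertoire of N unique clonotypes with counts c_i, total T = Σc_i and
frequencies p_i = c_i / T:

- **D50** — the minimum number of distinct clonotypes whose summed counts
  reach ≥ 50% of T. Small D50 = a few expanded clones dominate.
- **Normalized Shannon entropy (Pielou evenness)** —
  HNorm = −Σ p_i ln p_i / ln N, which is 0 for a monoclonal repertoire and
  exactly 1 for a perfectly even one.
- **Clonal proportion** — N / T, the unique-per-read diversity proxy.
- **Abundance groups** — the fraction of reads held by clonotype rank decades
  (top 1–10, 11–100, …), the stacked relative-abundance representation.

Density measures are percentages of nucleated cells: per-TMA-core
immunoreactivity 100·pos/(pos+neg) with a ≥ 50%-tumor-cell core filter and
per-case averaging (IHC), and compartment-stratified phenotype fractions
(tumor nest vs stroma) from per-cell mIF calls, displayed as log2(density+1).

Inference follows the matched-pairs design: Wilcoxon signed-rank for pre/post
contrasts, Mann-Whitney for responder (TRG 0–1) vs non-responder (TRG 2–3)
contrasts, Spearman correlation, Benjamini-Hochberg FDR applied group-wise per
biomarker, rank-formulation ROC AUC with a stratified bootstrap CI for
response prediction, and Kaplan-Meier/log-rank plus two-stage Cox screening
(univariable entry at p ≤ 0.05, backward likelihood-ratio elimination) for
overall survival.

## Worked example

```python
from tcrtme import generate_repertoire, summarize
from tcrtme.synthetic import perturb_post_treatment

pre = generate_repertoire(n_clones=1000, zipf_exponent=1.5,
                          total_reads=50000, seed=1)
post = perturb_post_treatment(pre, top_elimination_fraction=0.01,
                              novel_influx=200, depth_factor=0.7, seed=1)
for name, rep in [("pre", pre), ("post", post)]:
    s = summarize(rep)
    print(f"{name:4s} total={s.total_tcr:6d} unique={s.unique_tcr:5d} "
          f"proportion={s.clonal_proportion:.4f} D50={s.d50:4d} HNorm={s.h_norm:.4f}")
```

prints

```
pre  total= 50000 unique= 1000 proportion=0.0200 D50=   2 HNorm=0.4281
post total= 35000 unique= 1164 proportion=0.0333 D50=  26 HNorm=0.7489
```

The pre-treatment repertoire is dominated by expanded clones (two clonotypes
hold half of all 50,000 reads; evenness 0.43). Eliminating the top 1% of
clones, shrinking depth to 70% and admitting 200 new low-abundance clonotypes
reproduces the canonical post-chemotherapy signature: fewer total reads,
*more* unique clonotypes, and sharply higher D50 and evenness — the clonally
expanded compartment was removed and diversity rose.

The same flow runs end-to-end from the command line:

```bash
tcrtme all -c config.yaml -o results/        # simulate → metrics → densities
                                             # → comparisons → survival
tcrtme repertoire sample1.airr.tsv -o summary.csv   # real AIRR TSV input
```

Every stage output is a tidy CSV with a JSON column-schema sidecar, and
`manifest.json` records the config hash, seed and output checksums
(identical config + seed ⇒ identical checksums).

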