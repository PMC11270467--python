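# methylzyg

Promoter-methylation calling, tumour-purity/copy-number correction and
methylation **zygosity** classification for homologous-recombination-repair
(HRR) genes, from methylation-array beta values.

## The problem

Promoter CpG methylation of HRR genes such as *BRCA1* and *RAD51C* can
silence the gene and produce homologous recombination deficiency (HRD) — a
therapeutically actionable state (PARP-inhibitor sensitivity). But a bulk
tumour beta value mixes signal from tumour and contaminating normal cells,
and from methylated and unmethylated gene copies. The question that matters
clinically is not "is the promoter methylated?" but "are **all** tumour
copies methylated?" (homozygous methylation, HRD-competent) versus "only
some copies or some cells?" (heterozygous/subclonal, residual expression
retained).

`methylzyg` implements that analysis as a reusable pipeline for
epigenomics researchers working with HM450-style beta matrices:

1. **Probe selection** — per gene and cancer type, promoter probes
   (|TSS distance| ≤ 200 bp, plus probes in overlapping CpG islands, plus
   the directly adjacent probe on each flank) are filtered on normal-tissue
   statistics: kept iff normal median beta ≤ 0.2 and IQR ≤ 0.2. Genes with
   fewer than 3 surviving probes are excluded for that cancer type.
2. **Methylation calling** — a tumour is called methylated for a gene when
   ≥ 60% of evaluable panel probes show beta ≥ 0.25 (both inclusive).
3. **Purity/copy-number correction** — the bulk beta is modelled as a
   mixture,

       m_b = (ρ·n_t·m_t + n_n·m_n·(1−ρ)) / (ρ·n_t + n_n·(1−ρ))

   with tumour purity ρ, tumour gene copy number n_t, normal copy number
   n_n = 2 and per-probe normal methylation m_n (mean beta of normals).
   Inverting for the pure-tumour methylation m_t per probe and taking the
   median classifies each gene-sample as **high** (median ≥ 0.7, consistent
   with homozygous methylation) or **low** (< 0.7, heterozygous or
   subclonal); joining with LOH gives the zygosity classes
   `high+LOH / high-LOH / low+LOH / low-LOH / uncorrected`.
4. **Association statistics** — Fisher-exact enrichment scans with
   Benjamini–Hochberg control within explicit families, Mann–Whitney U and
   Kruskal–Wallis + Dunn post-hoc comparisons for scores such as the HRD
   scar score (threshold table at ≥ 42), and a simple log2 CPM transform
   for expression contrasts.

A synthetic-cohort generator draws cohorts with known purity, copy number,
LOH and allelic methylation states, so every stage is testable against
ground truth without any data downloads.

## Worked example

```python
import methylzyg as mz

config = mz.CohortConfig(n_tumours=300, n_normals=50, seed=7)
cohort = mz.simulate_cohort(config)

selector = mz.select_probe_panels(
    cohort.beta, cohort.annotation, cohort.islands, cohort.samples
)
calls = mz.call_cohort(cohort.beta, selector, cohort.samples)
prevalence, _ = mz.prevalence(calls)
print(prevalence)

corrected = mz.correct_cohort(
    cohort.beta, selector, cohort.samples, cohort.copy_number
)
table, counts = mz.zygosity_summary(corrected)
merged = table.merge(cohort.truth, on=["sample_id", "gene"])
meth = merged[merged["allelic_state"] != "unmethylated"]
print(meth.groupby("allelic_state")["level"].value_counts())
```

Output:

```
     gene group  n_methylated  n_total   percent
0   BRCA1   all            23      300  7.666667
1  RAD51C   all            26      300  8.666667
allelic_state  level
heterozygous   low      27
homozygous     high     26
Name: count, dtype: int64
```

Both genes were simulated at 10% prevalence; the caller detects 7.7% and
8.7% (misses concentrate in low-purity heterozygous cases, where the bulk
signal genuinely drops below the calling threshold). After correction,
every heterozygous-truth case classifies **low** and every
homozygous-truth case classifies **high** — the corrected median, not the
raw bulk beta, separates methylation zygosity.

The same pipeline is scriptable from a shell:

```bash
methylzyg --seed 7 simulate --out-dir sim
methylzyg select-probes --beta sim/beta.tsv --samples sim/samples.tsv \
    --annotation sim/annotation.tsv --islands sim/islands.bed --out panels.tsv
methylzyg call --beta sim/beta.tsv --panels panels.tsv \
    --samples sim/samples.tsv --out calls.tsv
methylzyg correct --beta sim/beta.tsv --panels panels.tsv \
    --samples sim/samples.tsv --cn sim/copy_number.tsv --out corrected.tsv
methylzyg associate --calls calls.tsv --corrected corrected.tsv \
    --features features.tsv --scores scores.tsv --out-prefix assoc
```

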