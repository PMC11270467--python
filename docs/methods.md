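# Methods

## Model and procedure

### Bulk mixture model

A bulk tumour specimen contains a fraction ρ of tumour cells (purity) and
1 − ρ of normal cells. For one CpG probe, with tumour gene copy number n_t,
normal copy number n_n, pure-tumour methylation fraction m_t and normal
methylation fraction m_n, the expected bulk beta value is the copy-weighted
mixture

    m_b = (ρ·n_t·m_t + n_n·m_n·(1−ρ)) / (ρ·n_t + n_n·(1−ρ)).

`forward_mix` evaluates this; `correct_probe` inverts it,

    m_t = (m_b·(ρ·n_t + n_n·(1−ρ)) − n_n·m_n·(1−ρ)) / (ρ·n_t),

and the two are exact inverses (property-tested to 1e-12 over random
valid parameters). Assumptions: n_n = 2 for all specimens; m_n per probe is
the **mean** beta of the cohort's normal samples (probe selection uses the
median/IQR — both statistics are retained separately); copy numbers are
used as provided, real-valued, with no rounding, since gene-level totals
from segmentation are generally non-integer and the equation does not
require integers.

Under noise or mis-estimated purity the inversion can leave [0, 1]; the
estimate is clamped with a per-probe `clamped` flag and clamp totals are
reported per cohort — never silently.

### Probe selection

Candidates per gene: probes with |TSS distance| ≤ 200 bp, probes inside any
CpG island overlapping that window (BED half-open semantics: 1-based
position p is inside (start, end] iff start < p ≤ end), and the single
nearest probe on each flank of the resulting span ("directly adjacent" read
minimally — one probe per flank, subjected to the same filters). Filters:
normal-tissue median ≤ 0.2 and IQR ≤ 0.2, both inclusive; quantiles use
linear interpolation between order statistics, applied identically to
median and IQR (consistency matters more than the convention). A gene
keeping fewer than `min_probes = 3` probes is excluded for that cancer
type — 3 is the smallest panel for which the 60% calling rule is
non-degenerate, and exclusion operationalises dropping genes whose
promoters are methylated in normal tissue. Panels are built per cancer type
from that type's normals, with a configurable fallback map for types
lacking normals (e.g. glioblastoma normals for low-grade glioma).

### Methylation calling

Methylated iff ≥ 60% of evaluable probes have beta ≥ 0.25, both thresholds
inclusive. The denominator is **evaluable** (non-missing) probes: the rule
stays defined on incomplete arrays, and each call records
n_panel/n_evaluable/n_above so the decision is auditable. Calls with fewer
than `min_evaluable = 3` evaluable probes are `not_evaluable` and excluded
from prevalence denominators. Cross-gene co-methylation is summarised
descriptively (counts per sample); formal tests live in the association
module.

### Zygosity classification

Per gene-sample: correct each evaluable probe, take the median, classify
**high** iff median ≥ 0.7 (inclusive at 0.7, since the low class is defined
strictly below 70%) — consistent with homozygous (all-copy) methylation —
else **low** (heterozygous or subclonal). Per-probe-then-median is used
rather than correcting a summarised beta: the median of corrected probes is
robust to single-probe artefacts that a corrected mean would propagate.
When purity or copy number is missing the raw bulk median is reported with
level `uncorrected` rather than assuming ρ = 1 — assuming purity would
misclassify exactly the low-purity cases where correction matters most.
Joining with LOH yields `high+LOH`, `high-LOH`, `low+LOH`, `low-LOH`,
`uncorrected`; a missing LOH flag maps to the `-LOH` arm (absence of
evidence) and is marked in a `loh_missing` column.

The 0.7 median rule is applied uniformly, including to data types where
zygosity might instead be judged from per-site heterogeneity; that
uniformity is a deliberate simplification.

### Statistics

* **Fisher's exact test**: two-sided by the point-probability rule — sum
  hypergeometric probabilities (fixed margins) of all tables whose point
  probability is ≤ the observed one within relative tolerance 1e-7 (the
  slack guards floating-point ties). Odds ratio is the sample estimate
  a·d/(b·c), ∞ when b·c = 0 with a·d > 0, NaN when both products vanish.
* **Benjamini–Hochberg**: step-up q-values; families are always explicit
  arguments of a scan, never inferred, because the family silently changes
  every q-value. Note BH is not idempotent in general (re-adjusting can
  only increase q-values); tests assert the property that actually holds.
* **Mann–Whitney U**: midrank ties; exact distribution when both n ≤ 20 and
  the pooled sample is tie-free, else normal approximation with tie and
  continuity correction. The switch points are fixed recorded constants and
  the method used is stored in every result, so the choice is auditable.
* **Kruskal–Wallis + Dunn**: tie-corrected H against χ²(k−1); Dunn pairwise
  z-statistics on midranks with BH adjustment, computed only when the
  omnibus p < 0.05 (post-hoc tests follow a significant omnibus test).
  Dunn's test is implemented in-package (z = ΔR̄ / √[(N(N+1)/12 − T)·(1/nᵢ +
  1/nⱼ)] with tie term T = Σ(t³−t)/(12(N−1))).
* **HRD-score threshold table**: per-class counts of scores ≥ 42,
  inclusive.
* **log2 CPM**: log2((count + 0.5)/(library + 1)·1e6) — a documented simple
  transform for rank-based expression contrasts; it is not a
  library-composition (TMM-style) normalisation and is not meant to
  reproduce one.

## Synthetic-cohort generator

The generator emulates the statistical structure of a bulk methylation
cohort with promoter methylation of tumour-suppressor-like genes:

* **Probe layout** per gene: `probes_per_gene` signal probes — most within
  ±150 bp of the TSS, two at +230/+260 bp inside a CpG island that overlaps
  the window — plus one distant high-baseline decoy probe that a correct
  filter must drop (and the adjacency rule will nominate, exercising both
  rules).
* **Normal baseline**: per-probe mean 0.05 with ±0.03 uniform jitter
  (signal probes), 0.4–0.6 for decoys; low baselines make generator panels
  always selectable under default thresholds, by construction.
* **Allelic truth** per (tumour, gene): methylated with probability
  `prevalence` (default 0.10); methylated cases homozygous with probability
  0.5, else heterozygous. Homozygous: all copies methylated, LOH true by
  construction (the methylated allele is retained), copies ∈ {1, 2, 3}.
  Heterozygous: one methylated copy of a diploid locus, no LOH.
  Unmethylated: copies ∈ {1, 2, 3, 4} (weighted to diploid), LOH at rate
  0.15. The implied methylated-copy fraction f is scaled by a
  `clonal_fraction` (default 1.0) — a single scalar standing in for
  subclonality, which bulk data cannot distinguish from heterozygosity.
* **Per-probe tumour methylation**: m_t,i = f + (1−f)·baseline_i
  (methylated copies read 1, the rest sit at the normal baseline), mixed
  through `forward_mix` with the sample's purity (uniform on (0.4, 0.9) by
  default) and copy number.
* **Noise**: observed beta ~ Beta(μ·φ, (1−μ)·φ) with precision φ = 100 —
  the standard bounded-noise family for fractions; means are clipped to
  [1e-3, 1−1e-3] to keep both shape parameters positive. Entries are then
  masked missing at rate 0.02.
* **Sizes**: 300 tumours, 50 normals, 2 genes, 8 probes per gene (between
  typical promoter coverage extremes of ~7 and ~21 probes), one cancer
  type.

What the generator does **not** emulate: genome-wide probe sets and
background regions, CpG-island methylator phenotypes, batch/array effects,
probe-specific biases (type I/II chemistry), correlated noise across
neighbouring probes, purity estimation error, and HRD genomic-scar
profiles. Passing tests therefore demonstrate correctness of the
*algorithms under the stated mixture model*, not robustness to every
artefact of real arrays.

## Numerical choices and degenerate inputs

* Readers reject rather than repair: out-of-range betas, duplicate ids,
  purity outside (0, 1], negative copy numbers and malformed BED intervals
  raise errors naming the offending row/column. Missing tokens: empty cell
  or `NA`, configurable.
* ρ = 0 or n_t = 0 make the correction undefined; cohort code reports such
  calls `uncorrected` instead of guessing.
* All-zero contingency tables and all-tied rank data raise rather than
  return an arbitrary statistic.
* Determinism: a cohort is a pure function of (config, seed) via one
  `numpy` generator with a fixed draw order; every downstream stage is
  deterministic, so identical seeds give bit-identical artifacts.

## Verification problem sizes

The acceptance script and test suite use: 10,000 random parameter draws
for the mixture round trip; the default 300-tumour cohort for recovery and
prevalence checks; an exhaustive sweep of all 2×2 tables with margins ≤ 15
(12,375 tables) against the hypergeometric enumeration oracle; full
rank-assignment enumeration for Mann–Whitney at n₁, n₂ ≤ 7; and
2,000-replicate null simulations (Mann–Whitney 2×50, Kruskal–Wallis 3×40,
Fisher on two arms of 500 with a balanced binary feature, enrichment scan
over 20 features × 40 samples). The Fisher null uses large arms because
the exact test is conservative at small counts — its finite-sample size
sits below the nominal α, approaching it only as counts grow; under a
global null the enrichment scan's empirical FDR is checked against the
BH upper bound, which is the guarantee BH actually provides (discrete
Fisher p-values make it strictly conservative).

## Known limitations

* The zygosity call inherits any error in the supplied purity and copy
  number; it does not infer them from methylation data.
* The 0.7 median threshold is a proxy for homozygosity, not a direct
  allele-level measurement; heterozygous-with-LOH combinations at unusual
  copy numbers can land near the boundary.
* Raw-intensity preprocessing (IDAT normalisation, RRBS quantification),
  HRD-score computation, signature fitting, CNA calling and survival
  analysis are out of scope; their outputs are consumed as inputs.
* The log2 CPM transform is intentionally simpler than dedicated RNA-seq
  normalisation; use it only for rank-based contrasts.
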