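"""Synthetic methylation-array cohorts with known ground truth.

The generator emulates the statistical structure of a bulk HM450-style
cohort: per-probe normal-tissue baselines near zero, tumour promoters in one
of three allelic methylation states (unmethylated, heterozygous = one
methylated copy, homozygous = all copies methylated), gene-level copy number
and LOH, tumour purity, and the bulk signal as a purity/copy-number weighted
mixture of tumour and contaminating normal methylation. Observed beta values
are drawn from a mean/precision-parameterised beta distribution, the standard
bounded-noise model for methylation fractions.

Every run is a pure function of its configuration and seed; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateMixtureError, ValidationError

ALLELIC_STATES = ("unmethylated", "heterozygous", "homozygous")

#: mean values are clipped away from {0, 1} before beta-noise sampling so the
#: beta distribution's shape parameters stay strictly positive
_MEAN_EPS = 1e-3


def forward_mix(m_t, m_n, rho, n_t, n_n=2.0):
    """Bulk beta value of a tumour/normal DNA mixture.

    m_b = (rho * n_t * m_t + n_n * m_n * (1 - rho)) / (rho * n_t + n_n * (1 - rho))

    where ``rho`` is tumour purity, ``n_t`` the tumour gene copy number,
    ``n_n`` the normal copy number, ``m_t`` the pure-tumour and ``m_n`` the
    normal methylation fraction. Accepts scalars or broadcastable arrays.
    """
    m_t = np.asarray(m_t, dtype=float)
    m_n = np.asarray(m_n, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    n_n = np.asarray(n_n, dtype=float)
    if np.any(rho <= 0) or np.any(rho > 1):
        raise ValidationError("purity rho must lie in (0, 1]")
    denom = rho * n_t + n_n * (1.0 - rho)
    if np.any(denom <= 0):
        raise DegenerateMixtureError(
            "rho * n_t + n_n * (1 - rho) must be positive"
        )
    result = (rho * n_t * m_t + n_n * m_n * (1.0 - rho)) / denom
    return float(result) if result.ndim == 0 else result


def allelic_state_to_mt(state, total_copies=2.0, loh=None, clonal_fraction=1.0):
    """Pure-tumour methylated-copy fraction implied by an allelic state.

    unmethylated -> 0; heterozygous -> one methylated copy out of
    ``total_copies``; homozygous -> all copies methylated; each scaled by the
    fraction of tumour cells carrying the event (``clonal_fraction``). The
    ``loh`` flag is accepted for signature symmetry with the truth table but
    does not alter the fraction (its effect is already in ``total_copies``).
    """
    if state not in ALLELIC_STATES:
        raise ValidationError(f"unknown allelic state {state!r}")
    if not (0 < clonal_fraction <= 1):
        raise ValidationError("clonal_fraction must lie in (0, 1]")
    if state == "unmethylated":
        return 0.0
    if total_copies <= 0:
        raise ValidationError(
            f"total_copies must be positive for state {state!r}"
        )
    if state == "heterozygous":
        return clonal_fraction * 1.0 / float(total_copies)
    return clonal_fraction * 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a single-cancer-type cohort of 300 tumours and 50
    normals with two promoter-methylation target genes at 10% prevalence
    each, purity uniform on (0.4, 0.9), beta-noise precision 100 and 2%
    missing entries.
    """

    n_tumours: int = 300
    n_normals: int = 50
    genes: tuple = ("BRCA1", "RAD51C")
    probes_per_gene: int = 8
    prevalence: float | Mapping[str, float] = 0.10
    p_homozygous_given_methylated: float = 0.5
    purity_range: tuple = (0.4, 0.9)
    normal_baseline_mean: float = 0.05
    baseline_jitter: float = 0.03
    noise_precision: float = 100.0
    missing_rate: float = 0.02
    clonal_fraction_range: tuple = (1.0, 1.0)
    loh_rate_unmethylated: float = 0.15
    cancer_type: str = "OV"
    seed: int = 0

    def __post_init__(self):
        if self.n_tumours < 0 or self.n_normals < 1:
            raise ConfigError("need n_tumours >= 0 and n_normals >= 1")
        if not self.genes:
            raise ConfigError("gene list must be non-empty")
        if self.probes_per_gene < 1:
            raise ConfigError("probes_per_gene must be >= 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("purity_range must lie within (0, 1]")
        lo, hi = self.clonal_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("clonal_fraction_range must lie within (0, 1]")
        for name in (
            "p_homozygous_given_methylated",
            "normal_baseline_mean",
            "missing_rate",
            "loh_rate_unmethylated",
        ):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_precision <= 0:
            raise ConfigError("noise_precision must be positive")
        for gene in self.genes:
            p = self.prevalence_for(gene)
            if not (0 <= p <= 1):
                raise ConfigError(f"prevalence for {gene!r} must lie in [0, 1]")

    def prevalence_for(self, gene: str) -> float:
        if isinstance(self.prevalence, Mapping):
            return float(self.prevalence.get(gene, 0.0))
        return float(self.prevalence)

    def with_overrides(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


class SyntheticCohort(NamedTuple):
    """All artifacts of one simulated cohort plus its ground truth."""

    beta: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    islands: pd.DataFrame
    copy_number: pd.DataFrame
    truth: pd.DataFrame


def _build_annotation(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe layout per gene: promoter-window probes, two island-tail probes
    beyond the 200 bp window but inside the CpG island, and one distant
    high-baseline decoy that any correct probe filter must drop."""
    rows = []
    islands = []
    for i, gene in enumerate(config.genes):
        chrom = f"chr{i + 1}"
        tss = 1_000_000 * (i + 1)
        k = config.probes_per_gene
        if k >= 3:
            core = np.linspace(-150, 150, k - 2)
            distances = sorted([int(round(d)) for d in core] + [230, 260])
        else:
            distances = [int(round(d)) for d in np.linspace(-150, 150, k)]
        for j, dist in enumerate(distances):
            rows.append(
                {
                    "probe_id": f"cg_{gene}_{j:02d}",
                    "chromosome": chrom,
                    "position": tss + dist,
                    "gene": gene,
                    "tss_distance": dist,
                    "signal": True,
                }
            )
        rows.append(
            {
                "probe_id": f"cg_{gene}_decoy",
                "chromosome": chrom,
                "position": tss + 5000,
                "gene": gene,
                "tss_distance": 5000,
                "signal": False,
            }
        )
        # 0-based half-open interval covering 1-based positions
        # tss-300 .. tss+300: includes the island-tail probes, not the decoy
        islands.append({"chromosome": chrom, "start": tss - 301, "end": tss + 300})
    annotation = pd.DataFrame(rows).sort_values(
        ["chromosome", "position"], kind="stable"
    )
    return annotation.reset_index(drop=True), pd.DataFrame(islands)


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Draw a full cohort: beta matrix, sample sheet, annotation, islands,
    copy-number table and truth table.

    ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    annotation_full, islands = _build_annotation(config)
    annotation = annotation_full.drop(columns="signal")

    n_probes = len(annotation_full)
    probe_ids = annotation_full["probe_id"].to_numpy()
    signal = annotation_full["signal"].to_numpy()
    probe_gene = annotation_full["gene"].to_numpy()

    # per-probe normal-tissue baselines: low for promoter probes, high for
    # the decoys (emulating a constitutively methylated flanking region)
    jitter = rng.uniform(-config.baseline_jitter, config.baseline_jitter, n_probes)
    baseline = np.clip(config.normal_baseline_mean + jitter, 1e-3, 0.2)
    baseline[~signal] = rng.uniform(0.4, 0.6, (~signal).sum())

    normal_ids = [f"N{j:03d}" for j in range(config.n_normals)]
    tumour_ids = [f"T{j:03d}" for j in range(config.n_tumours)]

    purity = rng.uniform(*config.purity_range, config.n_tumours)

    truth_rows = []
    cn_rows = []
    # mean bulk beta for tumour columns, probe x tumour
    tumour_mean = np.tile(baseline[:, None], (1, config.n_tumours))
    for gene in config.genes:
        prev = config.prevalence_for(gene)
        methylated = rng.random(config.n_tumours) < prev
        homo = rng.random(config.n_tumours) < config.p_homozygous_given_methylated
        cf = rng.uniform(*config.clonal_fraction_range, config.n_tumours)
        copies_unmeth = rng.choice(
            [1.0, 2.0, 3.0, 4.0], config.n_tumours, p=[0.1, 0.7, 0.1, 0.1]
        )
        copies_homo = rng.choice([1.0, 2.0, 3.0], config.n_tumours)
        loh_unmeth = rng.random(config.n_tumours) < config.loh_rate_unmethylated
        mask = signal & (probe_gene == gene)
        for s in range(config.n_tumours):
            if not methylated[s]:
                state, n_t, loh, cfrac = "unmethylated", copies_unmeth[s], bool(
                    loh_unmeth[s]
                ), 1.0
            elif homo[s]:
                # homozygous methylation arises via LOH of the unmethylated
                # allele, so LOH is true by construction
                state, n_t, loh, cfrac = "homozygous", copies_homo[s], True, float(
                    cf[s]
                )
            else:
                # one methylated copy of a diploid locus, no LOH
                state, n_t, loh, cfrac = "heterozygous", 2.0, False, float(cf[s])
            f = allelic_state_to_mt(state, n_t, loh, cfrac)
            # methylated copies read 1, the rest sit at the normal baseline
            m_t = f + (1.0 - f) * baseline[mask]
            tumour_mean[mask, s] = forward_mix(m_t, baseline[mask], purity[s], n_t)
            truth_rows.append(
                {
                    "sample_id": tumour_ids[s],
                    "gene": gene,
                    "purity": purity[s],
                    "total_copies": n_t,
                    "loh": loh,
                    "allelic_state": state,
                    "clonal_fraction": cfrac,
                    "true_mt": f,
                }
            )
            cn_rows.append(
                {
                    "sample_id": tumour_ids[s],
                    "gene": gene,
                    "total_copies": n_t,
                    "loh": loh,
                }
            )

    normal_mean = np.tile(baseline[:, None], (1, config.n_normals))
    mean = np.concatenate([normal_mean, tumour_mean], axis=1)
    mean = np.clip(mean, _MEAN_EPS, 1.0 - _MEAN_EPS)
    prec = config.noise_precision
    observed = rng.beta(mean * prec, (1.0 - mean) * prec)
    if config.missing_rate > 0:
        observed[rng.random(observed.shape) < config.missing_rate] = np.nan

    beta = pd.DataFrame(observed, index=probe_ids, columns=normal_ids + tumour_ids)
    beta.index.name = "probe_id"

    samples = pd.DataFrame(
        {
            "sample_id": normal_ids + tumour_ids,
            "role": ["normal"] * config.n_normals + ["tumour"] * config.n_tumours,
            "cancer_type": config.cancer_type,
            "purity": [np.nan] * config.n_normals + list(purity),
        }
    )
    copy_number = pd.DataFrame(cn_rows, columns=["sample_id", "gene", "total_copies", "loh"])
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id",
            "gene",
            "purity",
            "total_copies",
            "loh",
            "allelic_state",
            "clonal_fraction",
            "true_mt",
        ],
    )
    return SyntheticCohort(beta, samples, annotation, islands, copy_number, truth)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write all cohort artifacts as TSV/BED under ``out_dir``; returns the
    path of each artifact."""
    from pathlib import Path

    from .io import write_beta_matrix, write_cpg_islands, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "islands": out / "islands.bed",
        "copy_number": out / "copy_number.tsv",
        "truth": out / "truth.tsv",
    }
    write_beta_matrix(cohort.beta, paths["beta"])
    write_table(cohort.samples, paths["samples"])
    write_table(cohort.annotation, paths["annotation"])
    write_cpg_islands(cohort.islands, paths["islands"])
    write_table(cohort.copy_number, paths["copy_number"])
    write_table(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
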