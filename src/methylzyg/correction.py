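"""Purity/copy-number correction of bulk beta values and zygosity classes.

Inverting the bulk-mixture relation

    m_b = (rho * n_t * m_t + n_n * m_n * (1 - rho)) / (rho * n_t + n_n * (1 - rho))

for the pure-tumour methylation fraction gives

    m_t = (m_b * (rho * n_t + n_n * (1 - rho)) - n_n * m_n * (1 - rho)) / (rho * n_t)

with tumour purity rho, tumour gene copy number n_t, normal copy number n_n
(assumed 2) and per-probe normal methylation m_n taken as the mean beta of
the normal samples. Under noise or mis-estimated purity the inversion can
leave [0, 1]; estimates are clamped with a recorded flag, never silently.

A gene-sample is classified ``high`` (consistent with homozygous, i.e.
all-copy, methylation) when the median corrected probe value is >= 0.7 and
``low`` (heterozygous or subclonal methylation) below; when purity or copy
number is unavailable the raw median is reported with level
``uncorrected`` rather than assuming purity 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import UndefinedCorrectionError, ValidationError
from .io import validate_beta_matrix
from .probes import PromoterProbeSelector

LEVEL_HIGH = "high"
LEVEL_LOW = "low"
LEVEL_UNCORRECTED = "uncorrected"

CORRECTED_COLUMNS = [
    "sample_id",
    "gene",
    "cancer_type",
    "n_probes",
    "median_mt",
    "level",
    "n_clamped",
    "purity_used",
    "copies_used",
    "normal_copies",
    "loh",
]


def correct_probe(m_b, m_n, rho, n_t, n_n=2.0):
    """Pure-tumour methylation estimate for one probe (vectorised).

    Returns ``(m_t, clamped)`` where ``m_t`` is clamped to [0, 1] and
    ``clamped`` flags estimates that fell outside it.
    """
    m_b = np.asarray(m_b, dtype=float)
    m_n = np.asarray(m_n, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    n_n = np.asarray(n_n, dtype=float)
    if np.any(rho <= 0) or np.any(rho > 1):
        raise UndefinedCorrectionError("purity rho must lie in (0, 1]")
    if np.any(n_t <= 0):
        raise UndefinedCorrectionError("tumour copy number n_t must be positive")
    raw = (m_b * (rho * n_t + n_n * (1.0 - rho)) - n_n * m_n * (1.0 - rho)) / (
        rho * n_t
    )
    clamped = (raw < 0.0) | (raw > 1.0)
    m_t = np.clip(raw, 0.0, 1.0)
    if m_t.ndim == 0:
        return float(m_t), bool(clamped)
    return m_t, clamped


@dataclass
class CorrectedCall:
    sample_id: str
    gene: str
    probe_ids: list
    per_probe_mt: np.ndarray
    clamped_flags: np.ndarray
    median_mt: float
    level: str
    purity_used: float
    copies_used: float
    normal_copies: float


def correct_gene(
    sample_id: str,
    gene: str,
    beta_column: pd.Series,
    panel,
    purity,
    total_copies,
    level_threshold: float = 0.7,
    normal_copies: float = 2.0,
) -> CorrectedCall:
    """Correct one gene in one sample probe-by-probe and take the median.

    Missing purity or copy number (NaN/None, or copies == 0) yields the raw
    bulk medians with level ``uncorrected``.
    """
    if panel.excluded:
        raise ValidationError(
            f"panel for gene {gene!r} ({panel.cancer_type}) is excluded"
        )
    values = beta_column.reindex(panel.probes).to_numpy(dtype=float)
    evaluable = ~np.isnan(values)
    probe_ids = [p for p, e in zip(panel.probes, evaluable) if e]
    m_b = values[evaluable]
    m_n = panel.normal_mean.reindex(panel.probes).to_numpy(dtype=float)[evaluable]

    purity = np.nan if purity is None else float(purity)
    total_copies = np.nan if total_copies is None else float(total_copies)
    correctable = (
        np.isfinite(purity)
        and np.isfinite(total_copies)
        and total_copies > 0
        and m_b.size > 0
    )
    if correctable:
        m_t, clamped = correct_probe(m_b, m_n, purity, total_copies, normal_copies)
        median_mt = float(np.median(m_t)) if m_t.size else np.nan
        level = LEVEL_HIGH if median_mt >= level_threshold else LEVEL_LOW
    else:
        m_t = m_b
        clamped = np.zeros(m_b.shape, dtype=bool)
        median_mt = float(np.median(m_b)) if m_b.size else np.nan
        level = LEVEL_UNCORRECTED
    return CorrectedCall(
        sample_id=sample_id,
        gene=gene,
        probe_ids=probe_ids,
        per_probe_mt=np.atleast_1d(m_t),
        clamped_flags=np.atleast_1d(clamped),
        median_mt=median_mt,
        level=level,
        purity_used=purity,
        copies_used=total_copies,
        normal_copies=normal_copies,
    )


class TumourMethylationCorrector(BaseEstimator):
    """Cohort-wide purity/copy-number correction and level classification.

    Attributes
    ----------
    panels_ : dict
        (gene, cancer_type) -> ProbePanel (from :meth:`fit`).
    """

    def __init__(self, level_threshold=0.7, normal_copies=2.0):
        self.level_threshold = level_threshold
        self.normal_copies = normal_copies

    def fit(self, panels, y=None):
        if isinstance(panels, PromoterProbeSelector):
            panels = panels.panels_
        self.panels_ = dict(panels)
        return self

    def transform(
        self,
        beta: pd.DataFrame,
        samples: pd.DataFrame,
        copy_number: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Corrected calls for every (tumour, non-excluded gene)."""
        validate_beta_matrix(beta)
        cn_index = (
            copy_number.set_index(["sample_id", "gene"])
            if copy_number is not None and len(copy_number)
            else None
        )
        tumours = samples[samples["role"] == "tumour"]
        rows = []
        for _, sample in tumours.iterrows():
            sid = sample["sample_id"]
            if sid not in beta.columns:
                continue
            cancer_type = str(sample["cancer_type"])
            purity = sample.get("purity", np.nan)
            column = beta[sid]
            for (gene, ct), panel in self.panels_.items():
                if ct != cancer_type or panel.excluded:
                    continue
                copies, loh = np.nan, pd.NA
                if cn_index is not None and (sid, gene) in cn_index.index:
                    record = cn_index.loc[(sid, gene)]
                    copies = record["total_copies"]
                    loh = record["loh"]
                call = correct_gene(
                    sid,
                    gene,
                    column,
                    panel,
                    purity,
                    copies,
                    self.level_threshold,
                    self.normal_copies,
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "gene": gene,
                        "cancer_type": cancer_type,
                        "n_probes": len(call.probe_ids),
                        "median_mt": call.median_mt,
                        "level": call.level,
                        "n_clamped": int(call.clamped_flags.sum()),
                        "purity_used": call.purity_used,
                        "copies_used": call.copies_used,
                        "normal_copies": call.normal_copies,
                        "loh": loh,
                    }
                )
        corrected = pd.DataFrame(rows, columns=CORRECTED_COLUMNS)
        return corrected.sort_values(
            ["sample_id", "gene"], kind="stable"
        ).reset_index(drop=True)


def correct_cohort(
    beta,
    panels,
    samples,
    copy_number=None,
    level_threshold: float = 0.7,
    normal_copies: float = 2.0,
) -> pd.DataFrame:
    """Functional wrapper over :class:`TumourMethylationCorrector`."""
    corrector = TumourMethylationCorrector(level_threshold, normal_copies).fit(panels)
    return corrector.transform(beta, samples, copy_number)


def zygosity_summary(corrected: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join corrected methylation level with LOH into the zygosity classes.

    Classes: ``high+LOH`` (consistent with homozygous methylation),
    ``high-LOH``, ``low+LOH``, ``low-LOH`` and ``uncorrected``. A missing
    LOH flag is counted as no observed LOH and marked via ``loh_missing``.
    Returns the per-row table and per-cohort class counts (clamped-probe
    totals included).
    """
    table = corrected.copy()
    loh_missing = table["loh"].isna()
    loh = table["loh"].map(lambda v: bool(v) if pd.notna(v) else False)
    joint = np.where(
        table["level"] == LEVEL_UNCORRECTED,
        LEVEL_UNCORRECTED,
        table["level"].astype(str) + np.where(loh, "+LOH", "-LOH"),
    )
    table["loh_missing"] = loh_missing
    table["joint_class"] = joint
    counts = (
        table.groupby(["cancer_type", "gene", "joint_class"])
        .agg(n=("sample_id", "count"), n_clamped_probes=("n_clamped", "sum"))
        .reset_index()
    )
    return table, counts
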