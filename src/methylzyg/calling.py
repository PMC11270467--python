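"""Per-sample, per-gene promoter methylation calls and prevalence summaries.

A gene is called methylated in a tumour when at least ``fraction_threshold``
(default 60%) of its evaluable panel probes show beta >= ``beta_threshold``
(default 0.25); both thresholds are inclusive. Probes missing in a sample
are removed from numerator and denominator, and a call with fewer than
``min_evaluable`` evaluable probes is reported as not_evaluable rather than
forced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .io import validate_beta_matrix
from .probes import PromoterProbeSelector

logger = logging.getLogger(__name__)

STATUS_METHYLATED = "methylated"
STATUS_UNMETHYLATED = "unmethylated"
STATUS_NOT_EVALUABLE = "not_evaluable"

CALL_COLUMNS = [
    "sample_id",
    "gene",
    "cancer_type",
    "n_panel",
    "n_evaluable",
    "n_above",
    "fraction_above",
    "status",
]


@dataclass
class MethylationCall:
    sample_id: str
    gene: str
    n_panel: int
    n_evaluable: int
    n_above: int
    fraction_above: float
    status: str


def call_gene(
    beta_column: pd.Series,
    panel,
    beta_threshold: float = 0.25,
    fraction_threshold: float = 0.60,
    min_evaluable: int = 3,
    sample_id: str = "",
) -> MethylationCall:
    """Call one gene in one sample from its panel probes.

    ``beta_column`` is indexed by probe id and may cover more probes than the
    panel; only panel probes are used.
    """
    if panel.excluded:
        raise ValidationError(
            f"panel for gene {panel.gene!r} ({panel.cancer_type}) is excluded: "
            f"{panel.reason}"
        )
    values = beta_column.reindex(panel.probes).to_numpy(dtype=float)
    evaluable = ~np.isnan(values)
    n_evaluable = int(evaluable.sum())
    n_above = int(np.sum(values[evaluable] >= beta_threshold))
    fraction = n_above / n_evaluable if n_evaluable else np.nan
    if n_evaluable < min_evaluable:
        status = STATUS_NOT_EVALUABLE
    elif fraction >= fraction_threshold:
        status = STATUS_METHYLATED
    else:
        status = STATUS_UNMETHYLATED
    return MethylationCall(
        sample_id=sample_id,
        gene=panel.gene,
        n_panel=len(panel.probes),
        n_evaluable=n_evaluable,
        n_above=n_above,
        fraction_above=fraction,
        status=status,
    )


class PromoterMethylationCaller(BaseEstimator):
    """Call promoter methylation across a tumour cohort.

    Parameters are the calling thresholds; the probe panels are supplied to
    :meth:`fit` (either a fitted :class:`PromoterProbeSelector` or a
    ``(gene, cancer_type) -> ProbePanel`` dict).

    Attributes
    ----------
    panels_ : dict
        (gene, cancer_type) -> ProbePanel used for calling.
    """

    def __init__(self, beta_threshold=0.25, fraction_threshold=0.60, min_evaluable=3):
        self.beta_threshold = beta_threshold
        self.fraction_threshold = fraction_threshold
        self.min_evaluable = min_evaluable

    def fit(self, panels, y=None):
        if isinstance(panels, PromoterProbeSelector):
            panels = panels.panels_
        self.panels_ = dict(panels)
        return self

    def transform(self, beta: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
        """One call per (tumour sample, non-excluded gene), ordered by
        (sample_id, gene)."""
        validate_beta_matrix(beta)
        known = set(samples["sample_id"].astype(str))
        unknown = [s for s in beta.columns if s not in known]
        if unknown:
            raise ValidationError(
                f"samples in beta matrix but absent from sample sheet: {unknown}"
            )
        tumours = samples[samples["role"] == "tumour"]
        rows = []
        for _, sample in tumours.iterrows():
            sid = sample["sample_id"]
            if sid not in beta.columns:
                continue
            cancer_type = str(sample["cancer_type"])
            column = beta[sid]
            for (gene, ct), panel in self.panels_.items():
                if ct != cancer_type or panel.excluded:
                    continue
                call = call_gene(
                    column,
                    panel,
                    self.beta_threshold,
                    self.fraction_threshold,
                    self.min_evaluable,
                    sample_id=sid,
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "gene": gene,
                        "cancer_type": cancer_type,
                        "n_panel": call.n_panel,
                        "n_evaluable": call.n_evaluable,
                        "n_above": call.n_above,
                        "fraction_above": call.fraction_above,
                        "status": call.status,
                    }
                )
        calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
        return calls.sort_values(["sample_id", "gene"], kind="stable").reset_index(
            drop=True
        )


def call_cohort(
    beta: pd.DataFrame,
    panels,
    samples: pd.DataFrame,
    beta_threshold: float = 0.25,
    fraction_threshold: float = 0.60,
    min_evaluable: int = 3,
) -> pd.DataFrame:
    """Functional wrapper over :class:`PromoterMethylationCaller`."""
    caller = PromoterMethylationCaller(
        beta_threshold, fraction_threshold, min_evaluable
    ).fit(panels)
    return caller.transform(beta, samples)


def prevalence(
    calls: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    grouping: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prevalence of methylation per gene (and optional sample grouping).

    Returns ``(prevalence_table, co_methylation_table)``. Percentages are
    over samples with evaluable calls. The co-methylation table counts, per
    sample, how many genes are simultaneously called methylated — the
    descriptive mutual-exclusivity summary.
    """
    evaluable = calls[calls["status"] != STATUS_NOT_EVALUABLE].copy()
    if grouping is not None:
        if samples is None:
            raise ValidationError("grouping requires the sample sheet")
        if grouping not in samples.columns:
            raise ValidationError(f"grouping column {grouping!r} not in sample sheet")
        labels = samples.set_index("sample_id")[grouping]
        if labels.reindex(evaluable["sample_id"]).isna().any():
            raise ValidationError(f"grouping key {grouping!r} missing for some samples")
        evaluable["group"] = labels.reindex(evaluable["sample_id"]).to_numpy()
        keys = ["gene", "group"]
    else:
        evaluable["group"] = "all"
        keys = ["gene", "group"]

    rows = []
    for (gene, group), sub in evaluable.groupby(keys, sort=True):
        n_total = len(sub)
        if n_total == 0:
            logger.warning("empty group %r for gene %s omitted", group, gene)
            continue
        n_meth = int((sub["status"] == STATUS_METHYLATED).sum())
        rows.append(
            {
                "gene": gene,
                "group": group,
                "n_methylated": n_meth,
                "n_total": n_total,
                "percent": 100.0 * n_meth / n_total,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "group", "n_methylated", "n_total", "percent"]
    )

    meth = evaluable[evaluable["status"] == STATUS_METHYLATED]
    co = (
        meth.groupby("sample_id")["gene"]
        .agg(n_methylated_genes="count", genes=lambda g: ",".join(sorted(g)))
        .reset_index()
    )
    return table, co
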