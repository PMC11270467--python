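"""Promoter probe-panel selection from normal-tissue beta values.

A gene's candidate probes are those within ``tss_window`` bp of the TSS,
plus probes inside any CpG island overlapping that window, plus the single
nearest probe on each flank of the resulting span. Candidates are then
filtered on normal-tissue statistics: a probe is kept iff its normal median
beta is <= ``median_threshold`` and its normal IQR is <= ``iqr_threshold``
(both inclusive). A gene whose panel retains fewer than ``min_probes``
probes is excluded for that cancer type, with the reason recorded — the
operational form of dropping genes whose promoters are already methylated
in normal tissue.

Panels are built per cancer type from that type's normal samples; a
``normal_fallback`` map substitutes another type's normals where a type has
none (as when glioblastoma normals stand in for low-grade glioma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .io import probes_in_islands, validate_beta_matrix

logger = logging.getLogger(__name__)

EXCLUSION_REASON = "insufficient low-methylation probes in normal tissue"


@dataclass
class ProbePanel:
    """Selected promoter probes for one (gene, cancer type), with the
    per-probe normal-tissue statistics used downstream."""

    gene: str
    cancer_type: str
    probes: list = field(default_factory=list)
    normal_mean: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    normal_median: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    normal_iqr: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    excluded: bool = False
    reason: str = ""


def candidate_probes(
    annotation: pd.DataFrame,
    islands: pd.DataFrame,
    gene: str,
    tss_window: int = 200,
) -> list:
    """Candidate promoter probes for ``gene``, ordered by genomic position.

    Window membership uses |tss_distance| <= tss_window; island membership
    uses the BED half-open rule against islands overlapping the window;
    adjacency admits the single nearest probe on each flank of the candidate
    span.
    """
    rows = annotation[annotation["gene"] == gene]
    if rows.empty:
        raise ValidationError(f"gene {gene!r} absent from annotation")
    rows = rows.sort_values("position", kind="stable").reset_index(drop=True)
    tss = int(rows["position"].iloc[0] - rows["tss_distance"].iloc[0])
    chrom = str(rows["chromosome"].iloc[0])

    in_window = rows["tss_distance"].abs() <= tss_window

    # islands overlapping the 1-based closed window [tss - w, tss + w]
    window_lo, window_hi = tss - tss_window, tss + tss_window
    if islands is not None and len(islands):
        overlapping = islands[
            (islands["chromosome"].astype(str) == chrom)
            & (islands["start"] + 1 <= window_hi)
            & (islands["end"] >= window_lo)
        ]
        in_island = probes_in_islands(
            rows[["chromosome", "position"]], overlapping
        ).to_numpy()
    else:
        in_island = np.zeros(len(rows), dtype=bool)

    base = in_window.to_numpy() | in_island
    if base.any():
        idx = np.flatnonzero(base)
        lo, hi = idx.min(), idx.max()
        selected = base.copy()
        # single nearest probe on each flank of the candidate span
        if lo > 0:
            selected[lo - 1] = True
        if hi < len(rows) - 1:
            selected[hi + 1] = True
    else:
        selected = base
    return rows.loc[selected, "probe_id"].tolist()


def normal_stats(
    beta: pd.DataFrame, normal_samples, probes
) -> pd.DataFrame:
    """Per-probe mean, median and IQR over normal samples.

    Missing values are dropped probe-wise before computing statistics;
    quantiles use linear interpolation between order statistics. Probes with
    no non-missing normal value are flagged unusable.
    """
    normal_samples = list(normal_samples)
    if not normal_samples:
        raise ValidationError("need at least one normal sample")
    missing_probes = [p for p in probes if p not in beta.index]
    if missing_probes:
        raise ValidationError(f"probes absent from beta matrix: {missing_probes}")
    sub = beta.loc[list(probes), normal_samples].to_numpy(dtype=float)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_obs = np.sum(~np.isnan(sub), axis=1)
        mean = np.where(n_obs > 0, np.nanmean(sub, axis=1), np.nan)
        median = np.where(n_obs > 0, np.nanmedian(sub, axis=1), np.nan)
        q1 = np.where(n_obs > 0, np.nanquantile(sub, 0.25, axis=1), np.nan)
        q3 = np.where(n_obs > 0, np.nanquantile(sub, 0.75, axis=1), np.nan)
    return pd.DataFrame(
        {
            "probe_id": list(probes),
            "n_normals": n_obs,
            "normal_mean": mean,
            "normal_median": median,
            "normal_iqr": q3 - q1,
            "usable": n_obs > 0,
        }
    )


def select_panel(
    gene: str,
    cancer_type: str,
    candidates,
    stats: pd.DataFrame,
    median_threshold: float = 0.2,
    iqr_threshold: float = 0.2,
    min_probes: int = 3,
) -> tuple[ProbePanel, pd.DataFrame]:
    """Apply the normal-tissue filters to candidate probes.

    Returns the panel plus a per-probe detail table (kept flag and reason).
    Thresholds are inclusive: median == median_threshold is kept.
    """
    stats = stats.set_index("probe_id").loc[list(candidates)].reset_index()
    reasons = np.array([""] * len(stats), dtype=object)
    kept = stats["usable"].to_numpy(copy=True)
    reasons[~kept] = "no non-missing normal values"
    high_median = kept & (stats["normal_median"].to_numpy() > median_threshold)
    reasons[high_median] = "normal median above threshold"
    high_iqr = (
        kept & ~high_median & (stats["normal_iqr"].to_numpy() > iqr_threshold)
    )
    reasons[high_iqr] = "normal IQR above threshold"
    kept = kept & ~high_median & ~high_iqr

    detail = stats.assign(
        gene=gene, cancer_type=cancer_type, kept=kept, reason=reasons
    )[
        [
            "gene",
            "cancer_type",
            "probe_id",
            "normal_mean",
            "normal_median",
            "normal_iqr",
            "n_normals",
            "kept",
            "reason",
        ]
    ]
    kept_stats = stats[kept]
    excluded = int(kept.sum()) < min_probes
    panel = ProbePanel(
        gene=gene,
        cancer_type=cancer_type,
        probes=kept_stats["probe_id"].tolist(),
        normal_mean=kept_stats.set_index("probe_id")["normal_mean"],
        normal_median=kept_stats.set_index("probe_id")["normal_median"],
        normal_iqr=kept_stats.set_index("probe_id")["normal_iqr"],
        excluded=excluded,
        reason=EXCLUSION_REASON if excluded else "",
    )
    return panel, detail


class PromoterProbeSelector(BaseEstimator):
    """Select per-(gene, cancer type) promoter probe panels from normals.

    Parameters
    ----------
    genes : list of str, optional
        Genes to build panels for; defaults to every gene in the annotation.
    tss_window : int
        Promoter window half-width around the TSS in bp.
    median_threshold, iqr_threshold : float
        Inclusive upper bounds on the normal-tissue median beta and IQR.
    min_probes : int
        Minimum surviving probes; fewer excludes the gene for that type.
    normal_fallback : dict, optional
        cancer_type -> cancer_type map used when a type has no normals.

    Attributes
    ----------
    panels_ : dict
        (gene, cancer_type) -> :class:`ProbePanel`.
    panel_table_ : pandas.DataFrame
        Per-probe detail for every candidate (kept flag + reason).
    exclusions_ : pandas.DataFrame
        Excluded (gene, cancer_type) pairs with reasons.
    """

    def __init__(
        self,
        genes=None,
        tss_window=200,
        median_threshold=0.2,
        iqr_threshold=0.2,
        min_probes=3,
        normal_fallback=None,
    ):
        self.genes = genes
        self.tss_window = tss_window
        self.median_threshold = median_threshold
        self.iqr_threshold = iqr_threshold
        self.min_probes = min_probes
        self.normal_fallback = normal_fallback

    def fit(self, beta, annotation, islands, samples):
        validate_beta_matrix(beta)
        genes = list(self.genes) if self.genes is not None else sorted(
            annotation["gene"].unique()
        )
        fallback = dict(self.normal_fallback or {})
        cancer_types = sorted(samples["cancer_type"].astype(str).unique())
        normals_by_type = {
            ct: sub.loc[sub["role"] == "normal", "sample_id"].tolist()
            for ct, sub in samples.groupby(samples["cancer_type"].astype(str))
        }
        panels: dict = {}
        details = []
        exclusions = []
        for cancer_type in cancer_types:
            normal_ids = normals_by_type.get(cancer_type, [])
            if not normal_ids and cancer_type in fallback:
                source = fallback[cancer_type]
                normal_ids = normals_by_type.get(source, [])
                logger.info(
                    "using %s normals for cancer type %s", source, cancer_type
                )
            if not normal_ids:
                raise ValidationError(
                    f"no normal samples for cancer type {cancer_type!r} "
                    "and no fallback configured"
                )
            normal_ids = [s for s in normal_ids if s in beta.columns]
            for gene in genes:
                candidates = candidate_probes(
                    annotation, islands, gene, self.tss_window
                )
                stats = normal_stats(beta, normal_ids, candidates)
                panel, detail = select_panel(
                    gene,
                    cancer_type,
                    candidates,
                    stats,
                    self.median_threshold,
                    self.iqr_threshold,
                    self.min_probes,
                )
                panels[(gene, cancer_type)] = panel
                details.append(detail)
                if panel.excluded:
                    exclusions.append(
                        {
                            "gene": gene,
                            "cancer_type": cancer_type,
                            "reason": panel.reason,
                        }
                    )
        self.panels_ = panels
        self.panel_table_ = pd.concat(details, ignore_index=True)
        self.exclusions_ = pd.DataFrame(
            exclusions, columns=["gene", "cancer_type", "reason"]
        )
        return self


def select_probe_panels(
    beta, annotation, islands, samples, **params
) -> PromoterProbeSelector:
    """Functional wrapper over :class:`PromoterProbeSelector`."""
    return PromoterProbeSelector(**params).fit(beta, annotation, islands, samples)


def panels_from_table(panel_table: pd.DataFrame, min_probes: int = 3) -> dict:
    """Rebuild :class:`ProbePanel` objects from a written panel TSV."""
    panels = {}
    for (gene, cancer_type), sub in panel_table.groupby(["gene", "cancer_type"]):
        kept = sub[sub["kept"].astype(bool)]
        excluded = len(kept) < min_probes
        panels[(gene, cancer_type)] = ProbePanel(
            gene=gene,
            cancer_type=cancer_type,
            probes=kept["probe_id"].tolist(),
            normal_mean=kept.set_index("probe_id")["normal_mean"],
            normal_median=kept.set_index("probe_id")["normal_median"],
            normal_iqr=kept.set_index("probe_id")["normal_iqr"],
            excluded=excluded,
            reason=EXCLUSION_REASON if excluded else "",
        )
    return panels
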