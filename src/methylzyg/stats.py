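"""Association statistics: Fisher-exact enrichment with BH control,
rank-based group comparisons and the expression transform.

The statistical toolbox pairs methylation classes with molecular features:
Fisher's exact test (two-sided, point-probability rule) for binary
enrichment scanned across feature families with Benjamini-Hochberg control;
Mann-Whitney U for two-group score contrasts; Kruskal-Wallis with Dunn's
post-hoc z-tests (BH-adjusted) for three or more groups; and a simple
log2 counts-per-million transform for expression comparisons (rank-based
downstream, so full library-composition normalisation is deliberately not
reproduced here).

Multiple-testing families are always explicit arguments: BH is applied
within the family a scan declares, never inferred.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedTestError, ValidationError

logger = logging.getLogger(__name__)

#: record-keeping constants for the exact/approximate switch of the
#: Mann-Whitney test: exact when both groups are at most this large and the
#: pooled values contain no ties, normal approximation otherwise
MWU_EXACT_MAX_N = 20

Q_SIGNIFICANT = 0.05


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p_value)`` with the sample odds ratio
    ``(a*d)/(b*c)``; infinity when ``b*c == 0`` and ``a*d > 0``, NaN when
    both products are zero. The p-value sums hypergeometric probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed one (within relative tolerance 1e-7).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("fisher_exact needs a 2x2 table")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValidationError("fisher_exact needs non-negative integer counts")
    a, b, c, d = (int(x) for x in arr.ravel())
    if a + b + c + d == 0:
        raise UndefinedTestError("all-zero contingency table")
    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = math.inf if ad > 0 else math.nan
    else:
        odds_ratio = ad / bc
    _, p_value = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds_ratio, float(min(p_value, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparison:
    """Result of a rank-based group comparison."""

    statistic_name: str
    statistic: float
    p_value: float
    method: str
    group_sizes: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None


def mann_whitney_u(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Exact distribution when both groups have at most ``MWU_EXACT_MAX_N``
    observations and the pooled values are tie-free; otherwise the normal
    approximation with tie and continuity correction. The method used is
    recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = x.size <= MWU_EXACT_MAX_N and y.size <= MWU_EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    result = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        statistic_name="MannWhitneyU",
        statistic=float(result.statistic),
        p_value=float(min(result.pvalue, 1.0)),
        method=method,
        group_sizes={"x": int(x.size), "y": int(y.size)},
    )


def _dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn's pairwise z-tests on midranks with tie correction and BH."""
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = np.array([len(groups[g]) for g in labels])
    n = values.size
    ranks = sps.rankdata(values)
    bounds = np.cumsum(sizes)
    mean_ranks = {
        g: ranks[start:stop].mean()
        for g, start, stop in zip(labels, np.r_[0, bounds[:-1]], bounds)
    }
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    variance = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            se = math.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group1": gi, "group2": gj, "z": z, "p_value": min(p, 1.0)})
    posthoc = pd.DataFrame(rows)
    posthoc["q_value"] = bh_adjust(posthoc["p_value"].to_numpy())
    return posthoc


def kruskal_dunn(groups, posthoc_gate: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected, chi-square reference) with Dunn's
    post-hoc computed only when the omnibus p falls below ``posthoc_gate``.

    ``groups`` is a mapping label -> values or a sequence of value lists.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 3:
        raise ValidationError("kruskal_dunn needs at least 3 groups")
    if any(v.size == 0 for v in groups.values()):
        raise ValidationError("all groups must be non-empty")
    pooled = np.concatenate(list(groups.values()))
    if np.unique(pooled).size < 2:
        raise UndefinedTestError("all values tied; H statistic undefined")
    h, p = sps.kruskal(*groups.values())
    posthoc = _dunn_posthoc(groups) if p < posthoc_gate else None
    return GroupComparison(
        statistic_name="KruskalWallisH",
        statistic=float(h),
        p_value=float(p),
        method="chi-square",
        group_sizes={k: int(v.size) for k, v in groups.items()},
        posthoc=posthoc,
    )


def enrichment_scan(
    status: pd.Series, features: pd.DataFrame, family: str = "all"
) -> pd.DataFrame:
    """One Fisher test per binary feature against a binary methylation
    status, BH-adjusted across the declared family.

    ``status`` (bool per sample) and ``features`` (samples x features, 0/1)
    must cover identical samples. Zero-variance features are skipped with a
    note. Returns a table with the 2x2 counts, odds ratio, p, q and a
    ``significant`` flag at q < 0.05.
    """
    if set(status.index) != set(features.index):
        raise ValidationError("status and features must cover the same samples")
    features = features.loc[status.index]
    status_arr = status.astype(bool).to_numpy()
    rows = []
    for name in features.columns:
        feat = features[name]
        if feat.isna().any():
            raise ValidationError(f"feature {name!r} has missing values")
        feat_arr = feat.astype(bool).to_numpy()
        if feat_arr.all() or not feat_arr.any():
            logger.info("feature %r has zero variance; skipped", name)
            continue
        a = int(np.sum(status_arr & feat_arr))
        b = int(np.sum(status_arr & ~feat_arr))
        c = int(np.sum(~status_arr & feat_arr))
        d = int(np.sum(~status_arr & ~feat_arr))
        odds_ratio, p = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "feature": name,
                "family": family,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds_ratio,
                "p_value": p,
            }
        )
    scan = pd.DataFrame(
        rows,
        columns=["feature", "family", "a", "b", "c", "d", "odds_ratio", "p_value"],
    )
    if len(scan):
        scan["q_value"] = bh_adjust(scan["p_value"].to_numpy())
        scan["significant"] = scan["q_value"] < Q_SIGNIFICANT
    else:
        scan["q_value"] = pd.Series(dtype=float)
        scan["significant"] = pd.Series(dtype=bool)
    return scan


def score_by_class(
    classes: pd.Series, scores: pd.Series, hrd_threshold: float = 42.0
) -> tuple[GroupComparison, pd.DataFrame]:
    """Compare a per-sample score (e.g. HRD score) between zygosity classes.

    Two classes -> Mann-Whitney; three or more -> Kruskal-Wallis with Dunn.
    Also returns a per-class table of scores at or above ``hrd_threshold``
    (inclusive). Classes with no finite scores are dropped with a note.
    """
    common = classes.index.intersection(scores.index)
    if len(common) != len(classes) or len(common) != len(scores):
        raise ValidationError("classes and scores must cover the same samples")
    frame = pd.DataFrame(
        {"cls": classes.loc[common], "score": scores.loc[common]}
    ).dropna(subset=["score"])
    groups = {}
    for cls, sub in frame.groupby("cls", sort=True):
        if len(sub) == 0:
            logger.info("class %r has no scores; dropped", cls)
            continue
        groups[cls] = sub["score"].to_numpy()
    if len(groups) < 2:
        raise UndefinedTestError("need at least two classes with scores")
    if len(groups) == 2:
        (x, y) = groups.values()
        comparison = mann_whitney_u(x, y)
        comparison.group_sizes = {k: len(v) for k, v in groups.items()}
    else:
        comparison = kruskal_dunn(groups)
    threshold_table = pd.DataFrame(
        [
            {
                "class": cls,
                "n": len(vals),
                "n_ge_threshold": int(np.sum(vals >= hrd_threshold)),
                "threshold": hrd_threshold,
            }
            for cls, vals in groups.items()
        ]
    )
    return comparison, threshold_table


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with a 0.5 pseudo-count:
    ``log2((count + 0.5) / (library_size + 1) * 1e6)``.

    A documented simple transform for rank-based expression comparisons; it
    does not reproduce library-composition (TMM-style) normalisation.
    """
    counts_arr = counts.to_numpy(dtype=float)
    if np.any(counts_arr < 0):
        raise ValidationError("counts must be non-negative")
    lib = counts_arr.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[np.flatnonzero(lib <= 0)[0]]
        raise ValidationError(f"library size is zero for sample {bad!r}")
    cpm = (counts_arr + 0.5) / (lib + 1.0) * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)
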