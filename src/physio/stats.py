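"""Event-level aggregation and group-comparison statistics with FDR control.

Window-level features are first averaged within each event, then the
event-level estimates are averaged per participant, giving one value per
participant and feature.  Groups are compared with pooled-variance
independent-samples t-tests (equal group sizes make Student's t the
natural choice), reported with Cohen's d and the 95% CI of the mean
difference, and corrected within declared feature families with the
Benjamini-Hochberg step-up FDR procedure.  A Mann-Whitney U test (normal
approximation with tie correction) and Cronbach's alpha are provided for
the demographic and questionnaire-style checks the paradigm calls for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_MODALITY, FEATURE_NAMES, META_COLUMNS

log = logging.getLogger(__name__)

#: default analysis families for FDR correction
DEFAULT_FAMILIES = {f: "physiology" for f in FEATURE_NAMES}


@dataclass
class GroupComparisonRow:
    feature: str
    modality: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p_raw: float
    p_fdr: float
    d: float
    ci95: tuple[float, float]
    degenerate: bool = False


def aggregate_participant(features: pd.DataFrame) -> pd.DataFrame:
    """Two-stage aggregation: windows -> event means -> participant means.

    Events are weighted equally regardless of how many windows they
    contain.  Returns one row per participant (index ``participant_id``,
    a ``condition`` column, one column per feature); all-NaN features
    propagate as NaN.
    """
    if features.empty:
        raise ValueError("empty feature matrix")
    value_cols = [c for c in features.columns if c not in META_COLUMNS]
    event_means = features.groupby(
        ["participant_id", "condition", "event_id"], sort=False
    )[value_cols].mean()
    part = event_means.groupby(["participant_id", "condition"],
                               sort=False).mean().reset_index()
    return part.set_index("participant_id")


def ttest_ind(a, b) -> tuple[float, float, float, tuple[float, float]]:
    """Pooled-variance two-sample t-test with effect size and 95% CI.

    Returns ``(t, p, d, ci95)`` where d is Cohen's d (mean difference over
    pooled SD) and ci95 is the t-based confidence interval of the mean
    difference with ``n_a + n_b - 2`` degrees of freedom.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("degenerate groups: zero pooled variance")
    diff = a.mean() - b.mean()
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    d = diff / np.sqrt(sp2)
    tcrit = sps.t.ppf(0.975, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    return float(t), float(p), float(d), (float(ci[0]), float(ci[1]))


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation and tie correction.

    Returns ``(Z, p)`` two-sided.  Z is signed so that a tendency for `a`
    to exceed `b` gives positive Z; swapping the samples negates it.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[:na].sum()
    u = ra - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0, 1.0
    z = (u - mu) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Internal-consistency reliability of a respondents x items table."""
    x = np.asarray(items, float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 items and >= 2 respondents")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1 - item_var / total_var))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    participant_table: pd.DataFrame,
    families: dict[str, str] | None = None,
) -> list[GroupComparisonRow]:
    """Per-feature group comparison with family-wise BH-FDR correction.

    `participant_table` comes from :func:`aggregate_participant`.  Missing
    values are excluded pairwise; features constant in both groups are
    returned flagged ``degenerate`` with NaN statistics and are not fed to
    the FDR correction.  Rows are sorted by modality then feature name.
    """
    families = families or DEFAULT_FAMILIES
    conditions = participant_table["condition"].unique()
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    cond_a, cond_b = sorted(conditions)
    ga = participant_table[participant_table["condition"] == cond_a]
    gb = participant_table[participant_table["condition"] == cond_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("fewer than 2 participants per group")

    feature_cols = [c for c in participant_table.columns if c != "condition"]
    rows: list[GroupComparisonRow] = []
    for feat in feature_cols:
        a = ga[feat].to_numpy(float)
        b = gb[feat].to_numpy(float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        modality = FEATURE_MODALITY.get(feat, "other")
        try:
            t, p, d, ci = ttest_ind(a, b)
            degenerate = False
        except ValueError:
            t = p = d = np.nan
            ci = (np.nan, np.nan)
            degenerate = True
            log.warning("feature %r degenerate: excluded from comparison",
                        feat)
        rows.append(GroupComparisonRow(
            feature=feat, modality=modality,
            mean_a=float(np.mean(a)) if len(a) else np.nan,
            sd_a=float(np.std(a, ddof=1)) if len(a) > 1 else np.nan,
            mean_b=float(np.mean(b)) if len(b) else np.nan,
            sd_b=float(np.std(b, ddof=1)) if len(b) > 1 else np.nan,
            t=t, p_raw=p, p_fdr=np.nan, d=d, ci95=ci, degenerate=degenerate,
        ))

    # family-wise FDR over the non-degenerate rows
    by_family: dict[str, list[GroupComparisonRow]] = {}
    for row in rows:
        if not row.degenerate:
            by_family.setdefault(families.get(row.feature, "other"),
                                 []).append(row)
    for members in by_family.values():
        adj = bh_fdr([m.p_raw for m in members])
        for m, q in zip(members, adj):
            m.p_fdr = float(q)
    rows.sort(key=lambda r: (r.modality, r.feature))
    return rows


def comparison_table(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    """Flatten comparison rows into a report table (one row per feature)."""
    return pd.DataFrame([
        {
            "modality": r.modality, "feature": r.feature,
            "mean_a": r.mean_a, "sd_a": r.sd_a,
            "mean_b": r.mean_b, "sd_b": r.sd_b,
            "t": r.t, "p_raw": r.p_raw, "p_fdr": r.p_fdr, "d": r.d,
            "ci95_low": r.ci95[0], "ci95_high": r.ci95[1],
            "degenerate": r.degenerate,
        }
        for r in rows
    ])
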