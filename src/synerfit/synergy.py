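"""Composite mitochondrial-function score (PCA) and group comparisons.

The five endpoints are reduced to a single per-animal score: lower-is-better
endpoints (swelling slope PT, membrane viscosity FP) are negated so every
column points toward "healthier", columns are z-scored over the full animal
pool, and the first principal component is extracted.  The PC sign is
arbitrary, so the score is oriented such that the sham group mean exceeds
the vehicle group mean (fallback: positive loading on the viability
endpoint).  Group differences are tested by one-way ANOVA; the synergy
verdict compares the full combination against every mono- and bi-component
group at the same total dose with Welch pairwise tests (Holm-adjusted by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import zscore

__all__ = [
    "SynergyScore",
    "composite_score",
    "one_way_anova",
    "synergy_assessment",
    "LOWER_BETTER",
]

# endpoints whose direction of benefit is downward
LOWER_BETTER = ("PT", "FP")


@dataclass
class SynergyScore:
    scores: np.ndarray               # per-animal PC1 score
    groups: np.ndarray               # per-animal group label
    loadings: np.ndarray             # unit-norm, on the aligned+standardized scale
    explained_fraction: float
    endpoint_names: list[str]
    group_stats: pd.DataFrame        # group, n, mean, sd
    anova_f: float
    anova_p: float

    def group_mean(self, group: str) -> float:
        row = self.group_stats.loc[self.group_stats["group"] == group]
        if row.empty:
            raise KeyError(f"no group {group!r}")
        return float(row["mean"].iloc[0])


def composite_score(
    responses: pd.DataFrame,
    group_col: str = "group",
    endpoint_names: list[str] | None = None,
    align_directions: bool = True,
    sham_label: str = "sham",
    vehicle_label: str = "vehicle",
) -> SynergyScore:
    """PC1 composite of the endpoint columns, one score per animal.

    ``responses`` holds one row per animal with a group-label column plus
    the endpoint columns.  Standardization is over the full animal pool.
    """
    if group_col not in responses.columns:
        raise ValueError(f"responses must carry a {group_col!r} column")
    if endpoint_names is None:
        endpoint_names = [c for c in responses.columns if c != group_col]
    groups = responses[group_col].to_numpy()
    M = responses[endpoint_names].to_numpy(dtype=float)
    _, counts = np.unique(groups, return_counts=True)
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 groups with at least 2 animals each")

    signs = np.array(
        [-1.0 if (align_directions and n in LOWER_BETTER) else 1.0
         for n in endpoint_names]
    )
    Z = zscore(M * signs, names=endpoint_names)

    # PC1 by SVD of the standardized pool
    _, s, vt = np.linalg.svd(Z.values, full_matrices=False)
    loadings = vt[0]
    scores = Z.values @ loadings
    explained = float(s[0] ** 2 / (s**2).sum())

    # orientation: sham mean above vehicle mean, else positive first loading
    flip = False
    glabels = set(np.unique(groups))
    if sham_label in glabels and vehicle_label in glabels:
        if scores[groups == sham_label].mean() < scores[groups == vehicle_label].mean():
            flip = True
    elif loadings[0] < 0:
        flip = True
    if flip:
        loadings, scores = -loadings, -scores

    stats_df = (
        pd.DataFrame({"group": groups, "score": scores})
        .groupby("group", sort=False)["score"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    F, p = one_way_anova(scores, groups)
    return SynergyScore(
        scores=scores,
        groups=groups,
        loadings=loadings,
        explained_fraction=explained,
        endpoint_names=list(endpoint_names),
        group_stats=stats_df,
        anova_f=F,
        anova_p=p,
    )


def one_way_anova(scores: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical F = MS_between / MS_within with (k-1, N-k) df."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [scores[groups == g] for g in labels]
    if all(np.allclose(s, s.mean()) for s in samples):
        raise ValueError("zero within-group variance; F undefined")
    F, p = stats.f_oneway(*samples)
    return float(F), float(p)


def synergy_assessment(
    score: SynergyScore,
    design,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Per total dose: does the full combination beat every mono/pair group?

    ``design`` is a :class:`~synerfit.design.DesignTable` whose table has
    ``label`` and ``total`` columns (the synergistic layout).  Scores must
    carry group labels of the form ``"<label>@<total>"`` or plain labels if
    only one total dose is present.  The verdict for a total dose is
    "synergistic" when the combination's mean composite score exceeds every
    counterpart mean AND every Welch pairwise comparison is significant at
    ``alpha`` (Holm-adjusted across the comparisons of that dose by
    default; ``adjust="none"`` for unadjusted)."""
    t = design.table
    if "label" not in t.columns or "total" not in t.columns:
        raise ValueError("design must carry 'label' and 'total' columns")
    full_len = max(len(l) for l in t["label"])
    rows = []
    for total, sub in t.groupby("total"):
        labels = list(sub["label"])
        full = [l for l in labels if len(l) == full_len]
        if not full:
            raise ValueError(f"no full-combination group at total {total}")
        full = full[0]
        others = [l for l in labels if l != full]
        if not others:
            raise ValueError(f"no mono/pair counterpart groups at total {total}")

        def gname(label: str) -> str:
            tagged = f"{label}@{total:g}"
            present = set(score.groups)
            if tagged in present:
                return tagged
            if label in present:
                return label
            raise ValueError(f"missing counterpart group {tagged!r}")

        combo = score.scores[score.groups == gname(full)]
        pvals, exceeds = [], []
        for lab in others:
            other = score.scores[score.groups == gname(lab)]
            exceeds.append(combo.mean() > other.mean())
            pvals.append(
                stats.ttest_ind(combo, other, equal_var=False).pvalue
            )
        if adjust == "holm":
            sig = multipletests(pvals, alpha=alpha, method="holm")[0]
        elif adjust == "none":
            sig = np.asarray(pvals) < alpha
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append(
            {
                "total": total,
                "combination": full,
                "exceeds_all": bool(all(exceeds)),
                "all_significant": bool(all(sig)),
                "synergistic": bool(all(exceeds) and all(sig)),
                "comparisons": {
                    lab: {"exceeds": bool(e), "p": float(p), "significant": bool(s)}
                    for lab, e, p, s in zip(others, exceeds, pvals, sig)
                },
            }
        )
    return pd.DataFrame(rows)
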