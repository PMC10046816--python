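"""Nonparametric group and color-configuration statistics.

All comparisons are Mann-Whitney U tests on trial-level feature values
(trials, not subject means, are the sampling unit, since the same feature
is observed once per subject x CC).  Three scopes are covered:

* all_cc — dyslexic vs control pooled over every CC,
* single_cc — dyslexic vs control on one CC at a time (13 tests),
* cc_pair — CC vs CC within one group (C(13,2) = 78 tests),

plus a best-/worst-CC separability summary: for each subject the CC with
the lowest feature value (least struggle) is their *best* CC and the
highest their *worst*; contrasting control-best against dyslexic-worst
shows the classes maximally separated, while dyslexic-best against
control-worst shows them brought together.

P-values are two-sided and reported raw by default; Bonferroni or Holm
correction is available by flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import CC_LABELS

#: Largest pooled sample size for which the exact null distribution of U is
#: enumerated; above it (or with ties) the tie-corrected normal
#: approximation with continuity correction is used.
EXACT_N_MAX = 20


@dataclass
class ComparisonResult:
    """One two-sided Mann-Whitney comparison.

    ``u`` is the U statistic of sample a; ``method`` records whether the
    exact or the asymptotic branch produced ``p``.  ``missing`` flags a
    comparison that could not be run (e.g. a CC absent from one group).
    """

    scope: str                    # all_cc | single_cc | cc_pair
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u: float
    p: float
    method: str
    missing: bool = False

    def to_dict(self) -> dict:
        return {
            "scope": self.scope, "label_a": self.label_a, "label_b": self.label_b,
            "n_a": self.n_a, "n_b": self.n_b, "u": self.u, "p": self.p,
            "method": self.method, "missing": self.missing,
        }


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    scope: str = "all_cc",
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    The exact permutation null is used for pooled n <= 20 when the data are
    tie-free; otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_N_MAX and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        scope=scope, label_a=label_a, label_b=label_b,
        n_a=int(a.size), n_b=int(b.size),
        u=float(res.statistic), p=float(res.pvalue), method=method,
    )


def _adjust(results: List[ComparisonResult], correction: Optional[str]) -> None:
    if correction is None:
        return
    ps = np.array([r.p for r in results if not r.missing])
    m = ps.size
    if m == 0:
        return
    if correction == "bonferroni":
        adj = np.minimum(ps * m, 1.0)
    elif correction == "holm":
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * ps[i])
            adj[i] = min(running, 1.0)
    else:
        raise ValueError(f"unknown correction {correction!r}; use 'bonferroni' or 'holm'")
    it = iter(adj)
    for r in results:
        if not r.missing:
            r.p = float(next(it))


def group_comparison(
    records: pd.DataFrame, feature_name: str
) -> ComparisonResult:
    """Dyslexic vs control on one feature, all CCs pooled."""
    df = records.loc[records["feature_name"] == feature_name]
    a = df.loc[df["group"] == "dyslexic", "value"].to_numpy()
    b = df.loc[df["group"] == "control", "value"].to_numpy()
    return mann_whitney(a, b, scope="all_cc", label_a="dyslexic", label_b="control")


def per_cc_comparisons(
    records: pd.DataFrame,
    feature_name: str,
    correction: Optional[str] = None,
) -> List[ComparisonResult]:
    """Dyslexic vs control separately on each of the 13 CCs.

    A CC missing one of the groups yields a flagged result (``missing``,
    p = NaN) rather than being silently skipped.
    """
    df = records.loc[records["feature_name"] == feature_name]
    results: List[ComparisonResult] = []
    for cc in CC_LABELS:
        sub = df.loc[df["cc"] == cc]
        a = sub.loc[sub["group"] == "dyslexic", "value"].to_numpy()
        b = sub.loc[sub["group"] == "control", "value"].to_numpy()
        if a.size == 0 or b.size == 0:
            results.append(ComparisonResult(
                scope="single_cc", label_a=cc, label_b=cc,
                n_a=int(a.size), n_b=int(b.size),
                u=float("nan"), p=float("nan"), method="none", missing=True,
            ))
        else:
            r = mann_whitney(a, b, scope="single_cc", label_a=cc, label_b=cc)
            results.append(r)
    _adjust(results, correction)
    return results


def pairwise_cc_within_group(
    records: pd.DataFrame,
    group: str,
    feature_name: str,
    correction: Optional[str] = None,
) -> List[ComparisonResult]:
    """All C(13,2) = 78 CC-vs-CC comparisons of trial values within a group."""
    df = records.loc[
        (records["feature_name"] == feature_name) & (records["group"] == group)
    ]
    if df.empty:
        raise ValueError(f"group {group!r} has no trials for feature {feature_name!r}")
    values = {cc: df.loc[df["cc"] == cc, "value"].to_numpy() for cc in CC_LABELS}
    results: List[ComparisonResult] = []
    for cc_a, cc_b in itertools.combinations(CC_LABELS, 2):
        a, b = values[cc_a], values[cc_b]
        if a.size == 0 or b.size == 0:
            results.append(ComparisonResult(
                scope="cc_pair", label_a=cc_a, label_b=cc_b,
                n_a=int(a.size), n_b=int(b.size),
                u=float("nan"), p=float("nan"), method="none", missing=True,
            ))
        else:
            results.append(mann_whitney(a, b, scope="cc_pair", label_a=cc_a, label_b=cc_b))
    _adjust(results, correction)
    return results


@dataclass
class CCSummary:
    """Best-/worst-CC separability summary for one feature.

    ``per_subject`` has one row per subject with its best/worst CC and the
    feature values there; ``distributions`` holds the four boxplot
    conditions; ``best_counts`` / ``worst_counts`` are the per-group CC
    frequency tables behind the pie charts.
    """

    feature_name: str
    per_subject: pd.DataFrame
    distributions: Dict[str, np.ndarray]   # control_best, control_worst, dyslexic_best, dyslexic_worst
    best_counts: pd.DataFrame              # group, cc, count
    worst_counts: pd.DataFrame

    def to_tidy(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        """(boxplot data, pie data) as tidy frames ready for any plotting layer."""
        box = pd.concat([
            pd.DataFrame({"condition": cond, "value": vals})
            for cond, vals in self.distributions.items()
        ], ignore_index=True)
        pies = pd.concat([
            self.best_counts.assign(extreme="best"),
            self.worst_counts.assign(extreme="worst"),
        ], ignore_index=True)
        return box, pies


def best_worst_summary(records: pd.DataFrame, feature_name: str) -> CCSummary:
    """Per-subject best (argmin) / worst (argmax) CC and the four contrasts.

    Lower feature values mean less reading struggle, so the best CC is the
    argmin of the subject's trial values and the worst the argmax; ties
    break to the first CC in canonical label order.  Subjects with excluded
    trials are summarized over their available CCs.
    """
    df = records.loc[records["feature_name"] == feature_name]
    rows = []
    for subject, sub in df.groupby("subject_id", sort=True):
        by_cc = sub.groupby("cc")["value"].mean()
        if by_cc.empty:
            raise ValueError(f"subject {subject!r} has no trials for feature {feature_name!r}")
        by_cc = by_cc.reindex([cc for cc in CC_LABELS if cc in by_cc.index])
        best_cc = by_cc.idxmin()    # first occurrence in canonical order on ties
        worst_cc = by_cc.idxmax()
        rows.append((subject, sub["group"].iloc[0], best_cc, float(by_cc[best_cc]),
                     worst_cc, float(by_cc[worst_cc])))
    per_subject = pd.DataFrame(
        rows, columns=["subject_id", "group", "best_cc", "best_value", "worst_cc", "worst_value"]
    )
    distributions = {
        f"{grp}_{extreme}": per_subject.loc[per_subject["group"] == grp, f"{extreme}_value"].to_numpy()
        for grp in ("control", "dyslexic")
        for extreme in ("best", "worst")
    }
    def counts(col: str) -> pd.DataFrame:
        c = (per_subject.groupby(["group", col]).size()
             .rename("count").reset_index().rename(columns={col: "cc"}))
        return c
    return CCSummary(
        feature_name=feature_name,
        per_subject=per_subject,
        distributions=distributions,
        best_counts=counts("best_cc"),
        worst_counts=counts("worst_cc"),
    )


__all__ = [
    "EXACT_N_MAX", "ComparisonResult", "CCSummary",
    "mann_whitney", "group_comparison", "per_cc_comparisons",
    "pairwise_cc_within_group", "best_worst_summary",
]
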