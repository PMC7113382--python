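"""Group comparisons with FDR control.

Efficiency measures are compared with Student's t (pooled variance by
default, Welch behind a flag); cognitive scores with the Kruskal–Wallis
rank test; demographic 2x2 tables with a chi-square test (Yates-corrected by
default, the small-sample convention). Benjamini–Hochberg adjustment is
applied within each family of tests — efficiency variables form one family,
cognitive scores another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "students_t",
    "kruskal_wallis",
    "chi_square_2x2",
    "bh_fdr",
    "compare_cohort",
]


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    group_summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_raw <= 1 and 0 <= self.p_adjusted <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be smaller than raw p")


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values in sample")
    return a


def students_t(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test; pooled variance unless ``welch``."""
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("both groups constant with different means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction, chi-square reference."""
    samples = [_clean(g) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if sum(s.size for s in samples) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # degenerate but well-defined: no rank variation
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def chi_square_2x2(table, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, Yates-corrected by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all table margins must be positive")
    res = stats.chi2_contingency(t, correction=yates)
    return float(res[0]), float(res[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _summaries(by_group: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    return {
        g: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0, "n": int(v.size)}
        for g, v in by_group.items()
    }


def compare_cohort(
    efficiency_table: pd.DataFrame,
    manifest: pd.DataFrame,
    group_order: tuple[str, str] = ("HC", "IC"),
) -> list[ComparisonResult]:
    """Full group comparison: t-tests on E_global and each E_s, Kruskal–Wallis
    on each cognitive score, BH-FDR within each family.

    ``efficiency_table`` needs a ``subject_id`` column plus ``E_*`` columns;
    ``manifest`` needs ``subject_id``, ``group`` and ``score_*`` columns.
    The t statistic is signed as group_order[0] minus group_order[1].
    """
    eff_ids = set(efficiency_table["subject_id"])
    man_ids = set(manifest["subject_id"])
    if eff_ids != man_ids:
        missing = sorted(eff_ids.symmetric_difference(man_ids))
        raise ValueError(f"subject ids do not match between tables: {missing}")
    merged = efficiency_table.merge(manifest, on="subject_id", validate="one_to_one")
    groups = merged["group"]
    unknown = set(group_order) - set(groups)
    if unknown:
        raise ValueError(f"groups {sorted(unknown)} absent from manifest")

    eff_cols = [c for c in efficiency_table.columns if c == "E_global" or
                (c.startswith("E_") and not c.startswith("E_global"))]
    score_cols = [c for c in manifest.columns if c.startswith("score_")]

    results: list[ComparisonResult] = []
    eff_entries = []
    for col in eff_cols:
        by_group = {g: merged.loc[groups == g, col].to_numpy(dtype=float) for g in group_order}
        t, p = students_t(by_group[group_order[0]], by_group[group_order[1]])
        eff_entries.append((col, "student_t", t, p, _summaries(by_group)))
    score_entries = []
    for col in score_cols:
        by_group = {g: merged.loc[groups == g, col].to_numpy(dtype=float) for g in group_order}
        h, p = kruskal_wallis([by_group[g] for g in group_order])
        score_entries.append((col, "kruskal_wallis", h, p, _summaries(by_group)))

    for entries in (eff_entries, score_entries):
        if not entries:
            continue
        adj = bh_fdr([e[3] for e in entries])
        for (col, test, stat, p, summ), p_adj in zip(entries, adj):
            results.append(
                ComparisonResult(
                    variable=col, test=test, statistic=stat, p_raw=p,
                    p_adjusted=float(p_adj), group_summaries=summ,
                )
            )
    return results


def results_table(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "test": r.test,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_fdr": r.p_adjusted,
            }
            for r in results
        ]
    )
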