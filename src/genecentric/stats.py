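"""Two-group nonparametric testing with cross-cohort consistency calls.

Differences in gene-family or clade abundance between the two
phenotypic groups of each cohort are assessed with two-sided
Mann-Whitney U tests (exact enumeration for small tie-free samples,
normal approximation with tie and continuity corrections otherwise),
adjusted per cohort with the Benjamini-Hochberg step-up procedure.
A feature is called consistent across cohorts when its direction of
change agrees everywhere and reaches adjusted significance in at least
``min_significant`` cohorts; named cohorts can be exempted from the
significance count (e.g. a cohort containing only diseased subjects).
Universal single-copy genes serve as a negative control: the control
passes when none of them is significant in any cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 12   # exact enumeration when n_a + n_b <= this and no ties


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U_a, U_b)`` under midrank
    handling of ties.  The p-value is exact (full enumeration of
    labelings) when the pooled sample size is at most 12 and there are
    no ties, otherwise a normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)


def mann_whitney_exact_oracle(group_a, group_b) -> float:
    """Brute-force exact two-sided p by enumerating all labelings.

    Counts label assignments whose rank-sum statistic is at least as far
    from its null mean as the observed one.  Intended as an independent
    check at small n; O(C(n, n_a)).
    """
    from itertools import combinations

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    ranks = rankdata(pooled)
    center = n_a * (n + 1) / 2.0
    obs = abs(ranks[:n_a].sum() - center)
    hits = total = 0
    for comb in combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(comb)].sum() - center) >= obs - 1e-12:
            hits += 1
    return hits / total


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Per-feature, per-cohort two-group test outcome."""

    feature: str
    cohort: str
    median_control: float
    median_disease: float
    fold_change: float           # disease / control; nan when 0/0
    direction: str               # up / down / flat
    u_statistic: float
    p_raw: float
    q: float = float("nan")


def _direction(med_c: float, med_d: float) -> tuple[float, str]:
    if med_c == 0 and med_d == 0:
        return float("nan"), "flat"
    if med_c == 0:
        return float("inf"), "up"
    fc = med_d / med_c
    if fc > 1:
        return fc, "up"
    if fc < 1:
        return fc, "down"
    return fc, "flat"


def compare_groups(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Test every feature in every cohort; BH within each cohort batch.

    ``table`` is features x samples (RPKSM or percent abundances);
    ``samples`` must carry ``sample_id``, ``cohort`` and ``role``
    (control/disease) columns, each cohort having exactly those two
    roles.  Fold change is the ratio of group medians
    (disease / control); 0/0 is flagged flat and x/0 as infinite.
    """
    meta = samples.set_index("sample_id")
    missing = [c for c in table.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = meta.loc[list(table.columns)]
    feats = list(features) if features is not None else list(table.index)

    rows = []
    for cohort, cols in meta.groupby("cohort").groups.items():
        roles = meta.loc[list(cols), "role"]
        role_set = set(roles.unique())
        if role_set != {"control", "disease"}:
            raise ValueError(
                f"cohort {cohort} must have exactly the control/disease "
                f"roles, found {sorted(role_set)}")
        ctrl_cols = roles[roles == "control"].index
        dis_cols = roles[roles == "disease"].index
        batch = []
        for feat in feats:
            a = table.loc[feat, ctrl_cols].to_numpy(dtype=float)
            b = table.loc[feat, dis_cols].to_numpy(dtype=float)
            u, p = mann_whitney(a, b)
            med_c, med_d = float(np.median(a)), float(np.median(b))
            fc, direction = _direction(med_c, med_d)
            batch.append(ComparisonResult(
                feature=str(feat), cohort=str(cohort),
                median_control=med_c, median_disease=med_d,
                fold_change=fc, direction=direction,
                u_statistic=u, p_raw=p))
        q = bh_adjust([r.p_raw for r in batch])
        for r, qi in zip(batch, q):
            r.q = float(qi)
        rows.extend(batch)
    return pd.DataFrame([vars(r) for r in rows])


def cross_cohort_consistency(
    results: pd.DataFrame,
    min_significant: int = 2,
    alpha: float = 0.05,
    exempt_cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Call per-feature cross-cohort verdicts.

    ``consistent-significant``: the direction is identical (and not
    flat) in every cohort AND q < alpha in at least ``min_significant``
    cohorts, exempted cohorts not counting toward (or against) the
    significance quota.  ``trend-only``: directions agree but the
    significance count falls short.  Anything else: ``inconsistent``.
    Features tested in fewer than two cohorts are skipped with a
    warning.
    """
    exempt = set(exempt_cohorts or [])
    calls = []
    for feat, sub in results.groupby("feature", sort=False):
        if sub["cohort"].nunique() < 2:
            warnings.warn(f"feature {feat} tested in < 2 cohorts; skipped")
            continue
        directions = set(sub["direction"])
        n_sig = int(((sub["q"] < alpha) & ~sub["cohort"].isin(exempt)).sum())
        if len(directions) == 1 and directions != {"flat"}:
            verdict = ("consistent-significant" if n_sig >= min_significant
                       else "trend-only")
        else:
            verdict = "inconsistent"
        calls.append({
            "feature": feat,
            "direction": sub["direction"].iloc[0] if len(directions) == 1 else "mixed",
            "n_cohorts": int(sub["cohort"].nunique()),
            "n_significant": n_sig,
            "verdict": verdict,
        })
    return pd.DataFrame(calls)


def uscg_control(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    uscg_features: list[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, bool]:
    """Negative control on universal single-copy genes.

    Runs `compare_groups` restricted to the USCG features; the control
    passes when no USCG reaches q < alpha in any cohort — single-copy
    housekeeping genes should track total bacterial load, not phenotype.
    """
    present = [f for f in uscg_features if f in table.index]
    if not present:
        raise ValueError("no USCG features present in the table")
    results = compare_groups(table.loc[present], samples)
    passed = bool((results["q"] >= alpha).all())
    return results, passed
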