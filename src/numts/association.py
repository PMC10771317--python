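"""numTS <-> miRNA-expression association analyses.

In healthy tissue, miRNA abundance and the abundance of its binding
opportunities (numTS) track each other — binding is a stoichiometric
process and homeostasis couples the two.  Tumors with pervasive 3'UTR
shortening break that coupling.  This module quantifies the relationship:
per-family squared Spearman correlation, a rank-sum test for the
tumor-vs-normal disruption of those squared correlations, and the
BH-significant correlated family set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "correlation_profile",
    "disruption_test",
    "significant_correlated_set",
    "DisruptionResult",
]

_EXACT_MAX_N = 8  # full permutation enumeration up to n! = 40320


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(ry)))
    rx_c = rx - rx.mean()
    perms_c = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (perms_c**2).sum(axis=1))
    rhos = perms_c @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p (exact enumeration for tiny n)."""
    n = len(x)
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        return np.nan, np.nan
    if n <= _EXACT_MAX_N:
        return float(rho), _spearman_exact_p(x, y, rho)
    if abs(rho) >= 1.0:
        return float(rho), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return float(rho), float(2 * stats.t.sf(abs(t), df=n - 2))


def correlation_profile(
    numts: pd.DataFrame, expr: pd.DataFrame
) -> pd.DataFrame:
    """Per-family Spearman correlation between numTS and miRNA expression.

    Both inputs are family x sample matrices over the same samples; rows
    are matched by family ID and families missing from either matrix are
    dropped with a warning.  Families with a constant vector in either
    matrix get NaN rho/p and are excluded from the BH correction.

    Returns a DataFrame indexed by family with columns
    ``rho, rho_sq, p, q, n``.
    """
    if not numts.columns.equals(expr.columns):
        raise ValueError("correlation_profile: inputs must be sample-aligned")
    n = numts.shape[1]
    if n < 3:
        raise ValueError(f"correlation_profile: need >=3 samples, got {n}")
    common = numts.index.intersection(expr.index)
    dropped = len(numts.index.union(expr.index)) - len(common)
    if dropped:
        warnings.warn(
            f"correlation_profile: dropping {dropped} families missing "
            "from one of the matrices"
        )
    if len(common) == 0:
        raise ValueError("correlation_profile: no shared families")

    rows = []
    for fam in common:
        x = numts.loc[fam].to_numpy(dtype=float)
        y = expr.loc[fam].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((fam, np.nan, np.nan, np.nan, n))
            continue
        rho, p = _spearman(x, y)
        rows.append((fam, rho, rho**2, p, n))
    profile = pd.DataFrame(
        rows, columns=["mirna_family", "rho", "rho_sq", "p", "n"]
    ).set_index("mirna_family")

    q = np.full(len(profile), np.nan)
    ok = profile["p"].notna().to_numpy()
    if ok.any():
        q[ok] = multipletests(profile["p"].to_numpy()[ok], method="fdr_bh")[1]
    profile["q"] = q
    return profile[["rho", "rho_sq", "p", "q", "n"]]


@dataclass
class DisruptionResult:
    statistic: float
    p: float
    direction: str          # "normal > tumor", "tumor > normal" or "none"
    median_difference: float  # median rho_sq(normal) - median rho_sq(tumor)
    n_normal: int
    n_tumor: int


def disruption_test(
    profile_tumor: pd.DataFrame,
    profile_normal: pd.DataFrame,
    paired: bool = False,
) -> DisruptionResult:
    """Test whether squared correlations drop from normal to tumor.

    Two-sided Wilcoxon rank-sum on the per-family rho^2 distributions (the
    default, treating the two tissue profiles as independent samples);
    ``paired=True`` switches to the signed-rank test on per-family
    differences for users who prefer to exploit the family pairing.
    """
    t = profile_tumor["rho_sq"].dropna()
    n = profile_normal["rho_sq"].dropna()
    if len(t) < 2 or len(n) < 2:
        raise ValueError("disruption_test: need >=2 non-missing rho_sq per group")
    if paired:
        common = t.index.intersection(n.index)
        diff = n.loc[common] - t.loc[common]
        if (diff == 0).all():
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(n.loc[common], t.loc[common])
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(n, t, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    med_diff = float(np.median(n) - np.median(t))
    if med_diff > 0:
        direction = "normal > tumor"
    elif med_diff < 0:
        direction = "tumor > normal"
    else:
        direction = "none"
    return DisruptionResult(stat, p, direction, med_diff, len(n), len(t))


def significant_correlated_set(
    profile: pd.DataFrame, q_cutoff: float = 0.05
) -> tuple[set, float]:
    """Families whose numTS-expression correlation survives BH at *q_cutoff*.

    Returns the significant family set and the percentage of (non-missing)
    families that are NOT significant — the fraction of miRNAs whose
    target-site abundance is uncoupled from expression.
    """
    ok = profile["q"].notna()
    sig = set(profile.index[ok & (profile["q"] < q_cutoff)])
    n_tested = int(ok.sum())
    if n_tested == 0:
        return set(), 100.0
    frac_nonsig = 100.0 * (n_tested - len(sig)) / n_tested
    return sig, frac_nonsig
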