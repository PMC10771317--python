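"""Elastic-net prediction of tumor phenotype scores from numTS or expression.

The workhorse is an elastic net with the penalty strength chosen by
10-fold cross-validation under the one-standard-error (1se) rule: among
all grid points whose CV error is within one SE of the minimum, pick the
most parsimonious (largest penalty).  On top of it sit

* nested CV performance estimation (repeated random 75/25 splits, RMSE on
  the held-out quarter),
* paired comparison of two feature sets sharing the outer splits,
* bootstrap stability selection (selection frequency of each feature over
  B bootstrap refits), and
* an exact hypergeometric test for the overlap of two selected sets.

Feature standardization always happens inside the training data of the
fold/bootstrap at hand — never on held-out samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

__all__ = [
    "NestedCvConfig",
    "RmseDistribution",
    "FeatureSetComparison",
    "StabilitySelectionResult",
    "ElasticNetFit",
    "fit_enet_cv",
    "nested_cv_rmse",
    "compare_feature_sets",
    "bootstrap_stability_selection",
    "hypergeometric_overlap",
]

_L1_FLOOR = 0.01  # coordinate descent is unreliable at pure ridge on an L1 path


@dataclass
class NestedCvConfig:
    """Settings for the nested cross-validation performance estimate."""

    outer_repeats: int = 300
    outer_test_fraction: float = 0.25
    inner_folds: int = 10
    l1_ratio_grid: tuple = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))
    n_alphas: int = 20
    lambda_rule: str = "one_se"  # or "min"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.outer_test_fraction < 1:
            raise ValueError("outer_test_fraction must be in (0, 1)")
        if any(not 0 <= a <= 1 for a in self.l1_ratio_grid):
            raise ValueError("l1 ratios must lie in [0, 1]")
        if self.lambda_rule not in ("one_se", "min"):
            raise ValueError("lambda_rule must be 'one_se' or 'min'")


@dataclass
class ElasticNetFit:
    """A fitted elastic net on the original feature scale."""

    coef: np.ndarray          # p, original scale
    intercept: float
    l1_ratio: float
    alpha: float              # chosen penalty strength
    alpha_cv_min: float       # CV-error-minimizing penalty on the same path
    support: np.ndarray       # boolean, nonzero standardized coefficients

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _alpha_grid(Xs, yc, l1_ratio, n_alphas, eps):
    n = Xs.shape[0]
    alpha_max = np.abs(Xs.T @ yc).max() / (n * max(l1_ratio, _L1_FLOOR))
    if alpha_max <= 0:
        return None
    return np.geomspace(alpha_max, alpha_max * eps, n_alphas)


def fit_enet_cv(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratios=(0.5,),
    n_alphas: int = 20,
    n_folds: int = 10,
    rule: str = "one_se",
    rng: np.random.Generator | None = None,
    groups: np.ndarray | None = None,
    alpha_eps: float = 1e-3,
) -> ElasticNetFit:
    """Elastic net with (l1_ratio, alpha) chosen by k-fold CV.

    The alpha path per l1 ratio is shared across folds (computed from the
    full training data, as in the usual glmnet workflow); inside each fold
    standardization uses fold-train statistics only.  ``rule='one_se'``
    picks the largest alpha whose mean CV error is within one standard
    error of the minimum (ties on alpha broken toward larger l1 ratio);
    ``rule='min'`` picks the minimizer.

    *groups*, when given, assigns folds by group label rather than by row,
    so duplicated observations (e.g. bootstrap copies of one sample) never
    sit on both sides of a CV split.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    Xs_all, mu_all, sd_all = _standardize(X)
    y_mean_all = y.mean()
    paths = {}
    for r in l1_ratios:
        grid = _alpha_grid(Xs_all, y - y_mean_all, r, n_alphas, alpha_eps)
        if grid is not None:
            paths[r] = grid
    if not paths:  # y (or every feature) constant: intercept-only model
        return ElasticNetFit(
            coef=np.zeros(p), intercept=float(y_mean_all), l1_ratio=float(l1_ratios[0]),
            alpha=np.inf, alpha_cv_min=np.inf, support=np.zeros(p, dtype=bool),
        )

    if groups is None:
        kf = KFold(n_splits=n_folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        splits = list(kf.split(X))
    else:
        uniq = np.unique(groups)
        perm = rng.permutation(uniq)
        chunks = np.array_split(perm, n_folds)
        splits = []
        for chunk in chunks:
            va = np.flatnonzero(np.isin(groups, chunk))
            tr = np.flatnonzero(~np.isin(groups, chunk))
            if len(va) and len(tr):
                splits.append((tr, va))
        n_folds = len(splits)
    sq_err = {r: np.zeros((n_folds, len(paths[r]))) for r in paths}
    for f, (tr, va) in enumerate(splits):
        Xtr_s, mu, sd = _standardize(X[tr])
        ytr = y[tr]
        ym = ytr.mean()
        Xva_s = (X[va] - mu) / sd
        for r, alphas in paths.items():
            _, coefs, _ = enet_path(
                Xtr_s, ytr - ym, l1_ratio=max(r, _L1_FLOOR), alphas=alphas,
                tol=1e-3,
            )
            pred = Xva_s @ coefs + ym  # (n_va, n_alphas)
            sq_err[r][f] = ((pred - y[va][:, None]) ** 2).mean(axis=0)

    # aggregate, apply the selection rule
    best = None  # (mean, -alpha) minimization for 'min'
    table = []
    for r, alphas in paths.items():
        mean = sq_err[r].mean(axis=0)
        se = sq_err[r].std(axis=0, ddof=1) / np.sqrt(n_folds)
        for j, a in enumerate(alphas):
            table.append((r, a, mean[j], se[j]))
    table = np.array(table)
    i_min = int(np.argmin(table[:, 2]))
    alpha_cv_min = float(table[i_min, 1])
    if rule == "min":
        r_sel, a_sel = float(table[i_min, 0]), float(table[i_min, 1])
    else:
        thr = table[i_min, 2] + table[i_min, 3]
        cand = table[table[:, 2] <= thr]
        # most parsimonious: largest alpha, then largest l1 ratio
        order = np.lexsort((cand[:, 0], cand[:, 1]))
        r_sel, a_sel = float(cand[order[-1], 0]), float(cand[order[-1], 1])

    _, coefs, _ = enet_path(
        Xs_all, y - y_mean_all, l1_ratio=max(r_sel, _L1_FLOOR),
        alphas=paths[r_sel], tol=1e-3,
    )
    j = int(np.argmin(np.abs(paths[r_sel] - a_sel)))
    coef_std = coefs[:, j]
    support = coef_std != 0
    coef = coef_std / sd_all
    intercept = float(y_mean_all - coef @ mu_all)
    return ElasticNetFit(coef, intercept, r_sel, a_sel, alpha_cv_min, support)


# ---------------------------------------------------------------------------
# nested CV performance
# ---------------------------------------------------------------------------

@dataclass
class RmseDistribution:
    rmse: np.ndarray
    chosen_alphas: np.ndarray
    cv_min_alphas: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.rmse.mean())

    @property
    def se(self) -> float:
        return float(self.rmse.std(ddof=1) / np.sqrt(len(self.rmse)))


def _as_samples_by_features(X) -> np.ndarray:
    """Accept a feature x sample DataFrame or a samples x features array."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float).T
    return np.asarray(X, dtype=float)


def nested_cv_rmse(X, y, cfg: NestedCvConfig) -> RmseDistribution:
    """Held-out RMSE over repeated random 75/25 splits with inner-CV tuning.

    *X* is a feature x sample DataFrame (or samples x features array), *y*
    the per-sample outcome.  Each repeat draws a fresh split from the
    config seed, tunes (l1_ratio, alpha) by inner k-fold CV on the
    training part, refits there, and scores RMSE on the held-out part.
    """
    Xv = _as_samples_by_features(X)
    yv = np.asarray(y, dtype=float)
    if Xv.shape[0] != len(yv):
        raise ValueError("X and y have mismatched sample counts")
    if not np.isfinite(yv).all():
        raise ValueError("outcome vector must be finite")
    n = len(yv)
    if n < 20:
        raise ValueError(f"need >=20 samples for nested CV, got {n}")
    rmses, alphas, alpha_mins = [], [], []
    for rep in range(cfg.outer_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, rep]))
        perm = rng.permutation(n)
        n_test = max(1, int(round(n * cfg.outer_test_fraction)))
        test, train = perm[:n_test], perm[n_test:]
        fit = fit_enet_cv(
            Xv[train], yv[train], l1_ratios=cfg.l1_ratio_grid,
            n_alphas=cfg.n_alphas, n_folds=cfg.inner_folds,
            rule=cfg.lambda_rule, rng=rng,
        )
        resid = fit.predict(Xv[test]) - yv[test]
        rmses.append(float(np.sqrt(np.mean(resid**2))))
        alphas.append(fit.alpha)
        alpha_mins.append(fit.alpha_cv_min)
    return RmseDistribution(np.array(rmses), np.array(alphas), np.array(alpha_mins))


@dataclass
class FeatureSetComparison:
    rmse_a: RmseDistribution
    rmse_b: RmseDistribution
    percent_decrease: float  # 100 * (mean_b - mean_a) / mean_b


def compare_feature_sets(X_a, X_b, y, cfg: NestedCvConfig) -> FeatureSetComparison:
    """Paired nested-CV comparison of two feature sets on identical splits.

    Repeats share the outer split (same seed-derived permutation), so the
    RMSE difference per repeat is a paired contrast.  ``percent_decrease``
    is the relative RMSE reduction of the first set versus the second:
    100 * (mean RMSE_b - mean RMSE_a) / mean RMSE_b.
    """
    Xa = _as_samples_by_features(X_a)
    Xb = _as_samples_by_features(X_b)
    yv = np.asarray(y, dtype=float)
    if Xa.shape[0] != Xb.shape[0] or Xa.shape[0] != len(yv):
        raise ValueError("feature sets must cover identical samples")
    out = []
    for Xv in (Xa, Xb):
        out.append(nested_cv_rmse(Xv, yv, cfg))
    dist_a, dist_b = out
    pct = 100.0 * (dist_b.mean - dist_a.mean) / dist_b.mean
    return FeatureSetComparison(dist_a, dist_b, pct)


# ---------------------------------------------------------------------------
# bootstrap stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilitySelectionResult:
    frequencies: pd.Series       # per feature, in [0, 1]
    predictive_set: set
    B: int
    n_skipped: int
    rule: dict = field(default_factory=dict)


def bootstrap_stability_selection(
    X,
    y,
    B: int = 200,
    rule: dict | None = None,
    seed: int = 0,
    l1_ratio: float = 0.5,
    inner_folds: int = 10,
    n_alphas: int = 15,
    alpha_eps: float = 1e-2,
) -> StabilitySelectionResult:
    """Selection frequency of each feature over B bootstrap elastic nets.

    Each bootstrap resamples the samples with replacement, tunes the
    penalty by inner k-fold CV (1se rule, mixing parameter fixed at
    ``l1_ratio``), and records the support of the refit.  Frequencies are
    counts / B.  The predictive set follows *rule*:

    * ``{"top_fraction": 0.5}`` — rank features by frequency and keep the
      top half, including ties at the cutoff (never-selected features are
      excluded);
    * ``{"min_frequency": 0.7}`` — keep features selected in >=70% of
      bootstraps.
    """
    rule = rule if rule is not None else {"top_fraction": 0.5}
    Xv = _as_samples_by_features(X)
    names = (
        list(X.index) if isinstance(X, pd.DataFrame)
        else [f"f{i}" for i in range(Xv.shape[1])]
    )
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < 20:
        raise ValueError(f"need >=20 samples, got {n}")
    counts = np.zeros(p)
    n_skipped = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        idx = rng.integers(0, n, n)
        yb = yv[idx]
        if np.ptp(yb) == 0:
            n_skipped += 1
            warnings.warn(f"bootstrap {b}: constant outcome, skipped")
            continue
        fit = fit_enet_cv(
            Xv[idx], yb, l1_ratios=(l1_ratio,), n_alphas=n_alphas,
            n_folds=inner_folds, rule="one_se", rng=rng, groups=idx,
            alpha_eps=alpha_eps,
        )
        counts += fit.support
    if n_skipped > 0.1 * B:
        raise RuntimeError(f"{n_skipped}/{B} bootstraps degenerate")
    freq = pd.Series(counts / B, index=names, name="selection_frequency")

    if "min_frequency" in rule:
        selected = set(freq.index[freq >= rule["min_frequency"]])
    elif "top_fraction" in rule:
        k = int(np.ceil(p * rule["top_fraction"]))
        order = freq.sort_values(ascending=False, kind="stable")
        cutoff = order.iloc[k - 1]
        selected = set(freq.index[(freq >= cutoff) & (freq > 0)])
    else:
        raise ValueError("rule must contain 'top_fraction' or 'min_frequency'")
    return StabilitySelectionResult(freq, selected, B, n_skipped, dict(rule))


def hypergeometric_overlap(set_a, set_b, universe) -> tuple[float, int]:
    """Upper-tail hypergeometric p for the overlap of two feature sets.

    With N = |universe|, K = |set_a| successes and n = |set_b| draws, the
    p-value is P(X >= k) for the observed overlap k = |A & B|.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = float(hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return p, k
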