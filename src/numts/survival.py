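"""Cox survival modeling with target-site-change (delta-numTS) features.

Three nested models per cohort:

* clinical-only — age, gender, stage (optionally smoking);
* numts-clinical — clinical covariates plus the delta-numTS of the miRNA
  families picked by a LASSO-Cox in which the clinical covariates are
  unpenalized (always kept) and only the family features are shrunk;
* expr-clinical — clinical covariates plus the delta-expression of the
  *same* families, so the comparison isolates what the target-site change
  adds over the expression change of identical miRNAs.

Model comparison uses the likelihood-ratio test on unpenalized refits
(an LRT on penalized partial likelihoods is not well defined), and risk
stratification splits patients at the median linear predictor, with
Kaplan-Meier curves and the log-rank test per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import chi2
from sklearn.model_selection import KFold
from sksurv.exceptions import NoComparablePairException
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = [
    "CoxModel",
    "LrtResult",
    "RiskStratification",
    "SurvivalModelSet",
    "encode_clinical",
    "fit_cox",
    "lasso_cox_select",
    "augment_with_expression",
    "risk_stratify",
    "lrt_compare",
    "build_survival_model_set",
]


@dataclass
class CoxModel:
    covariates: list
    coef: pd.Series               # log hazard ratios
    log_likelihood: float         # log partial likelihood at the fit
    n: int
    events: int

    def linear_predictor(self, covariates: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.covariates if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariates missing columns {missing}")
        X = covariates[self.covariates].to_numpy(dtype=float)
        return pd.Series(X @ self.coef.to_numpy(), index=covariates.index)


def encode_clinical(
    clinical: pd.DataFrame, stage_coding: str = "ordinal"
) -> pd.DataFrame:
    """Numeric design matrix from the clinical table (patient-level rows).

    Age stays continuous; gender becomes a 0/1 indicator; stage is coded
    ordinal-as-numeric by default or as dummy indicators
    (``stage_coding="dummy"``); a ``smoking`` flag is kept when present.
    """
    out = pd.DataFrame(index=clinical.index)
    if "age" in clinical.columns:
        out["age"] = clinical["age"].astype(float)
    if "gender" in clinical.columns:
        cats = pd.Categorical(clinical["gender"])
        if len(cats.categories) > 1:
            out["gender"] = cats.codes.astype(float)
    if "stage" in clinical.columns:
        if stage_coding == "ordinal":
            out["stage"] = pd.to_numeric(clinical["stage"], errors="raise")
        elif stage_coding == "dummy":
            dummies = pd.get_dummies(clinical["stage"], prefix="stage",
                                     drop_first=True, dtype=float)
            out = pd.concat([out, dummies], axis=1)
        else:
            raise ValueError("stage_coding must be 'ordinal' or 'dummy'")
    if "smoking" in clinical.columns and clinical["smoking"].notna().all():
        out["smoking"] = clinical["smoking"].astype(float)
    return out


def fit_cox(covariates: pd.DataFrame, time, event) -> CoxModel:
    """Maximum partial likelihood Cox fit (Efron handling of tied times)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("fit_cox: no events")
    if covariates.isna().any().any():
        raise ValueError("fit_cox: missing covariate values")
    df = covariates.astype(float).copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    return CoxModel(
        covariates=list(covariates.columns),
        coef=cph.params_,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        events=int(event.sum()),
    )


def lasso_cox_select(
    clinical: pd.DataFrame,
    features: pd.DataFrame,
    time,
    event,
    folds: int = 10,
    seed: int = 0,
    l1_ratio: float = 1.0,
    n_alphas: int = 30,
    rule: str = "one_se",
) -> tuple[list, CoxModel]:
    """LASSO-Cox selection of delta-numTS families, clinical unpenalized.

    *features* is a family x patient matrix; *clinical* a patient x
    covariate design (same patients, same order).  The penalty applies
    only to family columns (penalty factor 0 on clinical); the penalty
    strength maximizes k-fold cross-validated concordance on held-out
    folds — under ``rule="one_se"`` (default) the largest penalty whose
    mean CV concordance is within one standard error of the best, i.e.
    the most parsimonious competitive model.  The returned model is an
    unpenalized Cox refit on clinical plus the selected families.  An
    empty selection returns the clinical-only model (not an error).
    """
    F = features.T  # patients x families
    if not len(F) == len(clinical):
        raise ValueError("clinical and features cover different patients")
    X = pd.concat([clinical.reset_index(drop=True),
                   F.reset_index(drop=True)], axis=1)
    X.columns = list(clinical.columns) + list(features.index)
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xv - mu) / sd
    y = Surv.from_arrays(np.asarray(event, dtype=bool), np.asarray(time, dtype=float))
    pf = np.array([0.0] * clinical.shape[1] + [1.0] * features.shape[0])

    base = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, penalty_factor=pf, n_alphas=n_alphas,
        alpha_min_ratio=0.05,
    )
    base.fit(Xs, y)
    alphas = base.alphas_

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros((folds, len(alphas)))
    for f, (tr, va) in enumerate(kf.split(Xs)):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, penalty_factor=pf, alphas=alphas,
        )
        model.fit(Xs[tr], y[tr])
        ev = np.asarray(event, dtype=bool)[va]
        tv = np.asarray(time, dtype=float)[va]
        for j, a in enumerate(model.alphas_):
            risk = model.predict(Xs[va], alpha=a)
            if np.ptp(risk) == 0:
                scores[f, j] = 0.5
            else:
                try:
                    scores[f, j] = concordance_index_censored(ev, tv, risk)[0]
                except (NoComparablePairException, ValueError):
                    scores[f, j] = 0.5  # fold with no usable event pair
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(folds)
    i_best = int(np.argmax(mean))
    if rule == "one_se":
        # alphas_ is decreasing; the most parsimonious competitive model is
        # the smallest index (largest penalty) within one SE of the best
        ok = np.flatnonzero(mean >= mean[i_best] - se[i_best])
        best = int(ok[0])
    else:
        best = i_best
    coef = base.coef_[:, min(best, base.coef_.shape[1] - 1)]
    feat_coef = coef[clinical.shape[1]:]
    selected = [f for f, c in zip(features.index, feat_coef) if c != 0]

    refit_cols = pd.concat(
        [clinical, F[selected].set_axis(clinical.index, axis=0)], axis=1
    ) if selected else clinical
    model = fit_cox(refit_cols, time, event)
    return selected, model


def augment_with_expression(
    clinical: pd.DataFrame,
    selected_families: list,
    delta_expr: pd.DataFrame,
    time,
    event,
) -> CoxModel:
    """Unpenalized Cox on clinical plus delta-expression of the given families."""
    missing = [f for f in selected_families if f not in delta_expr.index]
    if missing:
        raise ValueError(f"families absent from delta_expr: {missing}")
    if not selected_families:
        return fit_cox(clinical, time, event)
    F = delta_expr.loc[list(selected_families)].T.set_axis(clinical.index, axis=0)
    return fit_cox(pd.concat([clinical, F], axis=1), time, event)


@dataclass
class RiskStratification:
    labels: pd.Series            # "high" / "low" per patient
    logrank_statistic: float
    logrank_p: float
    km_tables: dict = field(default_factory=dict)  # group -> survival curve


def risk_stratify(model: CoxModel, covariates: pd.DataFrame, time, event) -> RiskStratification:
    """Median split of the linear predictor into high/low risk groups.

    The split is rank-based (top half of predicted hazards = high risk),
    so it is invariant to strictly increasing transforms of the linear
    predictor, and group sizes differ by at most one.
    """
    lp = model.linear_predictor(covariates)
    if np.ptp(lp.to_numpy()) == 0:
        raise ValueError("risk_stratify: constant linear predictor")
    n = len(lp)
    order = np.argsort(lp.to_numpy(), kind="stable")
    labels = pd.Series("low", index=lp.index, name="risk_group")
    labels.iloc[order[-(n // 2):]] = "high"
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    hi = (labels == "high").to_numpy()
    res = logrank_test(time[hi], time[~hi], event[hi], event[~hi])
    km_tables = {}
    for name, mask in (("high", hi), ("low", ~hi)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=name)
        km_tables[name] = kmf.survival_function_
    return RiskStratification(labels, float(res.test_statistic),
                              float(res.p_value), km_tables)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float


def lrt_compare(nested: CoxModel, full: CoxModel) -> LrtResult:
    """Likelihood-ratio test of a nested against a full Cox model."""
    if not set(nested.covariates) <= set(full.covariates):
        raise ValueError("models are not nested")
    if nested.n != full.n:
        raise ValueError("models fit on different samples")
    df = len(full.covariates) - len(nested.covariates)
    stat = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return LrtResult(stat, df, p)


@dataclass
class SurvivalModelSet:
    clinical_only: CoxModel
    numts_clinical: CoxModel
    expr_clinical: CoxModel
    selected_families: list
    lrt_numts: LrtResult
    lrt_expr: LrtResult
    risk: dict                    # model name -> RiskStratification (or None)


def build_survival_model_set(
    clinical: pd.DataFrame,
    delta_numts: pd.DataFrame,
    delta_expr: pd.DataFrame,
    time,
    event,
    seed: int = 0,
    folds: int = 10,
) -> SurvivalModelSet:
    """Fit the clinical-only / numts-clinical / expr-clinical model trio."""
    clinical_model = fit_cox(clinical, time, event)
    selected, numts_model = lasso_cox_select(
        clinical, delta_numts, time, event, folds=folds, seed=seed
    )
    expr_model = augment_with_expression(clinical, selected, delta_expr, time, event)
    risk = {}
    specs = {
        "clinical_only": (clinical_model, clinical),
        "numts_clinical": (
            numts_model,
            pd.concat(
                [clinical,
                 delta_numts.loc[selected].T.set_axis(clinical.index, axis=0)],
                axis=1,
            ) if selected else clinical,
        ),
        "expr_clinical": (
            expr_model,
            pd.concat(
                [clinical,
                 delta_expr.loc[selected].T.set_axis(clinical.index, axis=0)],
                axis=1,
            ) if selected else clinical,
        ),
    }
    for name, (model, cov) in specs.items():
        try:
            risk[name] = risk_stratify(model, cov, time, event)
        except ValueError:
            risk[name] = None
    return SurvivalModelSet(
        clinical_only=clinical_model,
        numts_clinical=numts_model,
        expr_clinical=expr_model,
        selected_families=selected,
        lrt_numts=lrt_compare(clinical_model, numts_model),
        lrt_expr=lrt_compare(clinical_model, expr_model),
        risk=risk,
    )
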