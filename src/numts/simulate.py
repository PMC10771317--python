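"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without any external download:

* per-gene 3'UTR loci with a proximal polyA boundary and Poisson-
  distributed target-site counts split between pUTR and dUTR;
* log-normal gene FPKM and miRNA-family TPM;
* Beta-distributed PDUI, with the tumor group's mean shifted down by a
  configurable amount (3'UTR shortening);
* miRNA-family expression coupled to the true numTS at a target Spearman
  correlation per tissue group via a Gaussian copula (coupling in normal
  tissue, decoupling in tumor);
* outcome scores that are linear in the standardized numTS (or
  expression) of a planted feature subset plus Gaussian noise;
* Weibull/Cox survival times with hazards planted on delta-numTS
  features, and uniform censoring tuned to a target censoring rate;
* a four-group ICB layout (responder/non-responder x pre/post) with a
  mean shift planted only in responder-post samples.

Every cohort records its ground truth (planted sets, true effects, true
numTS) and is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erfinv

from . import core
from .io import ApaTable

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_paired_cohort",
    "simulate_survival",
    "simulate_survival_times",
    "simulate_icb_groups",
]


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Scales (300 genes, 100 families, 200 tumor samples, 40 tumor/normal
    pairs) are desk-scale stand-ins for cohort data that keep every
    downstream analysis well-posed.  PDUI is Beta-distributed around a
    per-gene mean (concentration ``pdui_concentration``); the tumor group
    mean drops by ``tumor_pdui_shift`` (3'UTR shortening).  Coupling
    targets are Spearman correlations between numTS and family TPM.
    """

    n_genes: int = 300
    n_families: int = 100
    n_samples: int = 200
    n_pairs: int = 40
    utr_length: int = 2000
    site_length: int = 7
    sites_per_gene_family: float = 0.3   # Poisson mean per (gene, family)
    fpkm_logmean: float = 2.0            # natural-log scale
    fpkm_logsd: float = 0.7
    tpm_logmean: float = 1.0
    tpm_logsd: float = 1.0
    pdui_concentration: float = 10.0
    pdui_mean_range: tuple = (0.55, 0.9)  # per-gene normal-tissue mean
    tumor_pdui_shift: float = 0.2
    coupling_rho_normal: float = 0.8
    coupling_rho_tumor: float = 0.0
    n_planted_outcome_features: int = 5
    outcome_effect_size: float = 1.0
    noise_sd: float = 1.0
    n_planted_hazard_features: int = 3
    log_hr: float = 0.7
    gamma_age: float = 0.3               # clinical (standardized age) log-HR
    weibull_shape: float = 1.5
    weibull_scale: float = 365.0
    censoring_rate: float = 0.3
    icb_group_shift: float = 2.0         # in within-group SDs
    icb_group_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sites_per_gene_family", "fpkm_logsd", "tpm_logsd",
                     "pdui_concentration", "noise_sd", "weibull_shape",
                     "weibull_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("coupling_rho_normal", "coupling_rho_tumor"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0.0 <= self.tumor_pdui_shift < 1.0:
            raise ValueError("tumor_pdui_shift must lie in [0, 1)")
        if self.icb_group_shift < 0:
            raise ValueError("icb_group_shift must be >= 0")


@dataclass
class SyntheticCohort:
    expr: pd.DataFrame                  # gene x sample FPKM
    apa: ApaTable
    sites: pd.DataFrame                 # per-site intervals (0-based half-open)
    mirna_expr: pd.DataFrame            # family x sample TPM
    clinical: pd.DataFrame              # one row per sample
    outcomes: dict                      # name -> per-sample Series
    truth: dict = field(default_factory=dict)

    @property
    def numts(self) -> pd.DataFrame:
        return self.truth["numts"]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _gene_ids(n):
    return [f"g{i:04d}" for i in range(1, n + 1)]


def _family_ids(n):
    return [f"fam{i:03d}" for i in range(1, n + 1)]


def _make_loci_and_sites(cfg: SimConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = _gene_ids(cfg.n_genes)
    L = cfg.utr_length
    boundary = rng.integers(L // 4, 3 * L // 4, cfg.n_genes)
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(cfg.n_genes) * (L + 1000) + 5000,
            "end": np.arange(cfg.n_genes) * (L + 1000) + 5000 + L,
            "strand": np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-"),
            "boundary": boundary,
            "utr_length": L,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    counts = rng.poisson(cfg.sites_per_gene_family,
                         size=(cfg.n_genes, cfg.n_families))
    gi, fi = np.nonzero(counts)
    rows = []
    fams = _family_ids(cfg.n_families)
    w = cfg.site_length
    for g, f in zip(gi, fi):
        b = boundary[g]
        for _ in range(counts[g, f]):
            if rng.random() < 0.5 and b >= w:          # constitutive site
                s = int(rng.integers(0, b - w + 1))
            else:                                       # distal site
                s = int(rng.integers(b, L - w + 1))
            rows.append((genes[g], fams[f], s, s + w))
    sites = pd.DataFrame(rows, columns=["gene_id", "mirna_family",
                                        "site_start", "site_end"])
    return loci, sites


def _beta_pdui(mean, conc, size, rng):
    mean = np.clip(mean, 0.02, 0.98)
    a = mean * conc
    b = (1.0 - mean) * conc
    return rng.beta(a, b, size=size)


def _couple_expression(numts_row, rho, logmean, logsd, rng):
    """Family TPM with target Spearman correlation to the numTS row.

    Gaussian copula: the Pearson correlation of the latent normals that
    yields Spearman rho is 2*sin(pi*rho/6).
    """
    n = len(numts_row)
    ranks = pd.Series(numts_row).rank(method="average").to_numpy()
    u = (ranks - 0.5) / n
    z_numts = np.sqrt(2) * erfinv(2 * u - 1)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    z = r * z_numts + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(n)
    return np.exp(logmean + logsd * z)


def _numts_for(cfg, expr, apa, sites) -> pd.DataFrame:
    counts = core.partition_sites(sites, apa)
    return core.compute_numts_matrix(expr, apa, counts)


def _planted_outcomes(cfg: SimConfig, numts, mirna_expr, rng):
    """Outcome pair: one driven by numTS features, one by expression."""
    fams = list(numts.index)
    planted = sorted(rng.choice(len(fams), cfg.n_planted_outcome_features,
                                replace=False))
    planted_fams = [fams[i] for i in planted]
    beta = np.full(len(planted_fams), cfg.outcome_effect_size)

    def _linear(mat):
        Z = mat.loc[planted_fams].to_numpy(dtype=float)
        sd = Z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=1, keepdims=True)) / sd
        return beta @ Z

    y_numts = _linear(numts) + cfg.noise_sd * rng.standard_normal(numts.shape[1])
    y_expr = _linear(mirna_expr) + cfg.noise_sd * rng.standard_normal(numts.shape[1])
    outcomes = {
        "score_from_numts": pd.Series(y_numts, index=numts.columns),
        "score_from_expr": pd.Series(y_expr, index=numts.columns),
    }
    return outcomes, planted_fams, beta


def _base_clinical(sample_ids, patient_ids, tissue, rng) -> pd.DataFrame:
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": patient_ids,
            "tissue": tissue,
            "age": np.round(rng.normal(60, 10, n), 1),
            "gender": rng.choice(["female", "male"], n),
            "stage": rng.integers(1, 5, n),
            "smoking": rng.integers(0, 2, n),
        }
    )


# ---------------------------------------------------------------------------
# cohort generators
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Tumor-only cohort with planted outcome structure.

    PDUI uses the tumor distribution (per-gene normal mean minus the
    shortening shift); miRNA expression is coupled to true numTS at the
    tumor coupling strength; two outcome vectors are planted, one linear
    in numTS features and one linear in the expression of the same
    families.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    loci, sites = _make_loci_and_sites(cfg, rng)
    genes = list(loci.index)
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]

    mu_normal = rng.uniform(*cfg.pdui_mean_range, cfg.n_genes)
    mu_tumor = mu_normal - cfg.tumor_pdui_shift
    pdui = _beta_pdui(mu_tumor[:, None], cfg.pdui_concentration,
                      (cfg.n_genes, cfg.n_samples), rng)
    apa = ApaTable(loci, pd.DataFrame(pdui, index=loci.index, columns=samples))

    gene_logmean = rng.normal(cfg.fpkm_logmean, 1.0, cfg.n_genes)
    fpkm = np.exp(gene_logmean[:, None]
                  + cfg.fpkm_logsd * rng.standard_normal((cfg.n_genes,
                                                          cfg.n_samples)))
    expr = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"),
                        columns=samples)

    numts = _numts_for(cfg, expr, apa, sites)
    fam_logmean = rng.normal(cfg.tpm_logmean, 1.0, len(numts))
    tpm = np.vstack([
        _couple_expression(numts.iloc[i].to_numpy(), cfg.coupling_rho_tumor,
                           fam_logmean[i], cfg.tpm_logsd, rng)
        for i in range(len(numts))
    ])
    mirna_expr = pd.DataFrame(tpm, index=numts.index, columns=samples)

    outcomes, planted_fams, beta = _planted_outcomes(cfg, numts, mirna_expr, rng)
    clinical = _base_clinical(samples, [f"P{i:04d}" for i in range(1, cfg.n_samples + 1)],
                              "tumor", rng)
    truth = {
        "numts": numts,
        "planted_outcome_features": planted_fams,
        "beta": beta,
        "pdui_mean_normal": mu_normal,
        "pdui_mean_tumor": np.clip(mu_tumor, 0.02, 0.98),
        "coupling_rho": cfg.coupling_rho_tumor,
    }
    return SyntheticCohort(expr, apa, sites, mirna_expr, clinical, outcomes, truth)


def simulate_paired_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Tumor/normal pairs per patient, with group-specific PDUI and coupling.

    Every patient contributes exactly one normal and one tumor sample.
    Normal samples draw PDUI around the per-gene normal mean and couple
    expression to numTS at ``coupling_rho_normal``; tumor samples use the
    shifted mean and ``coupling_rho_tumor``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    loci, sites = _make_loci_and_sites(cfg, rng)
    genes = list(loci.index)
    patients = [f"P{i:04d}" for i in range(1, cfg.n_pairs + 1)]
    s_norm = [f"{p}_N" for p in patients]
    s_tum = [f"{p}_T" for p in patients]
    samples = s_norm + s_tum

    mu_normal = rng.uniform(*cfg.pdui_mean_range, cfg.n_genes)
    mu_tumor = mu_normal - cfg.tumor_pdui_shift
    pd_norm = _beta_pdui(mu_normal[:, None], cfg.pdui_concentration,
                         (cfg.n_genes, cfg.n_pairs), rng)
    pd_tum = _beta_pdui(mu_tumor[:, None], cfg.pdui_concentration,
                        (cfg.n_genes, cfg.n_pairs), rng)
    pdui = pd.DataFrame(np.hstack([pd_norm, pd_tum]), index=loci.index,
                        columns=samples)
    apa = ApaTable(loci, pdui)

    gene_logmean = rng.normal(cfg.fpkm_logmean, 1.0, cfg.n_genes)
    patient_effect = 0.3 * rng.standard_normal((1, cfg.n_pairs))
    noise = cfg.fpkm_logsd * rng.standard_normal((cfg.n_genes, 2 * cfg.n_pairs))
    shared = np.hstack([patient_effect, patient_effect])  # same patient, both tissues
    fpkm = np.exp(gene_logmean[:, None] + shared + noise)
    expr = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"),
                        columns=samples)

    numts = _numts_for(cfg, expr, apa, sites)
    fam_logmean = rng.normal(cfg.tpm_logmean, 1.0, len(numts))
    tpm = np.zeros((len(numts), len(samples)))
    norm_cols = np.arange(cfg.n_pairs)
    tum_cols = np.arange(cfg.n_pairs, 2 * cfg.n_pairs)
    for i in range(len(numts)):
        row = numts.iloc[i].to_numpy()
        tpm[i, norm_cols] = _couple_expression(
            row[norm_cols], cfg.coupling_rho_normal, fam_logmean[i],
            cfg.tpm_logsd, rng)
        tpm[i, tum_cols] = _couple_expression(
            row[tum_cols], cfg.coupling_rho_tumor, fam_logmean[i],
            cfg.tpm_logsd, rng)
    mirna_expr = pd.DataFrame(tpm, index=numts.index, columns=samples)

    clinical = pd.concat([
        _base_clinical(s_norm, patients, "normal", rng),
        _base_clinical(s_tum, patients, "tumor", rng),
    ], ignore_index=True)
    # patient-level covariates must agree across the pair
    per_patient = clinical[clinical["tissue"] == "normal"].set_index("patient_id")
    for col in ("age", "gender", "stage", "smoking"):
        clinical[col] = per_patient.loc[clinical["patient_id"], col].to_numpy()

    truth = {
        "numts": numts,
        "coupling_rho_normal": cfg.coupling_rho_normal,
        "coupling_rho_tumor": cfg.coupling_rho_tumor,
        "pdui_mean_normal": mu_normal,
        "pdui_mean_tumor": np.clip(mu_tumor, 0.02, 0.98),
    }
    return SyntheticCohort(expr, apa, sites, mirna_expr, clinical, {}, truth)


def simulate_survival_times(
    eta: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull-baseline Cox survival times with tuned uniform censoring.

    T = scale * (-log U / exp(eta))^(1/shape); censoring C ~ U(0, c) with
    c chosen by bisection so the realized censoring fraction matches
    ``cfg.censoring_rate`` in expectation over the drawn times.
    """
    n = len(eta)
    U = rng.uniform(size=n)
    T = cfg.weibull_scale * (-np.log(U) / np.exp(eta)) ** (1.0 / cfg.weibull_shape)
    if cfg.censoring_rate == 0:
        return T, np.ones(n, dtype=int)

    def frac_censored(c):
        return float(np.mean(np.minimum(T / c, 1.0)))

    lo, hi = T.min() / 1000, T.max() * 1000
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac_censored(mid) > cfg.censoring_rate:
            lo = mid
        else:
            hi = mid
    c = np.sqrt(lo * hi)
    C = rng.uniform(0, c, size=n)
    event = (T <= C).astype(int)
    time = np.minimum(T, C)
    return time, event


def simulate_survival(cfg: SimConfig, cohort: SyntheticCohort) -> SyntheticCohort:
    """Attach survival times/events driven by planted delta-numTS hazards.

    Requires a paired cohort.  The per-patient log hazard is
    gamma_age * z(age) + sum over planted families of log_hr * z(delta-numTS);
    times are Weibull-baseline with uniform censoring at the target rate.
    Returns a new cohort whose clinical table carries surv_time/event
    (identical on both rows of a patient).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    dnum = core.delta_numts(cohort.numts, cohort.clinical)
    fams = list(dnum.index)
    if cfg.n_planted_hazard_features > 0 and cfg.log_hr != 0:
        idx = sorted(rng.choice(len(fams), cfg.n_planted_hazard_features,
                                replace=False))
        hazard_fams = [fams[i] for i in idx]
        Z = dnum.loc[hazard_fams].to_numpy(dtype=float)
        sd = Z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=1, keepdims=True)) / sd
        eta_feat = cfg.log_hr * Z.sum(axis=0)
    else:
        hazard_fams = []
        eta_feat = np.zeros(dnum.shape[1])

    patients = list(dnum.columns)
    clin = cohort.clinical.set_index("patient_id")
    age = clin.loc[patients, "age"].groupby(level=0).first().loc[patients]
    z_age = (age - age.mean()) / (age.std() or 1.0)
    eta = cfg.gamma_age * z_age.to_numpy() + eta_feat
    time, event = simulate_survival_times(eta, cfg, rng)

    clinical = cohort.clinical.copy()
    tmap = pd.Series(time, index=patients)
    emap = pd.Series(event, index=patients)
    clinical["surv_time"] = tmap.reindex(clinical["patient_id"]).to_numpy()
    clinical["event"] = emap.reindex(clinical["patient_id"]).to_numpy()

    truth = dict(cohort.truth)
    truth.update({
        "planted_hazard_features": hazard_fams,
        "log_hr": cfg.log_hr,
        "delta_numts": dnum,
        "eta": pd.Series(eta, index=patients),
    })
    return SyntheticCohort(cohort.expr, cohort.apa, cohort.sites,
                           cohort.mirna_expr, clinical, cohort.outcomes, truth)


def simulate_icb_groups(cfg: SimConfig) -> SyntheticCohort:
    """Four-group ICB cohort: responder/non-responder x pre/post treatment.

    All groups share the tumor generative process; a mean shift of
    ``icb_group_shift`` within-group standard deviations is planted on the
    planted features' numTS in responder-post samples only.  The shifted
    matrix is ``truth["numts_shifted"]`` (the analysis input); the tables
    and ``truth["numts"]`` remain unshifted.
    """
    n_per = cfg.icb_group_size
    base_cfg = replace(cfg, n_samples=4 * n_per)
    cohort = simulate_cohort(base_cfg)

    groups = (["responder"] * (2 * n_per) + ["non-responder"] * (2 * n_per))
    timepoints = (["pre"] * n_per + ["post"] * n_per) * 2
    clinical = cohort.clinical.copy()
    clinical["response"] = groups
    clinical["timepoint"] = timepoints

    numts = cohort.numts.copy()
    planted = cohort.truth["planted_outcome_features"]
    label = pd.Series([f"{r}/{t}" for r, t in zip(groups, timepoints)],
                      index=numts.columns)
    shifted = numts.copy()
    target = label == "responder/post"
    for fam in planted:
        row = numts.loc[fam]
        within_sd = np.mean([row[label == g].std(ddof=1)
                             for g in label.unique()])
        shifted.loc[fam, target.to_numpy()] += cfg.icb_group_shift * within_sd

    truth = dict(cohort.truth)
    truth.update({
        "numts_shifted": shifted,
        "icb_labels": label,
        "icb_shift": cfg.icb_group_shift,
    })
    return SyntheticCohort(cohort.expr, cohort.apa, cohort.sites,
                           cohort.mirna_expr, clinical, cohort.outcomes, truth)
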