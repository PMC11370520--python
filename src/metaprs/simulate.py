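"""Synthetic cohort generator for meta-PRS development and evaluation.

The generator emulates the data structure of a biobank-scale PRS study:

* biallelic genotype dosages with configurable MAF and optional
  two-subpopulation drift (so leading PCs separate subpopulations);
* several GWAS-like *sources*, each yielding noisy marginal effect estimates
  for a shared causal architecture, thresholded at a grid of significance
  levels into candidate weight tables (the candidate set the tuning harness
  chooses among).  A configurable number of "risk-factor" sources have true
  effects only partially correlated (rho) with the disease architecture;
* a liability-threshold model for prevalent disease: liability = genetic +
  covariate + residual components scaled to unit total variance; samples
  above the (1 - prevalence) normal quantile are prevalent cases;
* exponential proportional-hazards incident disease among non-prevalent
  samples, with right censoring, administrative truncation, and the
  record-grid *midpoint* onset-dating convention (an event observed at time t
  is dated halfway between t and the previous disease-free record);
* a pseudo-clinical 10-year risk score built from the covariate component
  plus noise, capturing a configurable fraction of the clinically
  explainable risk, plus a dysglycemia-like biomarker column so a second,
  better-informed clinical model can be emulated downstream.

All randomness is a deterministic function of ``SimConfig.seed`` through
per-stage child streams ``default_rng([seed, stage_id])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .scoring import GenotypeMatrix, VariantWeightTable

# stage ids for the seed-splitting rule default_rng([seed, stage])
_STAGE_GENO = 1
_STAGE_ARCH = 2
_STAGE_GWAS = 3
_STAGE_PHENO = 4

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"), ("C", "A"), ("C", "G"), ("C", "T"),
    ("G", "A"), ("G", "C"), ("G", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
]


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults reflect the structure of a UK-biobank-style type 2 diabetes
    study at desk scale: prevalence ~7.9%, incident hazard ratio 1.8 per SD
    of liability, ~12 years of follow-up, 44 GWAS-like sources of which 34
    are risk-factor sources.
    """

    n_samples: int = 10_000
    n_variants: int = 2_000
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_sources: int = 44
    n_candidates_per_source: int = 4
    n_causal: int = 200
    heritability_liability: float = 0.35
    prevalence: float = 0.079
    incident_hazard_log_hr_per_sd: float = math.log(1.8)
    censor_rate: float = 0.02  # events / year
    max_follow_up: float = 12.0  # years
    n_pcs: int = 4
    pc_confounding_sd: float = 0.05
    clinical_signal_fraction: float = 0.7
    seed: int = 0
    # -- structural extras (documented in the methods note) ----------------
    covariate_variance: float = 0.15  # liability variance from age/sex/clinical
    baseline_hazard: float = 0.005  # events / year at mean liability
    record_grid_years: float = 1.0  # spacing of disease-free records; 0 = baseline only
    gwas_n: int = 200_000  # per-source GWAS sample size
    gwas_se_scale: float = 1.0  # 0 => noiseless marginal effects
    n_risk_factor_sources: int = 34
    risk_factor_rho: float = 0.5
    candidate_pvalues: tuple[float, ...] = (5e-8, 1e-5, 1e-3, 1.0)
    ld_block_size: int = 1  # >1 => equicorrelated LD blocks
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
            raise ConfigurationError(f"maf_range bounds outside (0,1): {self.maf_range}")
        if lo > hi:
            raise ConfigurationError(f"inverted maf_range: {self.maf_range}")
        if self.n_causal > self.n_variants:
            raise ConfigurationError("n_causal exceeds n_variants")
        if not 0.0 <= self.heritability_liability <= 1.0:
            raise ConfigurationError("heritability_liability outside [0,1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence outside (0,1)")
        if not 0.0 <= self.clinical_signal_fraction <= 1.0:
            raise ConfigurationError("clinical_signal_fraction outside [0,1]")
        if not 0.0 <= self.covariate_variance <= 1.0:
            raise ConfigurationError("covariate_variance outside [0,1]")
        if self.heritability_liability + self.covariate_variance > 1.0:
            raise ConfigurationError(
                "heritability_liability + covariate_variance exceeds 1"
            )
        if self.n_sources <= 0:
            raise ConfigurationError("n_sources must be positive")
        if self.n_risk_factor_sources > self.n_sources:
            raise ConfigurationError("n_risk_factor_sources exceeds n_sources")
        if len(self.candidate_pvalues) != self.n_candidates_per_source:
            # the p-value grid IS the candidate set
            raise ConfigurationError(
                "candidate_pvalues length must equal n_candidates_per_source"
            )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class TrueArchitecture:
    """The simulated causal truth behind all sources."""

    causal_index: np.ndarray  # indices into the variant axis
    causal_effect: np.ndarray  # per-allele liability effects (scaled to h2)
    liability_sd_components: dict = field(default_factory=dict)

    def full_effects(self, n_variants: int) -> np.ndarray:
        beta = np.zeros(n_variants)
        beta[self.causal_index] = self.causal_effect
        return beta


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Binomial(2, p) dosages with optional two-subpopulation allele drift.

    Subpopulation allele frequencies drift apart by
    ``+- pc_confounding_sd * sqrt(p(1-p))`` so that, when the drift SD is
    positive, the leading genotype PCs separate the two subpopulations.
    The first half of samples belongs to subpopulation A.
    """
    rng = cfg.rng(_STAGE_GENO)
    n, m = cfg.n_samples, cfg.n_variants
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    drift = cfg.pc_confounding_sd * np.sqrt(p * (1 - p)) * rng.standard_normal(m)
    p_a = np.clip(p + drift, 1e-4, 1 - 1e-4)
    p_b = np.clip(p - drift, 1e-4, 1 - 1e-4)
    n_a = n // 2

    if cfg.ld_block_size > 1 and cfg.ld_rho > 0:
        dos = np.empty((n, m))
        dos[:n_a] = _ld_block_dosages(rng, p_a, n_a, cfg.ld_block_size, cfg.ld_rho)
        dos[n_a:] = _ld_block_dosages(rng, p_b, n - n_a, cfg.ld_block_size, cfg.ld_rho)
    else:
        dos = np.empty((n, m))
        dos[:n_a] = rng.binomial(2, p_a, size=(n_a, m))
        dos[n_a:] = rng.binomial(2, p_b, size=(n - n_a, m))

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{j}" for j in range(m)],
            "chr": "1",
            "pos": np.arange(1, m + 1),
            "allele1": [_ALLELE_PAIRS[k][0] for k in pair_idx],
            "allele2": [_ALLELE_PAIRS[k][1] for k in pair_idx],
            "af": dos.mean(axis=0) / 2.0,
        }
    )
    sample_ids = np.array([f"s{i:06d}" for i in range(n)])
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dos)


def _ld_block_dosages(rng, p, n, block, rho):
    """Equicorrelated haplotype blocks via a shared latent Gaussian per block."""
    m = len(p)
    z_thresh = stats.norm.ppf(p)  # allele present when latent < threshold
    dos = np.zeros((n, m))
    for hap in range(2):
        start = 0
        while start < m:
            stop = min(start + block, m)
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, stop - start))
            z = math.sqrt(rho) * shared + math.sqrt(1 - rho) * own
            dos[:, start:stop] += (z < z_thresh[start:stop]).astype(float)
            start = stop
    return dos


# ---------------------------------------------------------------------------
# Causal architecture and GWAS-like candidate weights
# ---------------------------------------------------------------------------


def simulate_architecture(cfg: SimConfig, geno: GenotypeMatrix) -> TrueArchitecture:
    """Draw causal effects and scale them analytically to the target h2.

    Under Hardy-Weinberg the genetic liability variance is
    ``sum_i b_i^2 * 2 p_i (1 - p_i)``; raw N(0,1) draws are rescaled so this
    equals ``heritability_liability`` exactly.
    """
    rng = cfg.rng(_STAGE_ARCH)
    causal = np.sort(rng.choice(cfg.n_variants, size=cfg.n_causal, replace=False))
    raw = rng.standard_normal(cfg.n_causal)
    p = geno.variants["af"].to_numpy()[causal]
    var_raw = float(np.sum(raw**2 * 2 * p * (1 - p)))
    if cfg.heritability_liability == 0.0 or var_raw == 0.0:
        effects = np.zeros(cfg.n_causal)
    else:
        effects = raw * math.sqrt(cfg.heritability_liability / var_raw)
    h2 = cfg.heritability_liability
    return TrueArchitecture(
        causal_index=causal,
        causal_effect=effects,
        liability_sd_components={
            "genetic": h2,
            "covariate": cfg.covariate_variance,
            "residual": 1.0 - h2 - cfg.covariate_variance,
        },
    )


def genetic_liability(geno: GenotypeMatrix, arch: TrueArchitecture) -> np.ndarray:
    """Centered genetic component of liability (variance ~ h2)."""
    beta = arch.full_effects(geno.n_variants)
    p = geno.variants["af"].to_numpy()
    return (geno.dosages - 2 * p) @ beta


def simulate_candidate_weights(
    cfg: SimConfig, arch: TrueArchitecture, geno: GenotypeMatrix
) -> list[list[VariantWeightTable]]:
    """Noisy per-source marginal effects thresholded into candidate tables.

    Each source draws ``effect_hat ~ Normal(true, se)`` with GWAS standard
    error ``se = se_scale / sqrt(2 N p (1-p))`` and emits one candidate table
    per entry of the p-value grid, keeping variants whose two-sided marginal
    p-value is <= the threshold.  Sources beyond the first
    ``n_sources - n_risk_factor_sources`` are risk-factor sources: their true
    effects correlate only ``risk_factor_rho`` with the disease architecture.
    """
    if cfg.n_sources <= 0:
        raise ConfigurationError("n_sources must be positive")
    rng = cfg.rng(_STAGE_GWAS)
    m = geno.n_variants
    p = geno.variants["af"].to_numpy()
    se = cfg.gwas_se_scale / np.sqrt(2.0 * cfg.gwas_n * p * (1 - p))
    beta_disease = arch.full_effects(m)
    scale = float(np.std(beta_disease[arch.causal_index])) or 1.0

    n_disease = cfg.n_sources - cfg.n_risk_factor_sources
    sources: list[list[VariantWeightTable]] = []
    for s in range(cfg.n_sources):
        is_rf = s >= n_disease
        if is_rf:
            # partially overlapping architecture: same causal support,
            # effects correlated rho with the disease effects
            perp = np.zeros(m)
            perp[arch.causal_index] = rng.standard_normal(cfg.n_causal) * scale
            rho = cfg.risk_factor_rho
            true_eff = rho * beta_disease + math.sqrt(max(0.0, 1 - rho**2)) * perp
        else:
            true_eff = beta_disease

        effect_hat = true_eff + se * rng.standard_normal(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, effect_hat / se, np.where(effect_hat != 0, np.inf, 0.0))
        pval = 2.0 * stats.norm.sf(np.abs(z))

        candidates = []
        for thr in cfg.candidate_pvalues:
            keep = pval <= thr
            df = geno.variants.loc[keep, ["variant_id", "chr", "pos"]].copy()
            df["effect_allele"] = geno.variants.loc[keep, "allele2"].to_numpy()
            df["other_allele"] = geno.variants.loc[keep, "allele1"].to_numpy()
            df["weight"] = effect_hat[keep]
            candidates.append(
                VariantWeightTable(
                    df=df.reset_index(drop=True),
                    metadata={
                        "name": f"source{s}_p{thr:g}",
                        "source": s,
                        "is_risk_factor": bool(is_rf),
                        "p_threshold": float(thr),
                    },
                )
            )
        sources.append(candidates)
    return sources


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

# fixed loadings of the covariate component on (standardized age, sex, latent
# clinical factor); squared loadings sum to 1 so the component has unit
# variance before scaling by sqrt(covariate_variance)
_L_AGE, _L_SEX = 0.6, 0.3
_L_CLIN = math.sqrt(1.0 - _L_AGE**2 - _L_SEX**2)


def simulate_phenotypes(
    geno: GenotypeMatrix, arch: TrueArchitecture, cfg: SimConfig
) -> pd.DataFrame:
    """Liability-threshold prevalent disease + PH incident disease + clinical score.

    Returns the cohort table with columns: sample_id, age, sex, pc1..pcK,
    prevalent, event, time (midpoint-dated for events), clinical_risk
    (pseudo-clinical 10-year probability), biomarker, and the simulation
    truths (true_liability, true_genetic, covariate_component) used by
    recovery oracles.
    """
    rng = cfg.rng(_STAGE_PHENO)
    n = geno.n_samples

    g = genetic_liability(geno, arch)
    age = rng.uniform(40, 70, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_std = (age - 55.0) / math.sqrt((70 - 40) ** 2 / 12.0)
    sex_std = (sex - 0.5) / 0.5
    clin_factor = rng.standard_normal(n)
    u = _L_AGE * age_std + _L_SEX * sex_std + _L_CLIN * clin_factor
    cov_comp = math.sqrt(cfg.covariate_variance) * u

    resid_var = 1.0 - cfg.heritability_liability - cfg.covariate_variance
    resid = math.sqrt(max(0.0, resid_var)) * rng.standard_normal(n)
    liability = g + cov_comp + resid

    tau = stats.norm.ppf(1.0 - cfg.prevalence)
    prevalent = liability > tau

    # incident disease among the non-prevalent, exponential PH model
    beta = cfg.incident_hazard_log_hr_per_sd
    hazard = cfg.baseline_hazard * np.exp(beta * liability)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, cfg.max_follow_up)
    event = (~prevalent) & (t_event <= t_cens)
    time = np.where(event, t_event, t_cens)

    # midpoint onset-dating: events are dated halfway between the observed
    # event time and the previous disease-free record on the record grid
    if cfg.record_grid_years > 0:
        prev_record = np.floor(t_event / cfg.record_grid_years) * cfg.record_grid_years
    else:
        prev_record = np.zeros(n)
    time = np.where(event, 0.5 * (prev_record + t_event), time)
    time = np.maximum(time, 1e-6)
    time[prevalent] = 0.0

    # pseudo-clinical score: noisy view of the covariate component capturing
    # clinical_signal_fraction of the clinically explainable liability
    f = cfg.clinical_signal_fraction
    if f > 0:
        noise_sd = math.sqrt(cfg.covariate_variance * (1.0 - f) / f) if f < 1 else 0.0
        clin_hat = cov_comp + noise_sd * rng.standard_normal(n)
    else:
        clin_hat = math.sqrt(cfg.covariate_variance) * rng.standard_normal(n)
    clinical_risk = 1.0 - np.exp(-10.0 * cfg.baseline_hazard * np.exp(beta * clin_hat))

    # dysglycemia-like biomarker: strongly liability-linked, lets downstream
    # code emulate a better-informed second-stage clinical model
    biomarker = 0.75 * liability + math.sqrt(1 - 0.75**2) * rng.standard_normal(n)

    pcs = _genotype_pcs(geno, cfg.n_pcs)

    out = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "age": age,
            "sex": sex,
            "prevalent": prevalent.astype(int),
            "event": event.astype(int),
            "time": time,
            "clinical_risk": clinical_risk,
            "biomarker": biomarker,
            "true_liability": liability,
            "true_genetic": g,
            "covariate_component": cov_comp,
        }
    )
    for k in range(pcs.shape[1]):
        out[f"pc{k + 1}"] = pcs[:, k]
    return out


def _genotype_pcs(geno: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Leading PCs of the centered dosage matrix, deterministic sign convention."""
    if n_pcs <= 0:
        return np.zeros((geno.n_samples, 0))
    from sklearn.decomposition import PCA

    n_pcs = min(n_pcs, geno.n_variants, geno.n_samples - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=0)
    pcs = pca.fit_transform(geno.dosages - geno.dosages.mean(axis=0))
    # fix each component's sign so its largest-|loading| coordinate is positive
    for k in range(pcs.shape[1]):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pcs[:, k] = -pcs[:, k]
    return pcs


def pc_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c.startswith("pc") and c[2:].isdigit()]
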