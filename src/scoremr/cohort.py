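"""Synthetic cohort generator for genetic-score Mendelian randomization.

Generates individual-level data with the statistical structure a score-based
MR analysis assumes: hard-call dosages at Hardy-Weinberg proportions with
optional linkage-disequilibrium (LD) blocks, a latent log-scale biomarker
("exposure") whose genetic variance is calibrated to a target R-squared, a
censored biomarker measurement (assay limit of detection), binary disease
outcomes on a logistic liability with an exactly calibrated case fraction,
and GWAS-style per-variant summary statistics.

The exposure is kept in SD units of the log-biomarker; per-allele effects are
reported back on that scale.  A single standard-normal confounder (think
kidney function) can be wired into both the exposure and the outcome, and
per-variant direct (pleiotropic) outcome effects can be planted to violate
the exclusion restriction on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "VariantSpec",
    "LDBlockSpec",
    "CohortConfig",
    "CensoredMeasurement",
    "ExposureSim",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_exposure",
    "censor_exposure",
    "simulate_outcomes",
    "simulate_cohort",
    "make_summary_stats",
    "SUMMARY_COLUMNS",
]

#: column order of the summary-statistics dialect used throughout the package
SUMMARY_COLUMNS = [
    "chromosome",
    "base_pair_location",
    "rsid",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class VariantSpec:
    """One biallelic autosomal variant and its role in the generating model.

    ``beta_exposure`` is the per-allele effect on the log-scale exposure
    (before any global rescaling to a target R-squared); ``pleiotropy_beta``
    is a per-allele *direct* effect on the outcome liability (log-odds per
    allele), i.e. the pathway the instrumental-variable assumptions exclude.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_exposure: float = 0.0
    is_cis: bool = False
    pleiotropy_beta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ConfigurationError(f"{self.rsid}: eaf must be in (0,1), got {self.eaf}")
        if self.effect_allele == self.other_allele:
            raise ConfigurationError(f"{self.rsid}: effect and other allele are equal")
        if self.pos < 1:
            raise ConfigurationError(f"{self.rsid}: pos must be >= 1")


@dataclass(frozen=True)
class LDBlockSpec:
    """A lead variant and satellites correlated with it at a target r^2."""

    lead_index: int
    satellite_indices: tuple[int, ...]
    pairwise_r2: float
    max_span_kb: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pairwise_r2 < 1.0:
            raise ConfigurationError(f"pairwise_r2 must be in [0,1), got {self.pairwise_r2}")


@dataclass
class CohortConfig:
    """Generating parameters for one simulated cohort.

    ``target_r2_total``/``target_r2_cis`` rescale the planted standardized
    effects so the theoretical genetic variance of the exposure matches the
    targets (cis subset contributing ``target_r2_cis``).  ``target_r2_total =
    None`` leaves ``beta_exposure`` as given.  Total exposure variance is 1.
    """

    n_individuals: int
    variants: list[VariantSpec]
    ld_blocks: list[LDBlockSpec] = field(default_factory=list)
    target_r2_total: float | None = None
    target_r2_cis: float = 0.0
    confounder_effect_exposure: float = 0.0
    confounder_effect_outcome: float = 0.0
    causal_log_or: float = 0.0
    case_fraction: float = 0.0778
    lod_quantile: float = 0.0
    measurement_noise_sd: float = 0.3
    n_principal_components: int = 0
    exposure_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be >= 2")
        if self.target_r2_total is not None:
            if not 0.0 <= self.target_r2_cis <= self.target_r2_total:
                raise ConfigurationError("need 0 <= target_r2_cis <= target_r2_total")
            if self.target_r2_total >= 1.0:
                raise ConfigurationError("target_r2_total must be < 1")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError("case_fraction must be in (0,1)")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ConfigurationError("lod_quantile must be in [0,1)")

    @property
    def eafs(self) -> np.ndarray:
        return np.array([v.eaf for v in self.variants])

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _hwe_cuts(p: float) -> tuple[float, float]:
    """Latent-normal cut points putting HWE mass on genotype classes 0/1/2."""
    q0 = (1.0 - p) ** 2
    q1 = q0 + 2.0 * p * (1.0 - p)
    return stats.norm.ppf(q0), stats.norm.ppf(q1)


def _dosage_corr(rho: float, p1: float, p2: float) -> float:
    """Pearson correlation of two thresholded-copula dosages at latent rho."""
    if rho == 0.0:
        return 0.0
    c1 = _hwe_cuts(p1)
    c2 = _hwe_cuts(p2)
    b1 = np.array([-8.0, c1[0], c1[1], 8.0])
    b2 = np.array([-8.0, c2[0], c2[1], 8.0])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    pts = np.array([[x, y] for x in b1 for y in b2])
    F = mvn.cdf(pts).reshape(4, 4)
    cell = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    g = np.array([0.0, 1.0, 2.0])
    e12 = g @ cell @ g
    m1, v1 = 2.0 * p1, 2.0 * p1 * (1.0 - p1)
    m2, v2 = 2.0 * p2, 2.0 * p2 * (1.0 - p2)
    return float((e12 - m1 * m2) / np.sqrt(v1 * v2))


@lru_cache(maxsize=4096)
def _latent_rho(p1: float, p2: float, target_r: float) -> float:
    """Latent correlation giving dosage correlation ``target_r`` (>= 0)."""
    if target_r == 0.0:
        return 0.0
    # dosage correlation is monotone in rho and bounded by the rho=0.9999 value
    hi = 0.9999
    if _dosage_corr(hi, p1, p2) < target_r:
        raise ConfigurationError(
            f"target r={target_r:.3f} unattainable for eafs {p1:.3f}/{p2:.3f}"
        )
    return float(optimize.brentq(lambda r: _dosage_corr(r, p1, p2) - target_r, 0.0, hi, xtol=1e-6))


def simulate_genotypes(config: CohortConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an n x J hard-call dosage matrix (values 0/1/2).

    Variants outside LD blocks are independent binomial(2, eaf) draws.  Within
    a block, lead and satellites come from a latent multivariate-normal copula
    thresholded at Hardy-Weinberg cut points, with the latent correlation
    calibrated so the realized dosage r^2 approximates the block's target.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    variants = config.variants
    J = len(variants)
    Z = rng.standard_normal((n, J))
    for block in config.ld_blocks:
        lead = Z[:, block.lead_index].copy()
        p_lead = variants[block.lead_index].eaf
        target_r = float(np.sqrt(block.pairwise_r2))
        for s in block.satellite_indices:
            if variants[s].chrom != variants[block.lead_index].chrom:
                raise ConfigurationError(
                    f"satellite {variants[s].rsid} not on lead's chromosome"
                )
            rho = _latent_rho(round(p_lead, 6), round(variants[s].eaf, 6), round(target_r, 6))
            Z[:, s] = rho * lead + np.sqrt(1.0 - rho**2) * Z[:, s]
    G = np.empty((n, J))
    for j, v in enumerate(variants):
        c0, c1 = _hwe_cuts(v.eaf)
        G[:, j] = np.digitize(Z[:, j], [c0, c1])
    return G


# ---------------------------------------------------------------------------
# exposure
# ---------------------------------------------------------------------------


@dataclass
class ExposureSim:
    """Latent exposure plus the realized generating effects."""

    exposure_true: np.ndarray
    per_allele_effects: np.ndarray  # per-allele, SD-of-exposure units
    std_effects: np.ndarray  # per standardized-genotype effects
    confounder: np.ndarray
    genetic_variance: float


def _rescaled_std_effects(config: CohortConfig) -> np.ndarray:
    """Standardized per-variant effects after R-squared calibration."""
    p = config.eafs
    base = np.array([v.beta_exposure for v in config.variants]) * np.sqrt(2 * p * (1 - p))
    if config.target_r2_total is None:
        return base
    cis = np.array([v.is_cis for v in config.variants])
    out = np.zeros_like(base)
    for mask, target in ((cis, config.target_r2_cis), (~cis, config.target_r2_total - config.target_r2_cis)):
        norm2 = float(base[mask] @ base[mask])
        if target == 0.0:
            continue
        if norm2 == 0.0:
            raise ConfigurationError("nonzero R^2 target for a group with all-zero effects")
        out[mask] = base[mask] * np.sqrt(target / norm2)
    return out


def simulate_exposure(
    dosages: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    confounder: np.ndarray | None = None,
) -> ExposureSim:
    """Build the latent log-exposure (total variance 1, SD units).

    exposure_i = sum_j beta*_j (g_ij - 2 p_j) / sqrt(2 p_j (1-p_j))
                 + c_U U_i + eps_i,
    with standardized effects beta*_j rescaled so the theoretical genetic
    variance matches ``target_r2_total`` (cis subset: ``target_r2_cis``) and
    eps chosen so the total theoretical variance is 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = dosages.shape[0]
    p = config.eafs
    std_eff = _rescaled_std_effects(config)
    g_var = float(std_eff @ std_eff)
    c_u = config.confounder_effect_exposure
    eps_var = 1.0 - g_var - c_u**2
    if eps_var < 0:
        raise ConfigurationError("genetic + confounder variance exceeds 1")
    Gs = (dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
    if confounder is None:
        confounder = rng.standard_normal(n)
    exposure = Gs @ std_eff + c_u * confounder + rng.normal(0.0, np.sqrt(eps_var), n)
    per_allele = std_eff / np.sqrt(2 * p * (1 - p))
    return ExposureSim(exposure, per_allele, std_eff, confounder, g_var)


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------


@dataclass
class CensoredMeasurement:
    """A measured biomarker with a lower limit of detection (LOD)."""

    values: np.ndarray
    below_lod: np.ndarray  # boolean mask
    lod: float

    @property
    def n_below_lod(self) -> int:
        return int(self.below_lod.sum())


def censor_exposure(
    exposure_true: np.ndarray,
    lod_quantile: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> CensoredMeasurement:
    """Add measurement noise and censor the lowest ``lod_quantile`` fraction.

    Exactly ``floor(n * lod_quantile)`` entries are flagged, ties broken by
    value then original order (stable sort), so the count is deterministic
    even for degenerate all-equal inputs.
    """
    if not 0.0 <= lod_quantile < 1.0:
        raise ConfigurationError("lod_quantile must be in [0,1)")
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(exposure_true)
    values = exposure_true + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    k = int(np.floor(n * lod_quantile))
    below = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.argsort(values, kind="stable")
        below[order[:k]] = True
        lod = float(values[order[k]]) if k < n else float("inf")
    else:
        lod = float("-inf")
    return CensoredMeasurement(np.asarray(values, dtype=float), below, lod)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def simulate_outcomes(
    exposure_true: np.ndarray,
    dosages: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    confounder: np.ndarray | None = None,
    case_fraction: float | None = None,
) -> np.ndarray:
    """Draw a binary outcome from a logistic liability.

    P(case) = expit(a0 + causal_log_or * exposure + c_V * U + G @ pleiotropy),
    with the intercept a0 found by root-finding so that mean(P) equals the
    target case fraction to 1e-6.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K = config.case_fraction if case_fraction is None else case_fraction
    eta = config.causal_log_or * np.asarray(exposure_true, dtype=float)
    if config.confounder_effect_outcome != 0.0:
        if confounder is None:
            raise ConfigurationError("confounder path requested but no confounder supplied")
        eta = eta + config.confounder_effect_outcome * confounder
    pleio = np.array([v.pleiotropy_beta for v in config.variants])
    if np.any(pleio != 0.0):
        eta = eta + dosages @ pleio
    lo, hi = -50.0, 50.0

    def gap(a: float) -> float:
        return float(np.mean(expit(a + eta)) - K)

    if gap(lo) > 0 or gap(hi) < 0:
        raise ConfigurationError("intercept root-finding failed to bracket the case fraction")
    a0 = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return rng.binomial(1, expit(a0 + eta)).astype(float)


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """Individual-level data for one cohort plus its generating truth."""

    dosages: np.ndarray
    rsids: list[str]
    iids: list[str]
    covariates: pd.DataFrame
    exposure_true: np.ndarray
    exposure_measured: CensoredMeasurement
    outcomes: dict[str, np.ndarray]
    truth: dict
    config: CohortConfig

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.rsids, index=pd.Index(self.iids, name="iid"))


def _stage_rngs(seed: int, n_stages: int = 5) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_stages)]


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full cohort: genotypes, covariates, exposure, measurement,
    outcome.  Bit-reproducible for a given (config, seed)."""
    r_geno, r_cov, r_exp, r_meas, r_out = _stage_rngs(config.seed)
    n = config.n_individuals
    G = simulate_genotypes(config, r_geno)
    cov = {
        "age": r_cov.normal(58.0, 8.0, n),
        "sex": r_cov.binomial(1, 0.54, n).astype(float),
        "confounder": r_cov.standard_normal(n),
    }
    for k in range(config.n_principal_components):
        cov[f"pc{k + 1}"] = r_cov.standard_normal(n)
    covariates = pd.DataFrame(cov)
    exp_sim = simulate_exposure(G, config, r_exp, confounder=covariates["confounder"].to_numpy())
    measured = censor_exposure(exp_sim.exposure_true, config.lod_quantile, config.measurement_noise_sd, r_meas)
    y = simulate_outcomes(exp_sim.exposure_true, G, config, r_out, confounder=covariates["confounder"].to_numpy())
    iids = [f"id{i + 1:07d}" for i in range(n)]
    truth = {
        "per_allele_effects": exp_sim.per_allele_effects,
        "std_effects": exp_sim.std_effects,
        "genetic_variance": exp_sim.genetic_variance,
        "causal_log_or": config.causal_log_or,
        "case_fraction": config.case_fraction,
    }
    return SimulatedCohort(
        dosages=G,
        rsids=config.rsids,
        iids=iids,
        covariates=covariates,
        exposure_true=exp_sim.exposure_true,
        exposure_measured=measured,
        outcomes={"disease": y},
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def per_variant_linear(
    G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant multiple-regression slope and SE of ``y`` on each dosage
    column plus shared covariates, via Frisch-Waugh-Lovell residualization.

    Equivalent to J separate OLS fits of y ~ 1 + covariates + g_j; vectorized
    across variants.  Monomorphic columns yield NaN.
    """
    n, J = G.shape
    C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    Q, _ = np.linalg.qr(C)
    My = y - Q @ (Q.T @ y)
    MG = G - Q @ (Q.T @ G)
    gg = np.einsum("nj,nj->j", MG, MG)
    ok = gg > 1e-12
    beta = np.full(J, np.nan)
    se = np.full(J, np.nan)
    beta[ok] = np.einsum("nj,n->j", MG[:, ok], My) / gg[ok]
    # residual sum of squares per variant: ||My||^2 - beta_j^2 * gg_j
    rss = np.einsum("n,n->", My, My) - beta[ok] ** 2 * gg[ok]
    df = n - C.shape[1] - 1
    se[ok] = np.sqrt(np.maximum(rss, 0.0) / df / gg[ok])
    return beta, se


def _per_variant_logistic(
    G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant logistic regression (statsmodels GLM) slope and SE."""
    import statsmodels.api as sm

    n, J = G.shape
    C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    beta = np.full(J, np.nan)
    se = np.full(J, np.nan)
    for j in range(J):
        g = G[:, j]
        if np.var(g) < 1e-12:
            continue
        X = np.column_stack([C, g])
        res = sm.Logit(y, X).fit(disp=False, maxiter=100)
        beta[j] = res.params[-1]
        se[j] = res.bse[-1]
    return beta, se


def make_summary_stats(
    cohort: SimulatedCohort,
    trait: str,
    covariate_names: Sequence[str] = (),
) -> pd.DataFrame:
    """GWAS-style per-variant summary statistics for one trait of a cohort.

    ``trait`` is ``"exposure"`` (linear model on the latent log-exposure), the
    name of a binary outcome (logistic model), or a column of the covariate
    table.  Returns a table in the package's summary-statistics dialect;
    monomorphic variants carry NaN beta/SE/p (excluded downstream).

    For a two-sample design, exposure and outcome statistics must come from
    cohorts generated with different seeds (no sample overlap).
    """
    if trait == "exposure":
        y = cohort.exposure_true
    elif trait in cohort.outcomes:
        y = cohort.outcomes[trait]
    elif trait in cohort.covariates.columns:
        y = cohort.covariates[trait].to_numpy(dtype=float)
    else:
        raise KeyError(f"trait {trait!r} not present in cohort")
    C = cohort.covariates[list(covariate_names)].to_numpy(dtype=float) if covariate_names else None
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        beta, se = _per_variant_logistic(cohort.dosages, y, C)
    else:
        beta, se = per_variant_linear(cohort.dosages, y, C)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    eaf = cohort.dosages.mean(axis=0) / 2.0
    v = cohort.config.variants
    return pd.DataFrame(
        {
            "chromosome": [x.chrom for x in v],
            "base_pair_location": [x.pos for x in v],
            "rsid": [x.rsid for x in v],
            "effect_allele": [x.effect_allele for x in v],
            "other_allele": [x.other_allele for x in v],
            "effect_allele_frequency": eaf,
            "beta": beta,
            "standard_error": se,
            "p_value": p,
            "n": cohort.n,
        }
    )
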