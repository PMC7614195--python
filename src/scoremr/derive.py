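"""Instrument derivation: exposure GWAS, genomic control, P-threshold
selection, greedy LD clumping, cis identification, and variance-explained
accounting.

The derivation follows the usual protein-GWAS workflow: per-variant additive
linear models of the log-biomarker adjusted for covariates, a genomic-control
inflation check, selection of candidates below a P threshold, and greedy
clumping of candidates into independent loci using a physical window and an
r^2 ceiling (PLINK semantics: a lead absorbs nearby *correlated* candidates;
nearby-but-uncorrelated candidates remain separate leads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import per_variant_linear

__all__ = [
    "ClumpParams",
    "InstrumentVariant",
    "LDReference",
    "run_exposure_gwas",
    "genomic_inflation",
    "select_candidates",
    "greedy_clump",
    "identify_cis",
    "annotate_pleiotropy",
    "variance_explained",
]

log = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df, the genomic-control anchor
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class ClumpParams:
    """Selection and clumping thresholds (GWAS defaults of the pipeline)."""

    p_threshold: float = 5e-6
    window_kb: float = 1000.0
    r2_max: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0,1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if not 0.0 <= self.r2_max < 1.0:
            raise ValueError("r2_max must be in [0,1)")


@dataclass
class InstrumentVariant:
    """A clump lead carrying its score weight and annotations."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    weight: float
    is_cis: bool = False
    pleiotropy_flags: list[str] = field(default_factory=list)
    clump_members: list[str] = field(default_factory=list)


class LDReference:
    """Squared-correlation lookup between variants, computed from reference
    dosages (by default the derivation cohort itself)."""

    def __init__(self, rsids: list[str], r2_matrix: np.ndarray) -> None:
        self.rsids = list(rsids)
        self.index = {r: i for i, r in enumerate(self.rsids)}
        if len(self.index) != len(self.rsids):
            raise ValueError("duplicate rsid in LD reference")
        self._r2 = np.asarray(r2_matrix, dtype=float)

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, rsids: list[str]) -> "LDReference":
        G = np.asarray(dosages, dtype=float)
        sd = G.std(axis=0)
        Gc = (G - G.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        r = (Gc.T @ Gc) / G.shape[0]
        r2 = r**2
        np.fill_diagonal(r2, 1.0)
        r2[sd == 0, :] = 0.0
        r2[:, sd == 0] = 0.0
        np.fill_diagonal(r2, 1.0)
        return cls(rsids, r2)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.index

    def r2(self, a: str, b: str) -> float:
        return float(self._r2[self.index[a], self.index[b]])


def run_exposure_gwas(
    dosages: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None,
    variants_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant OLS of the exposure on dosage plus covariates.

    ``variants_meta`` supplies chromosome/position/allele columns in the
    summary-statistics dialect.  Rows with missing exposure or covariates are
    dropped (complete-case analysis, count logged).  P-values use the normal
    approximation; zero-variance dosage columns are flagged as NaN and
    excluded downstream.
    """
    y = np.asarray(exposure, dtype=float)
    C = covariates.to_numpy(dtype=float) if covariates is not None and covariates.shape[1] else None
    keep = ~np.isnan(y)
    if C is not None:
        keep &= ~np.isnan(C).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("run_exposure_gwas: dropped %d incomplete rows", n_dropped)
    G = np.asarray(dosages, dtype=float)[keep]
    y = y[keep]
    C = C[keep] if C is not None else None
    beta, se = per_variant_linear(G, y, C)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
    out = variants_meta.copy()
    out["effect_allele_frequency"] = G.mean(axis=0) / 2.0
    out["beta"] = beta
    out["standard_error"] = se
    out["p_value"] = p
    out["n"] = int(keep.sum())
    return out


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic-control inflation factor lambda.

    Median of the chi-square(1 df) quantiles of the observed p-values divided
    by the null median 0.45494; values near 1 indicate well-controlled
    stratification/confounding.  Reported to 3 decimals.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 10:
        raise ValueError("need at least 10 p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return round(float(np.median(chi2) / CHI2_1_MEDIAN), 3)


def select_candidates(records: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Candidates with p strictly below the threshold, ordered by (chrom, pos)."""
    ok = records["p_value"] < p_threshold
    out = records.loc[ok.fillna(False)].copy()
    out["_chrom_key"] = out["chromosome"].map(_chrom_sort_key)
    out = out.sort_values(["_chrom_key", "base_pair_location"], kind="mergesort")
    return out.drop(columns="_chrom_key").reset_index(drop=True)


def _chrom_sort_key(chrom) -> tuple:
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def greedy_clump(
    candidates: pd.DataFrame, ld: LDReference, params: ClumpParams
) -> list[InstrumentVariant]:
    """Greedy p-value-ordered clumping of candidates into independent leads.

    Candidates are visited in ascending p (ties broken by chrom, pos, rsid);
    each unassigned candidate becomes a lead and absorbs all unassigned
    candidates on its chromosome within +/- window_kb whose r^2 with it is
    >= r2_max.  Leads are returned in genomic order with their members; the
    score weight is the exposure beta.
    """
    for rsid in candidates["rsid"]:
        if rsid not in ld:
            raise KeyError(f"candidate {rsid} absent from LD reference")
    df = candidates.copy()
    df["_ckey"] = df["chromosome"].map(_chrom_sort_key)
    df = df.sort_values(["p_value", "_ckey", "base_pair_location", "rsid"], kind="mergesort")
    rows = list(df.itertuples(index=False))
    assigned: set[str] = set()
    leads: list[InstrumentVariant] = []
    window_bp = params.window_kb * 1000.0
    for row in rows:
        if row.rsid in assigned:
            continue
        assigned.add(row.rsid)
        members = []
        for other in rows:
            if other.rsid in assigned:
                continue
            if str(other.chromosome) != str(row.chromosome):
                continue
            if abs(other.base_pair_location - row.base_pair_location) > window_bp:
                continue
            if ld.r2(row.rsid, other.rsid) >= params.r2_max:
                members.append(other.rsid)
                assigned.add(other.rsid)
        leads.append(
            InstrumentVariant(
                rsid=row.rsid,
                chrom=str(row.chromosome),
                pos=int(row.base_pair_location),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.effect_allele_frequency),
                beta=float(row.beta),
                se=float(row.standard_error),
                p=float(row.p_value),
                n=int(row.n),
                weight=float(row.beta),
                clump_members=members,
            )
        )
    leads.sort(key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.rsid))
    log.info("greedy_clump: %d candidates -> %d leads", len(rows), len(leads))
    return leads


def identify_cis(
    variants: list[InstrumentVariant],
    gene_chrom: str,
    gene_tss: int,
    window_kb: float = 100.0,
) -> list[InstrumentVariant]:
    """Flag variants within ``window_kb`` of the gene's transcription start
    site on the same chromosome (inclusive boundary)."""
    out = []
    for v in variants:
        cis = str(v.chrom) == str(gene_chrom) and abs(v.pos - gene_tss) <= window_kb * 1000.0
        out.append(replace_instrument(v, is_cis=cis))
    return out


def replace_instrument(v: InstrumentVariant, **kw) -> InstrumentVariant:
    d = {**v.__dict__, **kw}
    d["pleiotropy_flags"] = list(d["pleiotropy_flags"])
    d["clump_members"] = list(d["clump_members"])
    return InstrumentVariant(**d)


def annotate_pleiotropy(
    variants: list[InstrumentVariant], annotations: dict[str, list[str]]
) -> list[InstrumentVariant]:
    """Attach user-supplied pleiotropy trait flags (e.g. from a published
    phenome-wide lookup) to matching instruments."""
    return [
        replace_instrument(v, pleiotropy_flags=list(annotations.get(v.rsid, [])))
        for v in variants
    ]


def variance_explained(
    instruments: list[InstrumentVariant],
    mode: str = "analytic",
    dosages: np.ndarray | None = None,
    exposure: np.ndarray | None = None,
    exposure_variance: float = 1.0,
    ld: LDReference | None = None,
) -> float:
    """Fraction of exposure variance explained by the instruments.

    analytic: sum_j 2 p_j (1-p_j) beta_j^2 / Var(exposure), assuming mutual
    independence (a warning is logged if a supplied LD reference shows
    correlated instruments).  empirical: R^2 of the joint OLS of the exposure
    on all instrument dosage columns.
    """
    if mode == "analytic":
        if ld is not None:
            for i, a in enumerate(instruments):
                for b in instruments[i + 1 :]:
                    if a.rsid in ld and b.rsid in ld and ld.r2(a.rsid, b.rsid) > 0.05:
                        log.warning("analytic R^2 with correlated instruments %s/%s", a.rsid, b.rsid)
        return float(
            sum(2 * v.eaf * (1 - v.eaf) * v.beta**2 for v in instruments) / exposure_variance
        )
    if mode == "empirical":
        if dosages is None or exposure is None:
            raise ValueError("empirical mode needs dosages and exposure")
        G = np.asarray(dosages, dtype=float)
        y = np.asarray(exposure, dtype=float)
        X = np.column_stack([np.ones(len(y)), G])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))
    raise ValueError("mode must be 'analytic' or 'empirical'")
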