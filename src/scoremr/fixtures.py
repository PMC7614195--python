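"""Packaged synthetic study configurations.

Everything here is synthetic.  The variant table stands in for a real
proteomic-GWAS instrument set: 34 independent loci for a log-scale circulating
biomarker (FGF-23), two of them cis to the encoding gene.  Seven rsids are
real identifiers retained so that consortium-coverage bookkeeping (which
variants a given outcome panel lacks) matches the published worked examples;
their chromosome/position/allele/frequency/effect values are synthetic
stand-ins, not lookups.

Two cohort configurations share the variant table:

* :func:`discovery_config` — strong planted standardized effects (about 1% of
  exposure variance each) with two LD satellites per locus (r^2 ~ 0.6 within
  50 kb), for exercising P-threshold selection and greedy clumping.  At a
  six-percent *total* instrument R^2 spread over 34 loci, every variant would
  sit at the detection boundary of a 19k-sample GWAS (real instrument sets
  are post-selection), so discovery uses effects safely above threshold.
* :func:`calibrated_config` — the same 34 lead variants, mutually
  independent, with effects rescaled so the score explains 6.3% of exposure
  variance in total and the two cis variants 0.4%, matching the instrument
  strength the downstream power and validation analyses assume.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, LDBlockSpec, VariantSpec

__all__ = [
    "FIXTURE_SEED",
    "FGF23_CHROM",
    "FGF23_TSS",
    "CIS_RSIDS",
    "lead_variant_table",
    "discovery_config",
    "calibrated_config",
    "pleiotropy_annotations",
    "consortium_missing_rsids",
]

#: fixed seed defining the packaged variant table and the clumping fixture
FIXTURE_SEED = 1234

#: synthetic stand-in coordinates for the FGF23 locus (chrom, TSS bp)
FGF23_CHROM = "12"
FGF23_TSS = 4_477_000

CIS_RSIDS = ("rs6489536", "rs7955866")

#: instruments a stroke-consortium outcome panel lacks (4 variants)
_STROKE_MISSING = ["rs11542063", "rs117612483", "rs117989952", "rs189972262"]
#: instruments a heart-failure-consortium panel lacks (the same 4 plus one)
_HF_MISSING = _STROKE_MISSING + ["rs75357988"]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


def lead_variant_table() -> list[VariantSpec]:
    """The 34 lead variants (synthetic; deterministic for the package)."""
    rng = np.random.default_rng(FIXTURE_SEED)
    named = list(CIS_RSIDS) + _HF_MISSING
    rsids = named + [f"rs99{i:05d}" for i in range(1, 34 - len(named) + 1)]
    eafs = rng.uniform(0.05, 0.5, 34)
    # standardized effect magnitudes ~ U(0.085, 0.115), mixed signs
    std_mag = rng.uniform(0.085, 0.115, 34)
    signs = np.where(rng.random(34) < 0.5, -1.0, 1.0)
    variants = []
    non_cis_slot = 0
    for i, rsid in enumerate(rsids):
        if rsid in CIS_RSIDS:
            chrom = FGF23_CHROM
            pos = FGF23_TSS - 40_000 if rsid == CIS_RSIDS[0] else FGF23_TSS + 40_000
            is_cis = True
            sign = 1.0  # biomarker-increasing orientation for the cis pair
        else:
            chrom = str((non_cis_slot % 22) + 1)
            pos = 20_000_000 + (non_cis_slot // 22) * 50_000_000
            non_cis_slot += 1
            is_cis = False
            sign = signs[i]
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        p = float(eafs[i])
        beta = float(sign * std_mag[i] / np.sqrt(2 * p * (1 - p)))
        variants.append(
            VariantSpec(
                rsid=rsid,
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=p,
                beta_exposure=beta,
                is_cis=is_cis,
            )
        )
    return variants


def _satellites_for(lead: VariantSpec) -> list[VariantSpec]:
    offsets = (30_000, -45_000)
    out = []
    for s, off in enumerate(offsets):
        out.append(
            VariantSpec(
                rsid=f"{lead.rsid}_sat{s + 1}",
                chrom=lead.chrom,
                pos=lead.pos + off,
                effect_allele=lead.effect_allele,
                other_allele=lead.other_allele,
                eaf=lead.eaf,
                beta_exposure=0.0,
                is_cis=lead.is_cis,
            )
        )
    return out


def discovery_config(
    n: int = 19_195,
    seed: int = FIXTURE_SEED,
    satellite_r2: float = 0.6,
    n_null_variants: int = 0,
) -> CohortConfig:
    """Derivation cohort: 34 strong loci, each with two LD satellites.

    The two cis leads are additionally linked at r^2 = 0.08 (independent by
    the clumping rule yet physically close, like a real cis pair).
    ``n_null_variants`` appends unassociated background variants so that the
    genomic-control diagnostic has a null mass to work with.
    """
    leads = lead_variant_table()
    variants: list[VariantSpec] = []
    blocks: list[LDBlockSpec] = []
    lead_idx: dict[str, int] = {}
    for lead in leads:
        lead_idx[lead.rsid] = len(variants)
        variants.append(lead)
        sats = _satellites_for(lead)
        sat_indices = tuple(range(len(variants), len(variants) + len(sats)))
        variants.extend(sats)
        blocks.append(LDBlockSpec(lead_idx[lead.rsid], sat_indices, satellite_r2, 100.0))
    # cis pair: correlated but below the clumping r^2 ceiling
    blocks.insert(
        0, LDBlockSpec(lead_idx[CIS_RSIDS[0]], (lead_idx[CIS_RSIDS[1]],), 0.08, 100.0)
    )
    if n_null_variants:
        rng = np.random.default_rng(FIXTURE_SEED + 1)
        eafs = rng.uniform(0.05, 0.95, n_null_variants)
        for i in range(n_null_variants):
            variants.append(
                VariantSpec(
                    rsid=f"rs88{i:06d}",
                    chrom=str((i % 22) + 1),
                    pos=120_000_000 + (i // 22) * 2_000_000,
                    effect_allele="A",
                    other_allele="G",
                    eaf=float(eafs[i]),
                )
            )
    return CohortConfig(
        n_individuals=n,
        variants=variants,
        ld_blocks=blocks,
        target_r2_total=None,
        seed=seed,
    )


def calibrated_config(
    seed: int,
    n: int = 19_195,
    r2_total: float = 0.063,
    r2_cis: float = 0.004,
    case_fraction: float = 0.0778,
    causal_log_or: float = 0.0,
    lod_quantile: float = 0.0,
    confounder_effect_exposure: float = 0.0,
    confounder_effect_outcome: float = 0.0,
    n_principal_components: int = 0,
    include_satellites: bool = False,
) -> CohortConfig:
    """A cohort at the 34 lead variants with the score's variance explained
    calibrated to ``r2_total`` (cis subset: ``r2_cis``).

    By default the 34 leads are mutually independent.  With
    ``include_satellites`` the cohort is genotyped at the full locus panel
    (leads, LD satellites, and the correlated cis pair), so scores built on
    any clump representative can be computed; satellites carry no direct
    exposure effect.
    """
    variants: list[VariantSpec] = lead_variant_table()
    blocks: list[LDBlockSpec] = []
    if include_satellites:
        leads = variants
        variants = []
        lead_idx: dict[str, int] = {}
        for lead in leads:
            lead_idx[lead.rsid] = len(variants)
            variants.append(lead)
            sats = _satellites_for(lead)
            sat_indices = tuple(range(len(variants), len(variants) + len(sats)))
            variants.extend(sats)
            blocks.append(LDBlockSpec(lead_idx[lead.rsid], sat_indices, 0.6, 100.0))
        blocks.insert(
            0, LDBlockSpec(lead_idx[CIS_RSIDS[0]], (lead_idx[CIS_RSIDS[1]],), 0.08, 100.0)
        )
    return CohortConfig(
        n_individuals=n,
        variants=variants,
        ld_blocks=blocks,
        target_r2_total=r2_total,
        target_r2_cis=r2_cis,
        case_fraction=case_fraction,
        causal_log_or=causal_log_or,
        lod_quantile=lod_quantile,
        confounder_effect_exposure=confounder_effect_exposure,
        confounder_effect_outcome=confounder_effect_outcome,
        n_principal_components=n_principal_components,
        seed=seed,
    )


def pleiotropy_annotations() -> dict[str, list[str]]:
    """Synthetic stand-in for a published phenome-wide lookup: four of the 34
    instruments flagged for association with cardiovascular risk factors."""
    return {
        "rs9900001": ["eGFR"],
        "rs9900002": ["body_mass_index"],
        "rs9900003": ["systolic_blood_pressure"],
        "rs9900004": ["LDL_cholesterol"],
    }


def consortium_missing_rsids() -> dict[str, list[str]]:
    """Instrument rsids absent from each synthetic outcome consortium panel."""
    return {
        "coronary_artery_disease": [],
        "ischemic_stroke": list(_STROKE_MISSING),
        "heart_failure": list(_HF_MISSING),
    }
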