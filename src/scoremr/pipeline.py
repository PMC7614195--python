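"""End-to-end orchestration: simulate -> derive -> score -> estimate -> power.

The pipeline mirrors a three-step score-based MR study design:

1. derive the instrument in a derivation cohort (per-variant GWAS of the
   log-biomarker, genomic-control check, P-threshold selection, greedy LD
   clumping, cis flagging, variance-explained accounting);
2. validate the weighted score against a censored biomarker measurement in an
   independent validation cohort, and check covariate balance by score fifths
   in the target cohort;
3. estimate score-outcome associations in the target cohort (one-sample) and
   run two-sample IVW MR with sensitivity analyses (cis-only,
   pleiotropy-excluded, single-lead, Egger, weighted median, Q, leave-one-out)
   against simulated outcome-consortium summary statistics, plus analytic
   power tables.

Everything is a pure function of (config, master seed); per-stage seeds are
derived from the master seed by fixed offsets so one stage's settings do not
perturb another stage's randomness.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .cohort import make_summary_stats, simulate_cohort, simulate_outcomes
from .derive import (
    ClumpParams,
    InstrumentVariant,
    LDReference,
    annotate_pleiotropy,
    genomic_inflation,
    greedy_clump,
    identify_cis,
    run_exposure_gwas,
    select_candidates,
    variance_explained,
)
from .mr import (
    MRResult,
    associate_score_binary,
    associate_score_continuous,
    bonferroni,
    cochran_q,
    filter_instruments,
    harmonize,
    ivw,
    leave_one_out,
    mr_egger,
    weighted_median,
)
from .power import PowerSpec, min_detectable_or
from .score import compute_score, covariate_balance, validate_score_ordinal
from . import io as srio

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "render_forest_table", "format_measurement"]

log = logging.getLogger(__name__)

_STAGE_OFFSETS = {"derivation": 1, "validation": 2, "target": 3, "consortium": 4, "extra_outcome": 5}


def stage_seed(master_seed: int, stage: str, k: int = 0) -> int:
    """Per-stage sub-seed from the master seed by fixed offsets (< 2^31)."""
    return int((master_seed + 2_654_435_761 * (_STAGE_OFFSETS[stage] + 17 * k)) % (2**31))


@dataclass
class OutcomeSpec:
    """One binary outcome analyzed by the pipeline."""

    name: str
    case_fraction: float
    two_sample: bool = False
    missing_rsids: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Study-design constants for one pipeline run (scaled by default)."""

    seed: int = 0
    n_derivation: int = 6000
    n_validation: int = 4390
    n_target: int = 20000
    n_consortium: int = 20000
    n_null_variants: int = 2000
    r2_total: float = 0.063
    r2_cis: float = 0.004
    causal_log_or: float = 0.0
    lod_quantile: float = 0.59
    clump: ClumpParams = field(default_factory=ClumpParams)
    gene_chrom: str = fixtures.FGF23_CHROM
    gene_tss: int = fixtures.FGF23_TSS
    cis_window_kb: float = 100.0
    palindrome_policy: str = "frequency_align"
    exposure_sd: float = 1.0
    bonferroni_m: int = 7
    n_principal_components: int = 4
    one_sample_outcomes: list[OutcomeSpec] = field(
        default_factory=lambda: [
            OutcomeSpec("atherosclerotic_cvd", 26266 / 337448),
            OutcomeSpec("nonatherosclerotic_cvd", 12652 / 337448),
        ]
    )
    two_sample_outcomes: list[OutcomeSpec] = field(
        default_factory=lambda: [
            OutcomeSpec("coronary_artery_disease", 0.10, True, []),
            OutcomeSpec(
                "ischemic_stroke", 0.05, True, fixtures.consortium_missing_rsids()["ischemic_stroke"]
            ),
            OutcomeSpec(
                "heart_failure", 0.05, True, fixtures.consortium_missing_rsids()["heart_failure"]
            ),
        ]
    )

    def to_yaml(self) -> str:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("clump", "one_sample_outcomes", "two_sample_outcomes")
        }
        d["clump"] = self.clump.__dict__
        d["one_sample_outcomes"] = [o.__dict__ for o in self.one_sample_outcomes]
        d["two_sample_outcomes"] = [o.__dict__ for o in self.two_sample_outcomes]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        d["clump"] = ClumpParams(**d.get("clump", {}))
        d["one_sample_outcomes"] = [OutcomeSpec(**o) for o in d.get("one_sample_outcomes", [])]
        d["two_sample_outcomes"] = [OutcomeSpec(**o) for o in d.get("two_sample_outcomes", [])]
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All tables one pipeline run produces, regenerable from (config, seed)."""

    instruments: list[InstrumentVariant]
    instrument_table: pd.DataFrame
    genomic_lambda: float
    r2_joint: float
    r2_cis: float
    validation: pd.DataFrame
    balance: pd.DataFrame
    forest: pd.DataFrame
    measurements: pd.DataFrame
    sensitivity: pd.DataFrame
    leave_one_out_tables: dict[str, pd.DataFrame]
    power: pd.DataFrame
    counts: dict[str, int]
    provenance: dict[str, str]


def format_measurement(estimate: float, lo: float, hi: float, decimals: int = 0) -> str:
    """Render a continuous-outcome effect as ``e (lo to hi)``."""
    f = f"{{:.{decimals}f}}"
    return f"{f.format(estimate)} ({f.format(lo)} to {f.format(hi)})"


def format_or(result: MRResult) -> str:
    lo, hi = result.ci95_or
    return f"{result.odds_ratio:.2f} ({lo:.2f} to {hi:.2f})"


def render_forest_table(rows: list[dict]) -> pd.DataFrame:
    """Forest-plot-ready table: one row per (outcome, method) with the OR
    formatted to two decimals and the CI as ``(lo to hi)``.

    ``rows`` entries carry keys outcome, n_events, result (an MRResult) and
    optional analysis label; caller supplies composite-first ordering.
    """
    if not rows:
        raise ValueError("no results to render")
    recs = []
    for r in rows:
        res: MRResult = r["result"]
        lo, hi = res.ci95_or
        recs.append(
            {
                "outcome": r["outcome"],
                "analysis": r.get("analysis", "main"),
                "method": res.method,
                "n_events": r.get("n_events", ""),
                "n_variants": res.n_variants,
                "or": round(res.odds_ratio, 2),
                "ci_lo": round(lo, 2),
                "ci_hi": round(hi, 2),
                "or_95ci": format_or(res),
                "p": res.p,
            }
        )
    return pd.DataFrame(recs)


def _derive_instruments(cfg: PipelineConfig):
    """Stage 1: derivation GWAS, selection, clumping, annotation."""
    dconf = fixtures.discovery_config(
        n=cfg.n_derivation,
        seed=stage_seed(cfg.seed, "derivation"),
        n_null_variants=cfg.n_null_variants,
    )
    cohort = simulate_cohort(dconf)
    meta = pd.DataFrame(
        {
            "chromosome": [v.chrom for v in dconf.variants],
            "base_pair_location": [v.pos for v in dconf.variants],
            "rsid": [v.rsid for v in dconf.variants],
            "effect_allele": [v.effect_allele for v in dconf.variants],
            "other_allele": [v.other_allele for v in dconf.variants],
        }
    )
    gwas = run_exposure_gwas(
        cohort.dosages, cohort.exposure_true, cohort.covariates[["age", "sex"]], meta
    )
    lam = genomic_inflation(gwas["p_value"].to_numpy())
    candidates = select_candidates(gwas, cfg.clump.p_threshold)
    ld = LDReference.from_dosages(cohort.dosages, cohort.rsids)
    leads = greedy_clump(candidates, ld, cfg.clump)
    leads = identify_cis(leads, cfg.gene_chrom, cfg.gene_tss, cfg.cis_window_kb)
    leads = annotate_pleiotropy(leads, fixtures.pleiotropy_annotations())
    counts = {
        "variants_tested": len(gwas),
        "candidates": len(candidates),
        "leads": len(leads),
        "absorbed": sum(len(v.clump_members) for v in leads),
    }
    log.info("derivation: %s", counts)
    return cohort, gwas, lam, leads, counts


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> AnalysisReport:
    """Execute the full analysis; optionally write all report tables under
    ``out_dir`` with a commented provenance header."""
    # ---- stage 1: instrument derivation -----------------------------------
    _, gwas, lam, instruments, counts = _derive_instruments(cfg)

    # ---- stage 2: score validation & balance ------------------------------
    vconf = fixtures.calibrated_config(
        seed=stage_seed(cfg.seed, "validation"),
        n=cfg.n_validation,
        r2_total=cfg.r2_total,
        r2_cis=cfg.r2_cis,
        lod_quantile=cfg.lod_quantile,
        include_satellites=True,
    )
    vcohort = simulate_cohort(vconf)
    vscore = compute_score(vcohort.dosage_frame(), instruments)
    ofit = validate_score_ordinal(
        vcohort.exposure_measured, vscore, vcohort.covariates[["age", "sex"]]
    )
    validation = pd.DataFrame(
        [
            {
                "coefficient_per_sd": ofit.coefficient,
                "se": ofit.se,
                "p": ofit.p,
                "n": ofit.n,
                "n_below_lod": ofit.n_below_lod,
            }
        ]
    )

    # ---- stage 3a: one-sample target-cohort associations ------------------
    tconf = fixtures.calibrated_config(
        seed=stage_seed(cfg.seed, "target"),
        n=cfg.n_target,
        r2_total=cfg.r2_total,
        r2_cis=cfg.r2_cis,
        causal_log_or=cfg.causal_log_or,
        case_fraction=cfg.one_sample_outcomes[0].case_fraction,
        n_principal_components=cfg.n_principal_components,
        include_satellites=True,
    )
    tcohort = simulate_cohort(tconf)
    for k, spec in enumerate(cfg.one_sample_outcomes[1:], start=1):
        rng = np.random.default_rng(stage_seed(cfg.seed, "extra_outcome", k))
        tcohort.outcomes[spec.name] = simulate_outcomes(
            tcohort.exposure_true,
            tcohort.dosages,
            tconf,
            rng,
            confounder=tcohort.covariates["confounder"].to_numpy(),
            case_fraction=spec.case_fraction,
        )
    tcohort.outcomes[cfg.one_sample_outcomes[0].name] = tcohort.outcomes.pop("disease")
    tscore = compute_score(tcohort.dosage_frame(), instruments)
    adj_cols = ["age", "sex"] + [f"pc{i + 1}" for i in range(cfg.n_principal_components)]
    adj = tcohort.covariates[adj_cols]
    balance = covariate_balance(tcohort.covariates, tscore.raw)

    forest_rows = []
    for spec in cfg.one_sample_outcomes:
        y = tcohort.outcomes[spec.name]
        res = associate_score_binary(y, tscore.standardized, adj)
        res.n_variants = len(instruments)
        forest_rows.append({"outcome": spec.name, "n_events": int(y.sum()), "result": res})

    # continuous clinical measurements (null by construction), Bonferroni m=7
    rng_meas = np.random.default_rng(stage_seed(cfg.seed, "extra_outcome", 99))
    meas_rows = []
    for name, unit, decimals in [("carotid_imt_um", "um", 0), ("lv_mass_g", "g", 1)]:
        m = rng_meas.normal(0.0, 1.0, tcohort.n)
        r = associate_score_continuous(m, tscore.standardized, adj)
        lo, hi = r.ci95
        meas_rows.append(
            {
                "measurement": name,
                "unit": unit,
                "estimate_95ci": format_measurement(r.estimate, lo, hi, decimals),
                "p": r.p,
                "p_bonferroni": float(bonferroni(np.array([r.p]), cfg.bonferroni_m)[0]),
            }
        )
    measurements = pd.DataFrame(meas_rows)

    # ---- stage 3b: two-sample consortium MR -------------------------------
    sens_rows = []
    loo_tables: dict[str, pd.DataFrame] = {}
    for k, spec in enumerate(cfg.two_sample_outcomes):
        oconf = fixtures.calibrated_config(
            seed=stage_seed(cfg.seed, "consortium", k),
            n=cfg.n_consortium,
            r2_total=cfg.r2_total,
            r2_cis=cfg.r2_cis,
            causal_log_or=cfg.causal_log_or,
            case_fraction=spec.case_fraction,
            include_satellites=True,
        )
        ocohort = simulate_cohort(oconf)
        ostats = make_summary_stats(ocohort, "disease")
        # a missing instrument means its whole locus lacks coverage (the
        # study design has no proxy search), so satellites drop with leads
        locus = ostats["rsid"].str.replace(r"_sat\d+$", "", regex=True)
        ostats = ostats[~locus.isin(spec.missing_rsids)].reset_index(drop=True)
        harmonized, dropped = harmonize(instruments, ostats, cfg.palindrome_policy)
        counts[f"harmonized_{spec.name}"] = len(harmonized)
        main = ivw(harmonized, "fixed", cfg.exposure_sd)
        forest_rows.append(
            {"outcome": spec.name, "n_events": int(ocohort.outcomes["disease"].sum()), "result": main}
        )
        q, qdf, qp = cochran_q(harmonized, main.estimate / cfg.exposure_sd)
        egger_res, (ei, ei_se, ei_p) = mr_egger(harmonized, cfg.exposure_sd)
        wm = weighted_median(harmonized, seed=stage_seed(cfg.seed, "consortium", 100 + k))
        forest_rows.append({"outcome": spec.name, "analysis": "egger", "result": egger_res})
        forest_rows.append({"outcome": spec.name, "analysis": "weighted_median", "result": wm})
        loo_tables[spec.name] = leave_one_out(harmonized, cfg.exposure_sd)
        for label, exclusion in [("cis_only", "non_cis"), ("pleiotropy_excluded", "pleiotropy_flagged")]:
            subset = filter_instruments(instruments, exclusion)
            h_sub, _ = harmonize(subset, ostats, cfg.palindrome_policy)
            if h_sub:
                forest_rows.append(
                    {"outcome": spec.name, "analysis": label, "result": ivw(h_sub, "fixed", cfg.exposure_sd)}
                )
        sens_rows.append(
            {
                "outcome": spec.name,
                "n_instruments": len(harmonized),
                "n_dropped": len(dropped),
                "q": q,
                "q_df": qdf,
                "q_p": qp,
                "egger_intercept": ei,
                "egger_intercept_se": ei_se,
                "egger_intercept_p": ei_p,
            }
        )
    sensitivity = pd.DataFrame(sens_rows)
    forest = render_forest_table(forest_rows)

    # ---- instrument strength & power --------------------------------------
    r2_joint = variance_explained(
        instruments, "empirical",
        dosages=tcohort.dosage_frame()[[v.rsid for v in instruments]].to_numpy(),
        exposure=tcohort.exposure_true,
    )
    cis_set = [v for v in instruments if v.is_cis]
    r2_cis_emp = (
        variance_explained(
            cis_set, "empirical",
            dosages=tcohort.dosage_frame()[[v.rsid for v in cis_set]].to_numpy(),
            exposure=tcohort.exposure_true,
        )
        if cis_set
        else float("nan")
    )
    power_rows = []
    for spec in cfg.one_sample_outcomes:
        for label, n_total in [("scaled", cfg.n_target), ("full_scale", 337_448)]:
            n_cases = max(1, round(spec.case_fraction * n_total))
            ps = PowerSpec(n=n_total, n_cases=n_cases, r2=max(r2_joint, 1e-6))
            power_rows.append(
                {
                    "outcome": spec.name,
                    "design": label,
                    "n": n_total,
                    "n_cases": n_cases,
                    "r2": round(r2_joint, 4),
                    "alpha": ps.alpha,
                    "target_power": ps.power,
                    "min_detectable_or": round(min_detectable_or(ps), 4),
                }
            )
    power = pd.DataFrame(power_rows)

    instrument_table = pd.DataFrame(
        {
            "rsid": [v.rsid for v in instruments],
            "chrom": [v.chrom for v in instruments],
            "pos": [v.pos for v in instruments],
            "weight": [v.weight for v in instruments],
            "p": [v.p for v in instruments],
            "is_cis": [v.is_cis for v in instruments],
            "pleiotropy_flags": [";".join(v.pleiotropy_flags) for v in instruments],
            "n_members": [len(v.clump_members) for v in instruments],
        }
    )
    provenance = {"seed": str(cfg.seed), "config-hash": cfg.config_hash()}
    report = AnalysisReport(
        instruments=instruments,
        instrument_table=instrument_table,
        genomic_lambda=lam,
        r2_joint=r2_joint,
        r2_cis=r2_cis_emp,
        validation=validation,
        balance=balance,
        forest=forest,
        measurements=measurements,
        sensitivity=sensitivity,
        leave_one_out_tables=loo_tables,
        power=power,
        counts=counts,
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, out_dir, gwas)
    return report


def write_report(report: AnalysisReport, out_dir: str | Path, gwas: pd.DataFrame | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = report.provenance
    srio.write_instruments(report.instruments, out / "instruments.tsv", prov)
    srio.write_table(report.instrument_table, out / "instrument_summary.tsv", prov)
    srio.write_table(report.validation, out / "score_validation.tsv", prov)
    srio.write_table(report.balance, out / "covariate_balance.tsv", prov)
    srio.write_table(report.forest, out / "forest.tsv", prov)
    srio.write_table(report.measurements, out / "measurement_outcomes.tsv", prov)
    srio.write_table(report.sensitivity, out / "sensitivity.tsv", prov)
    srio.write_table(report.power, out / "power.tsv", prov)
    for name, table in report.leave_one_out_tables.items():
        srio.write_table(table, out / f"leave_one_out_{name}.tsv", prov)
    if gwas is not None:
        srio.write_summary_stats(gwas, out / "derivation_gwas.tsv", prov)
    summary = pd.DataFrame(
        [
            {
                "genomic_lambda": report.genomic_lambda,
                "r2_joint": report.r2_joint,
                "r2_cis": report.r2_cis,
                **{k: v for k, v in report.counts.items()},
            }
        ]
    )
    srio.write_table(summary, out / "run_summary.tsv", prov)
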