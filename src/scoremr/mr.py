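"""One-sample and two-sample Mendelian-randomization estimation.

One-sample: logistic / linear regression of the outcome on the standardized
genetic score with covariate adjustment.  Two-sample: allele harmonization of
exposure and outcome summary statistics, per-variant Wald ratios, the
inverse-variance-weighted (IVW) estimator with fixed or multiplicative
random-effects standard errors, Cochran's Q heterogeneity statistic, MR-Egger
regression (directional-pleiotropy intercept test), the weighted-median
estimator, leave-one-out diagnostics, instrument-exclusion sensitivity sets,
and Bonferroni multiplicity adjustment.

Estimates are log odds ratios per 1-SD of genetically predicted log-exposure
when the exposure betas are in SD units (the package convention); an
``exposure_sd`` factor rescales when they are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .derive import InstrumentVariant

__all__ = [
    "HarmonizedInstrument",
    "MRResult",
    "SensitivityReport",
    "associate_score_binary",
    "associate_score_continuous",
    "harmonize",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "mr_egger",
    "weighted_median",
    "leave_one_out",
    "filter_instruments",
    "bonferroni",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset("AT"), frozenset("CG")}


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One variant's aligned exposure (bx, sx) and outcome (by, sy) effects."""

    rsid: str
    bx: float
    sx: float
    by: float
    sy: float
    aligned_allele: str
    action_taken: str  # kept | sign_flipped | dropped_missing | dropped_palindromic


@dataclass
class MRResult:
    """A causal-effect estimate with its scale convention.

    ``estimate`` is on the log-odds (or linear-outcome) scale per 1-SD of
    genetically predicted log-exposure; ``odds_ratio``/``ci95_or`` exponentiate
    it for binary outcomes.
    """

    method: str
    estimate: float
    se: float
    p: float
    n_variants: int
    scaling_note: str = "per 1-SD genetically predicted log-exposure"

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def ci95_or(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))


@dataclass
class SensitivityReport:
    """Heterogeneity and pleiotropy diagnostics for one outcome."""

    q: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    leave_one_out: pd.DataFrame
    exclusions_applied: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# one-sample score associations
# ---------------------------------------------------------------------------


def _design(score_std: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    n = len(score_std)
    cols = [np.ones(n), np.asarray(score_std, dtype=float)]
    if covariates is not None and covariates.shape[1]:
        cols.append(covariates.to_numpy(dtype=float))
    return np.column_stack(cols)


def associate_score_binary(
    outcome: np.ndarray, score_std: np.ndarray, covariates: pd.DataFrame | None = None
) -> MRResult:
    """Logistic regression of a binary outcome on the standardized score."""
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome has zero cases (or zero controls)")
    X = _design(score_std, covariates)
    try:
        res = sm.Logit(y, X).fit(disp=False, maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise RuntimeError(f"logistic fit failed (separation?): {exc}") from exc
    est, se = float(res.params[1]), float(res.bse[1])
    if abs(est) > 50 or not np.isfinite(se):
        raise RuntimeError("separation detected: diverging score coefficient")
    return MRResult(
        method="score_logistic",
        estimate=est,
        se=se,
        p=float(2 * stats.norm.sf(abs(est / se))),
        n_variants=0,
        scaling_note="log-OR per 1-SD of standardized score",
    )


def associate_score_continuous(
    measure: np.ndarray, score_std: np.ndarray, covariates: pd.DataFrame | None = None
) -> MRResult:
    """OLS of a continuous measurement on the standardized score."""
    import statsmodels.api as sm

    y = np.asarray(measure, dtype=float)
    if np.var(y) == 0:
        raise ValueError("zero-variance measure")
    X = _design(score_std, covariates)
    res = sm.OLS(y, X).fit()
    est, se = float(res.params[1]), float(res.bse[1])
    note = "measurement units per 1-SD of standardized score"
    if res.ssr < 1e-12:
        note += " [degenerate fit: zero residual variance]"
    return MRResult(
        method="score_linear",
        estimate=est,
        se=se,
        p=float(2 * stats.norm.sf(abs(est / se)) if se > 0 else 0.0),
        n_variants=0,
        scaling_note=note,
    )


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _comp(a: str) -> str:
    return "".join(_COMPLEMENT.get(x, "?") for x in a)


def _is_palindromic(a: str, b: str) -> bool:
    return len(a) == len(b) == 1 and frozenset((a, b)) in _PALINDROMIC


def harmonize(
    instruments: list[InstrumentVariant],
    outcome_stats: pd.DataFrame,
    palindrome_policy: str = "frequency_align",
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[list[HarmonizedInstrument], list[tuple[str, str]]]:
    """Align outcome summary statistics to the instrument effect alleles.

    Matching is by rsid (no proxy search: instruments absent from the outcome
    panel are dropped and logged).  If the outcome effect allele equals the
    instrument's other allele, the outcome beta's sign is flipped; strand
    complements are resolved by complementing then matching.  Palindromic
    (A/T, G/C) variants follow ``palindrome_policy``: keep (letter match),
    drop, or frequency_align (align by allele frequency, dropping variants
    with EAF inside ``ambiguity_band``).
    Returns (harmonized kept records, drop log of (rsid, action)).
    """
    if palindrome_policy not in {"keep", "drop", "frequency_align"}:
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    rs = outcome_stats["rsid"]
    if rs.duplicated().any():
        raise ValueError("duplicate rsid in outcome table")
    seen: set[str] = set()
    for v in instruments:
        if v.rsid in seen:
            raise ValueError("duplicate rsid in instrument table")
        seen.add(v.rsid)
    by_rsid = {r["rsid"]: r for _, r in outcome_stats.iterrows()}
    kept: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    for v in instruments:
        row = by_rsid.get(v.rsid)
        if row is None:
            dropped.append((v.rsid, "dropped_missing"))
            continue
        ea, oa = str(row["effect_allele"]), str(row["other_allele"])
        by, sy = float(row["beta"]), float(row["standard_error"])
        if _is_palindromic(v.effect_allele, v.other_allele):
            if palindrome_policy == "drop":
                dropped.append((v.rsid, "dropped_palindromic"))
                continue
            if palindrome_policy == "frequency_align":
                eaf_x = v.eaf
                eaf_y = float(row["effect_allele_frequency"])
                lo, hi = ambiguity_band
                if lo < eaf_x < hi or lo < eaf_y < hi:
                    dropped.append((v.rsid, "dropped_palindromic"))
                    continue
                # for a palindromic variant letters cannot resolve strand;
                # the minor/major orientation of the frequencies can
                same_orientation = (eaf_x < 0.5) == (eaf_y < 0.5)
                action = "kept" if same_orientation else "sign_flipped"
                kept.append(
                    HarmonizedInstrument(
                        v.rsid, v.beta, v.se, by if same_orientation else -by, sy,
                        v.effect_allele, action,
                    )
                )
                continue
            # policy "keep": fall through to letter matching
        if (ea, oa) == (v.effect_allele, v.other_allele):
            action = "kept"
        elif (ea, oa) == (v.other_allele, v.effect_allele):
            by, action = -by, "sign_flipped"
        elif (_comp(ea), _comp(oa)) == (v.effect_allele, v.other_allele):
            action = "kept"
        elif (_comp(ea), _comp(oa)) == (v.other_allele, v.effect_allele):
            by, action = -by, "sign_flipped"
        else:
            raise ValueError(
                f"{v.rsid}: outcome alleles {ea}/{oa} irreconcilable with "
                f"instrument {v.effect_allele}/{v.other_allele}"
            )
        kept.append(
            HarmonizedInstrument(v.rsid, v.beta, v.se, by, sy, v.effect_allele, action)
        )
    for rsid, action in dropped:
        log.info("harmonize: %s %s", rsid, action)
    return kept, dropped


# ---------------------------------------------------------------------------
# summary-data estimators
# ---------------------------------------------------------------------------


def wald_ratio(h: HarmonizedInstrument) -> tuple[float, float]:
    """Per-variant ratio estimate by/bx with first-order SE |sy/bx|
    (exposure-beta uncertainty ignored, the standard IVW convention)."""
    if h.bx == 0:
        raise ZeroDivisionError(f"{h.rsid}: undefined Wald ratio (bx = 0)")
    return h.by / h.bx, abs(h.sy / h.bx)


def _arrays(harmonized: list[HarmonizedInstrument]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([h.bx for h in harmonized])
    by = np.array([h.by for h in harmonized])
    sy = np.array([h.sy for h in harmonized])
    return bx, by, sy


def ivw(
    harmonized: list[HarmonizedInstrument],
    effects_model: str = "fixed",
    exposure_sd: float = 1.0,
) -> MRResult:
    """Inverse-variance-weighted estimate: the precision-weighted average of
    Wald ratios, w_j = bx_j^2 / sy_j^2 (equivalently the no-intercept WLS
    slope of by on bx).  ``multiplicative_random`` inflates the SE by
    max(1, sqrt(Q/(J-1)))."""
    J = len(harmonized)
    if J == 0:
        raise ValueError("no harmonized instruments")
    if effects_model not in {"fixed", "multiplicative_random"}:
        raise ValueError(f"unknown effects_model {effects_model!r}")
    if effects_model == "multiplicative_random" and J < 3:
        raise ValueError("multiplicative_random needs >= 3 instruments")
    bx, by, sy = _arrays(harmonized)
    if np.any(bx == 0):
        raise ZeroDivisionError("bx = 0 instrument present")
    w = bx**2 / sy**2
    theta = by / bx
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    method = "ivw_fixed"
    if effects_model == "multiplicative_random":
        q = float(np.sum(w * (theta - est) ** 2))
        se *= max(1.0, np.sqrt(q / (J - 1)))
        method = "ivw_mre"
    est, se = est * exposure_sd, se * exposure_sd
    return MRResult(
        method=method,
        estimate=est,
        se=se,
        p=float(2 * stats.norm.sf(abs(est / se))),
        n_variants=J,
    )


def cochran_q(
    harmonized: list[HarmonizedInstrument], ivw_estimate: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic of the Wald ratios around the IVW
    estimate, with p from the chi-square upper tail on J-1 df."""
    J = len(harmonized)
    if J < 2:
        raise ValueError("Q needs >= 2 instruments")
    bx, by, sy = _arrays(harmonized)
    w = bx**2 / sy**2
    theta = by / bx
    if ivw_estimate is None:
        ivw_estimate = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - ivw_estimate) ** 2))
    df = J - 1
    return q, df, float(stats.chi2.sf(q, df))


def mr_egger(
    harmonized: list[HarmonizedInstrument], exposure_sd: float = 1.0
) -> tuple[MRResult, tuple[float, float, float]]:
    """MR-Egger: weighted least squares of by on bx with an intercept,
    weights 1/sy^2, rows first oriented so all bx >= 0.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropy (nonzero under exclusion-restriction violation,
    consistent slope under InSIDE).  SEs use the WLS residual variance floored
    at 1; p-values from t on J-2 df.
    Returns (slope MRResult, (intercept, intercept_se, intercept_p)).
    """
    import statsmodels.api as sm

    J = len(harmonized)
    if J < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    bx, by, sy = _arrays(harmonized)
    flip = bx < 0
    bx, by = np.abs(bx), np.where(flip, -by, by)
    if np.allclose(bx, bx[0]):
        raise np.linalg.LinAlgError("all exposure betas equal: Egger design singular")
    X = np.column_stack([np.ones(J), bx])
    res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    infl = np.sqrt(max(1.0, res.scale) / res.scale)  # floor residual sd at 1
    icpt, slope = float(res.params[0]), float(res.params[1])
    icpt_se, slope_se = float(res.bse[0] * infl), float(res.bse[1] * infl)
    df = J - 2
    slope_p = float(2 * stats.t.sf(abs(slope / slope_se), df))
    icpt_p = float(2 * stats.t.sf(abs(icpt / icpt_se), df))
    result = MRResult(
        method="egger",
        estimate=slope * exposure_sd,
        se=slope_se * exposure_sd,
        p=slope_p,
        n_variants=J,
    )
    return result, (icpt, icpt_se, icpt_p)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    wn = w[order] / w.sum()
    # weight-percentile of each ordered ratio
    pq = np.cumsum(wn) - wn / 2.0
    if pq[0] >= 0.5:
        return float(th[0])
    if pq[-1] <= 0.5:
        return float(th[-1])
    k = int(np.searchsorted(pq, 0.5, side="right")) - 1
    return float(th[k] + (th[k + 1] - th[k]) * (0.5 - pq[k]) / (pq[k + 1] - pq[k]))


def weighted_median(
    harmonized: list[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
    exposure_sd: float = 1.0,
) -> MRResult:
    """Weighted-median estimator: the causal value at the 50% point of the
    weight-ordered Wald ratios (consistent when >= 50% of weight comes from
    valid instruments), with SE from a seeded parametric bootstrap."""
    J = len(harmonized)
    if J < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    bx, by, sy = _arrays(harmonized)
    sx = np.array([h.sx for h in harmonized])
    w = bx**2 / sy**2
    est = _weighted_median_point(by / bx, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, 1e-12, bx_b)
        boots[b] = _weighted_median_point(by_b / bx_b, bx_b**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    est, se = est * exposure_sd, se * exposure_sd
    return MRResult(
        method="weighted_median",
        estimate=est,
        se=se,
        p=float(2 * stats.norm.sf(abs(est / se))),
        n_variants=J,
    )


def leave_one_out(
    harmonized: list[HarmonizedInstrument], exposure_sd: float = 1.0
) -> pd.DataFrame:
    """IVW recomputed excluding each instrument in turn."""
    if len(harmonized) < 2:
        raise ValueError("leave-one-out needs >= 2 instruments")
    rows = []
    for i, h in enumerate(harmonized):
        rest = harmonized[:i] + harmonized[i + 1 :]
        r = ivw(rest, "fixed", exposure_sd)
        rows.append(
            {
                "excluded_rsid": h.rsid,
                "estimate": r.estimate,
                "se": r.se,
                "p": r.p,
                "n_variants": r.n_variants,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity filters & multiplicity
# ---------------------------------------------------------------------------


def filter_instruments(
    instruments: list[InstrumentVariant], exclusion: str
) -> list[InstrumentVariant]:
    """Sensitivity instrument subsets.

    pleiotropy_flagged: drop instruments with any pleiotropy flag.
    non_cis: keep only cis instruments.
    non_lead: drop any instrument that is a member of another's clump
    (single lead variant per locus).
    """
    if exclusion == "pleiotropy_flagged":
        kept = [v for v in instruments if not v.pleiotropy_flags]
    elif exclusion == "non_cis":
        kept = [v for v in instruments if v.is_cis]
    elif exclusion == "non_lead":
        members = {m for v in instruments for m in v.clump_members}
        kept = [v for v in instruments if v.rsid not in members]
    else:
        raise ValueError(f"unknown exclusion {exclusion!r}")
    if not kept:
        raise ValueError(f"exclusion {exclusion!r} removes every instrument")
    removed = [v.rsid for v in instruments if v not in kept]
    if removed:
        log.info("filter_instruments(%s): removed %s", exclusion, removed)
    return kept


def bonferroni(p_values: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m * p) for m tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0,1]")
    if m < np.size(p):
        raise ValueError("m must be >= number of tests")
    return np.minimum(1.0, m * p)
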