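"""Weighted allele score construction, censored-biomarker validation, and
covariate-balance diagnostics.

The score S_i = sum_j w_j g_ij is a weighted sum of instrument dosages with
the derivation-GWAS betas as weights.  Because the validation biomarker has a
lower limit of detection, validation uses proportional-odds (ordinal
logistic) regression with the below-LOD mass as the lowest category and
quantile bins of the detectable range above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CensoredMeasurement
from .derive import InstrumentVariant

__all__ = ["ScoreVector", "OrdinalFit", "compute_score", "validate_score_ordinal", "covariate_balance"]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlleleMismatchError(ValueError):
    """Raised when dosage and instrument alleles cannot be reconciled."""


@dataclass
class ScoreVector:
    """Per-individual raw and standardized weighted allele scores."""

    raw: np.ndarray
    standardized: np.ndarray
    weights: dict[str, float]
    n: int


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(a, "?") for a in allele)


def compute_score(
    dosages: np.ndarray | pd.DataFrame,
    instruments: list[InstrumentVariant],
    rsids: list[str] | None = None,
    dosage_alleles: dict[str, tuple[str, str]] | None = None,
) -> ScoreVector:
    """Weighted sum of aligned instrument dosages.

    ``dosage_alleles`` maps rsid -> (effect_allele, other_allele) of the
    dosage file's coding; when the file's effect allele is the instrument's
    other allele (directly or after strand complement), the dosage is flipped
    g -> 2 - g.  Missing instrument columns or irreconcilable alleles raise.
    """
    if isinstance(dosages, pd.DataFrame):
        rsids = list(dosages.columns)
        G = dosages.to_numpy(dtype=float)
    else:
        if rsids is None:
            raise ValueError("rsids required when dosages is an array")
        G = np.asarray(dosages, dtype=float)
    col = {r: i for i, r in enumerate(rsids)}
    missing = [v.rsid for v in instruments if v.rsid not in col]
    if missing:
        raise KeyError(f"instrument columns missing from dosages: {missing}")
    n = G.shape[0]
    raw = np.zeros(n)
    weights: dict[str, float] = {}
    for v in instruments:
        g = G[:, col[v.rsid]]
        if dosage_alleles is not None and v.rsid in dosage_alleles:
            ea, oa = dosage_alleles[v.rsid]
            if (ea, oa) == (v.effect_allele, v.other_allele):
                pass
            elif (ea, oa) == (v.other_allele, v.effect_allele):
                g = 2.0 - g
            elif (_complement(ea), _complement(oa)) == (v.effect_allele, v.other_allele):
                pass
            elif (_complement(ea), _complement(oa)) == (v.other_allele, v.effect_allele):
                g = 2.0 - g
            else:
                raise AlleleMismatchError(
                    f"{v.rsid}: dosage alleles {ea}/{oa} irreconcilable with "
                    f"instrument {v.effect_allele}/{v.other_allele}"
                )
        raw = raw + v.weight * g
        weights[v.rsid] = v.weight
    sd = raw.std()
    standardized = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    return ScoreVector(raw=raw, standardized=standardized, weights=weights, n=n)


@dataclass
class OrdinalFit:
    """Proportional-odds validation fit of measured biomarker on the score."""

    coefficient: float  # per 1 SD of score, latent logistic scale
    se: float
    p: float
    cutpoints: np.ndarray
    n: int
    n_below_lod: int
    converged: bool


def validate_score_ordinal(
    exposure_measured: CensoredMeasurement,
    score: ScoreVector,
    covariates: pd.DataFrame | None = None,
    n_detectable_bins: int = 4,
) -> OrdinalFit:
    """Validate the score against a censored biomarker measurement.

    Category 0 is the below-LOD mass; detectable values are split into
    ``n_detectable_bins`` quantile bins.  A proportional-odds logistic model
    of category on the standardized score (plus covariates) is maximized by
    Newton-type iteration; the returned coefficient is per 1 SD of score with
    a Wald SE.  Bins with fewer than 2 observations are merged into their
    lower neighbour (logged).
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if n_detectable_bins < 1:
        raise ValueError("n_detectable_bins must be >= 1")
    values = exposure_measured.values
    below = exposure_measured.below_lod
    n = len(values)
    cat = np.zeros(n, dtype=int)
    detect = ~below
    if detect.sum() and n_detectable_bins > 1:
        qs = np.quantile(values[detect], np.linspace(0, 1, n_detectable_bins + 1)[1:-1])
        cat[detect] = 1 + np.searchsorted(qs, values[detect], side="right")
    else:
        cat[detect] = 1
    # merge categories with < 2 observations into the lower neighbour
    labels, counts = np.unique(cat, return_counts=True)
    for lab, cnt in zip(labels, counts):
        if cnt < 2 and lab > 0:
            log.info("validate_score_ordinal: merging sparse category %d", lab)
            cat[cat == lab] = lab - 1
    # re-label to consecutive codes
    cat = np.searchsorted(np.unique(cat), cat)
    X = score.standardized.reshape(-1, 1)
    names = ["score"]
    if covariates is not None and covariates.shape[1]:
        X = np.column_stack([X, covariates.to_numpy(dtype=float)])
        names += list(covariates.columns)
    exog = pd.DataFrame(X, columns=names)
    endog = pd.Series(pd.Categorical(cat, ordered=True))
    model = OrderedModel(endog, exog, distr="logit")
    res = model.fit(method="bfgs", maxiter=200, gtol=1e-8, disp=False)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"ordinal fit did not converge: {res.mle_retvals}")
    coef = float(res.params["score"])
    se = float(res.bse["score"])
    k = len(np.unique(cat))
    cut = np.asarray(model.transform_threshold_params(res.params[-(k - 1):]))[1:-1]
    return OrdinalFit(
        coefficient=coef,
        se=se,
        p=float(2 * stats.norm.sf(abs(coef / se))),
        cutpoints=cut,
        n=n,
        n_below_lod=exposure_measured.n_below_lod,
        converged=True,
    )


def covariate_balance(
    covariates: pd.DataFrame, score: np.ndarray, n_groups: int = 5
) -> pd.DataFrame:
    """Covariate means by equal-size score groups (fifths by default).

    Individuals are ranked by score (ties broken by row order) and cut into
    ``n_groups`` groups, remainder individuals going to the lower groups.
    Returns one row per covariate with the overall mean, per-group means,
    per-group SDs, and the top-minus-bottom difference.  Under valid random
    allele allocation, covariates not downstream of genotype should balance.
    """
    score = np.asarray(score, dtype=float)
    n = len(score)
    if n < n_groups:
        raise ValueError("need at least n_groups individuals")
    if score.std() == 0:
        raise ValueError("constant score: groups undefined")
    order = np.argsort(score, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    group = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        group[order[start : start + size]] = g
        start += size
    rows = []
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=float)
        row: dict[str, float | str] = {"covariate": name, "all_mean": x.mean()}
        means = []
        for g in range(n_groups):
            xg = x[group == g]
            row[f"group{g + 1}_mean"] = xg.mean()
            row[f"group{g + 1}_sd"] = xg.std(ddof=1)
            means.append(xg.mean())
        row["top_minus_bottom"] = means[-1] - means[0]
        rows.append(row)
    return pd.DataFrame(rows)
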