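"""Statistical power for score-based Mendelian randomization with binary
outcomes.

Uses the standard normal-approximation for the Wald test of the score
coefficient in logistic regression: with n individuals, case fraction K, and
a score explaining a fraction R^2 of exposure variance, the test statistic
for a true odds ratio OR per 1-SD of exposure has mean
|log OR| * sqrt(n * R^2 * K * (1-K)), giving

    power = Phi(sqrt(n R^2 K(1-K)) |log OR| - z_{1-alpha/2})

and the minimum detectable OR as its inverse.  An empirical check simulates
cohorts end-to-end and counts rejections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import stats

from .cohort import CohortConfig, simulate_cohort
from .mr import associate_score_binary

__all__ = ["PowerSpec", "min_detectable_or", "power_at_or", "min_detectable_or_per_allele", "empirical_power"]


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs for a score-based MR power calculation."""

    n: int
    n_cases: int
    r2: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.n_cases < self.n:
            raise ValueError("need 0 < n_cases < n")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must be in (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0,1)")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n


def _ncp_scale(n: float, r2: float, k: float) -> float:
    return float(np.sqrt(n * r2 * k * (1.0 - k)))


def min_detectable_or(spec: PowerSpec) -> float:
    """Smallest odds ratio per 1-SD of exposure detectable at the spec's
    alpha and power (upper-tail approximation)."""
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    b = (z_a + z_b) / _ncp_scale(spec.n, spec.r2, spec.case_fraction)
    return float(np.exp(b))


def power_at_or(spec: PowerSpec, or_value: float) -> float:
    """Power to detect a true odds ratio ``or_value`` per 1-SD of exposure."""
    if or_value <= 0:
        raise ValueError("or_value must be > 0")
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = _ncp_scale(spec.n, spec.r2, spec.case_fraction) * abs(np.log(or_value))
    return float(stats.norm.cdf(ncp - z_a))


def min_detectable_or_per_allele(
    n: int, n_cases: int, eaf: float, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Two-sample per-variant analogue: minimum detectable OR per effect
    allele of a single variant with allele frequency ``eaf`` (allele dosage
    variance 2 eaf (1-eaf) replaces the score R^2)."""
    k = n_cases / n
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    b = (z_a + z_b) / np.sqrt(n * 2.0 * eaf * (1.0 - eaf) * k * (1.0 - k))
    return float(np.exp(b))


def empirical_power(
    cohort_config: CohortConfig,
    true_or: float,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Rejection fraction of the score-outcome logistic test by simulation.

    Each replicate simulates a cohort at ``true_or`` (log-odds per 1-SD of
    true exposure), scores individuals with the generating per-allele
    effects, fits the logistic association, and records p < alpha.  Returns
    (rejection fraction, binomial SE).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = dc_replace(cohort_config, causal_log_or=float(np.log(true_or)), seed=rep_seed)
        cohort = simulate_cohort(cfg)
        raw = cohort.dosages @ cohort.truth["per_allele_effects"]
        sd = raw.std()
        score_std = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
        res = associate_score_binary(cohort.outcomes["disease"], score_std)
        rejections += int(res.p < alpha)
    frac = rejections / n_reps
    return frac, float(np.sqrt(frac * (1 - frac) / n_reps))
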