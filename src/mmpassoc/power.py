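"""Analytic power and minimal detectable odds ratio (MDOR) for case-control
genetic association tests.

Setup: genotypes in controls follow Hardy-Weinberg proportions at the control
minor-allele frequency; under a logistic disease model with odds ratio ``or_``
per unit of the genetic coding (additive dose, dominant or recessive
indicator), the case-group genotype distribution is the control distribution
tilted by ``or_ ** coding``.  The test considered is the 1-df score test of
the genetic term (for the binary codings this is the Pearson chi-square of
the collapsed 2x2 table).

Power is computed exactly for the binary codings by enumerating the two
binomial margins of the collapsed table, and by a normal approximation with
the exact retrospective mean/variance of the score statistic for the additive
coding.  The MDOR is the smallest odds ratio on a grid achieving the target
power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CODINGS = {
    "additive": np.array([0.0, 1.0, 2.0]),
    "dominant": np.array([0.0, 1.0, 1.0]),
    "recessive": np.array([0.0, 0.0, 1.0]),
}


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a power calculation."""

    n_cases: int
    n_controls: int
    maf: float
    model: str = "additive"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError("maf must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.model not in CODINGS:
            raise ValueError(f"unknown model {self.model!r}")


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """(p^2, 2pq, q^2) genotype probabilities for minor-allele frequency q."""
    p, q = 1.0 - maf, maf
    return np.array([p * p, 2 * p * q, q * q])


def case_genotype_probs(maf: float, or_: float, model: str) -> np.ndarray:
    """Control HWE probabilities tilted by the genotype odds ratios."""
    x = CODINGS[model]
    q = hwe_genotype_probs(maf)
    r = q * or_ ** x
    return r / r.sum()


def _exact_binary_power(
    n1: int, n0: int, p1: float, p0: float, alpha: float
) -> float:
    """Exact power of the 2x2 Pearson (score) test with binomial margins:
    exposure probability p1 in the n1 cases, p0 in the n0 controls."""
    crit = stats.chi2.ppf(1 - alpha, 1)
    k1 = np.arange(n1 + 1)
    k0 = np.arange(n0 + 1)
    K1, K0 = np.meshgrid(k1, k0, indexing="ij")
    n = n1 + n0
    phat = (K1 + K0) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        variance = phat * (1 - phat) * (n1 * n0 / n)
        score = (n0 / n) * K1 - (n1 / n) * K0
        statistic = np.where(variance > 0, score * score / variance, 0.0)
    weight = np.outer(stats.binom.pmf(k1, n1, p1), stats.binom.pmf(k0, n0, p0))
    return float((weight * (statistic > crit)).sum())


def genetic_power(spec: PowerSpec, or_: float) -> float:
    """Power of the 1-df score test at a given genotype odds ratio.

    At ``or_ = 1`` this returns the nominal alpha (up to the discreteness of
    the exact binary calculation).
    """
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    x = CODINGS[spec.model]
    q = hwe_genotype_probs(spec.maf)
    r = case_genotype_probs(spec.maf, or_, spec.model)
    n1, n0 = spec.n_cases, spec.n_controls
    n = n1 + n0

    if spec.model in ("dominant", "recessive"):
        return _exact_binary_power(
            n1, n0, float((r * x).sum()), float((q * x).sum()), spec.alpha
        )

    # additive: normal approximation with exact retrospective moments of the
    # score statistic U = sum x (case_count - expected under pooled rate)
    mean_u = (n1 * n0 / n) * float((x * r).sum() - (x * q).sum())
    var_x = lambda probs: float((x * x * probs).sum() - ((x * probs).sum()) ** 2)
    var_u = (n0 / n) ** 2 * n1 * var_x(r) + (n1 / n) ** 2 * n0 * var_x(q)
    mixture = (n1 * r + n0 * q) / n
    var_pooled = (n1 * n0 / n) * var_x(mixture)
    cut = np.sqrt(stats.chi2.ppf(1 - spec.alpha, 1) * var_pooled)
    sd = np.sqrt(var_u)
    return float(
        stats.norm.cdf((-cut - mean_u) / sd) + stats.norm.sf((cut - mean_u) / sd)
    )


@dataclass
class MDORResult:
    """Smallest grid odds ratio reaching the target power."""

    mdor: float | None  # None when the target is unreachable below or_max
    power_at_mdor: float | None
    target_power: float
    grid_step: float
    or_max: float
    reachable: bool

    def __str__(self) -> str:
        if not self.reachable:
            return f">{self.or_max:g}"
        return f"{self.mdor:.2f}"


def mdor_search(
    spec: PowerSpec,
    target_power: float = 0.80,
    grid_step: float = 0.01,
    or_min: float = 1.01,
    or_max: float = 10.0,
) -> MDORResult:
    """Grid search for the minimal detectable odds ratio.

    Scans odds ratios from ``or_min`` to ``or_max`` in ``grid_step``
    increments and returns the first one whose power reaches the target; an
    unreachable target is reported as an open upper bound rather than an
    error.
    """
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    for or_ in np.arange(or_min, or_max + grid_step / 2, grid_step):
        power = genetic_power(spec, float(or_))
        if power >= target_power:
            return MDORResult(
                mdor=round(float(or_), 10),
                power_at_mdor=power,
                target_power=target_power,
                grid_step=grid_step,
                or_max=or_max,
                reachable=True,
            )
    return MDORResult(
        mdor=None,
        power_at_mdor=None,
        target_power=target_power,
        grid_step=grid_step,
        or_max=or_max,
        reachable=False,
    )


def monte_carlo_power(
    spec: PowerSpec,
    or_: float,
    n_sims: int = 2000,
    seed: int | None = None,
) -> float:
    """Empirical rejection rate of the score test under retrospective
    sampling; the simulation oracle for :func:`genetic_power`."""
    rng = np.random.default_rng(seed)
    x = CODINGS[spec.model]
    q = hwe_genotype_probs(spec.maf)
    r = case_genotype_probs(spec.maf, or_, spec.model)
    n1, n0 = spec.n_cases, spec.n_controls
    n = n1 + n0
    crit = stats.chi2.ppf(1 - spec.alpha, 1)
    rejections = 0
    for _ in range(n_sims):
        cases = rng.multinomial(n1, r)
        controls = rng.multinomial(n0, q)
        total = cases + controls
        pooled = n1 / n
        u = float((x * (cases - total * pooled)).sum())
        xbar = float((x * total).sum()) / n
        v = pooled * (1 - pooled) * float(((x - xbar) ** 2 * total).sum())
        if v > 0 and u * u / v > crit:
            rejections += 1
    return rejections / n_sims
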