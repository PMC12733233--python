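"""Single-locus association statistics under genetic inheritance models.

Covers the within-study analysis chain: genotype-code encodings (codominant,
dominant, recessive, overdominant, log-additive), crude odds ratios with
Woolf confidence intervals, likelihood-ratio / Pearson tests, covariate-
adjusted logistic fits, an exact Hardy-Weinberg test by full enumeration of
heterozygote counts, and Benjamini-Hochberg adjustment within declared test
families.

Zero-cell policy: no continuity correction.  A zero in an exposed-case or
unexposed-noncase cell yields OR 0; a zero in the other diagonal yields an
infinite OR; the confidence interval is omitted whenever any cell is zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

MODEL_NAMES = ("codominant", "dominant", "recessive", "overdominant", "log_additive")

#: Genotype-code (1/2/3) to exposure mapping for the two-group models.
_BINARY_GROUPING = {
    "dominant": {1: 0, 2: 1, 3: 1},
    "recessive": {1: 0, 2: 0, 3: 1},
    "overdominant": {1: 0, 2: 1, 3: 0},
}


def encode_model(codes: np.ndarray, model: str) -> np.ndarray:
    """Map genotype codes to the exposure under a genetic model.

    Codominant and log-additive return the 0/1/2 minor-allele dose (treated as
    a 3-level factor with dose 0 as reference, or as a numeric dose,
    respectively); the binary models return 0/1 groups.  NaN propagates.
    """
    codes = np.asarray(codes, dtype=float)
    if model in ("codominant", "log_additive"):
        return codes - 1
    try:
        grouping = _BINARY_GROUPING[model]
    except KeyError:
        raise ValueError(f"unknown genetic model {model!r}") from None
    out = np.full(codes.shape, np.nan)
    for code, grp in grouping.items():
        out[codes == code] = grp
    return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (exposed-case, exposed-noncase, unexposed-case,
    unexposed-noncase)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell count in {cells}")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def flipped_exposure(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass
class EffectEstimate:
    """An odds ratio with Woolf CI and test p-value under one encoding."""

    or_: float
    ci_low: float | None
    ci_high: float | None
    p: float | None
    model: str
    contrast: str
    p_fdr: float | None = None
    estimator: str = "crude"
    flags: list[str] = field(default_factory=list)


def woolf_ci(
    t: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float] | None:
    """Woolf (log-OR normal) confidence interval; None when any cell is zero."""
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    a, b, c, d = t.cells
    if min(a, b, c, d) == 0:
        return None
    z = stats.norm.ppf(1 - (1 - level) / 2)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def association_p(t: ContingencyTable2x2, method: str = "lrt") -> float:
    """Association p for a 2x2 table: likelihood-ratio (G) test by default,
    Pearson chi-square via ``method='pearson'``."""
    obs = np.array(t.cells, dtype=float).reshape(2, 2)
    return _table_test_p(obs, method)


def _table_test_p(obs: np.ndarray, method: str) -> float:
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        return 1.0
    exp = row * col / n
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if method == "lrt":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        stat = 2 * terms.sum()
    elif method == "pearson":
        stat = ((obs - exp) ** 2 / exp).sum()
    else:
        raise ValueError(f"unknown test method {method!r}")
    return float(stats.chi2.sf(stat, df))


def crude_odds_ratio(
    t: ContingencyTable2x2,
    model: str = "",
    contrast: str = "",
    level: float = 0.95,
    p_method: str = "lrt",
) -> EffectEstimate:
    """Cross-product odds ratio with Woolf CI and a G-test p-value."""
    a, b, c, d = t.cells
    flags = []
    if a == 0 or d == 0:
        or_ = 0.0
        flags.append("zero_cell")
    elif b == 0 or c == 0:
        or_ = math.inf
        flags.append("zero_cell")
    else:
        or_ = a * d / (b * c)
    ci = woolf_ci(t, level)
    low, high = ci if ci is not None else (None, None)
    return EffectEstimate(
        or_=or_,
        ci_low=low,
        ci_high=high,
        p=association_p(t, p_method),
        model=model,
        contrast=contrast,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    counts: tuple[int, int, int]
    maf: float
    p_exact: float
    p_chisq: float


def hwe_test(counts: tuple[int, int, int]) -> HWEResult:
    """Hardy-Weinberg test for (n_AA, n_Aa, n_aa) genotype counts.

    The exact p sums, over all heterozygote counts compatible with the
    observed allele counts, the conditional probabilities of tables no more
    probable than the observed one (the standard two-sided exact HWE test).
    A 1-df Pearson chi-square p against the p^2 / 2pq / q^2 expectations is
    reported alongside.
    """
    n_aa_maj, n_het, n_aa_min = (int(x) for x in counts)
    if min(n_aa_maj, n_het, n_aa_min) < 0:
        raise ValueError("negative genotype count")
    n = n_aa_maj + n_het + n_aa_min
    if n == 0:
        raise ValueError("empty genotype counts")
    n_minor = 2 * n_aa_min + n_het
    maf = n_minor / (2 * n)
    if n_minor == 0 or n_minor == 2 * n:  # monomorphic
        return HWEResult(tuple(counts), maf, 1.0, 1.0)

    rare = min(n_minor, 2 * n - n_minor)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts): multinomial/hypergeometric-form
    log_p = (
        -gammaln((n_minor - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - n_minor - hets) / 2 + 1)
        + hets * math.log(2)
    )
    probs = np.exp(log_p - log_p.max())
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_het)]
    p_exact = float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))

    p = 1 - maf
    exp = np.array([p * p, 2 * p * maf, maf * maf]) * n
    stat = (((np.array(counts) - exp) ** 2) / exp).sum()
    p_chisq = float(stats.chi2.sf(stat, 1))
    return HWEResult(tuple(counts), maf, p_exact, p_chisq)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Logistic association
# ---------------------------------------------------------------------------

def _design_for_model(exposure: np.ndarray, model: str) -> tuple[np.ndarray, list[str]]:
    if model == "codominant":
        cols = np.column_stack([(exposure == 1), (exposure == 2)]).astype(float)
        return cols, ["het_vs_ref", "hom_vs_ref"]
    return exposure.reshape(-1, 1).astype(float), [_contrast_name(model)]


def _contrast_name(model: str) -> str:
    return {
        "dominant": "carrier_vs_ref",
        "recessive": "hom_vs_rest",
        "overdominant": "het_vs_hom",
        "log_additive": "per_allele",
    }[model]


def logistic_association(
    c,
    snp_id: str,
    outcome: str,
    model: str,
    covariates: tuple[str, ...] = (),
) -> list[EffectEstimate]:
    """Maximum-likelihood logistic fit of an outcome on one encoded SNP.

    Returns one estimate per contrast (two for codominant, sharing the 2-df
    likelihood-ratio p of the genotype term).  Perfect separation is flagged
    on the estimate rather than raised.
    """
    y = c.outcome(outcome)
    codes = pd.Series(c.genotypes.column(snp_id), index=c.samples).loc[y.index]
    df = pd.DataFrame({"y": y, "codes": codes})
    for cov in covariates:
        df[cov] = c.phenotypes.data.loc[y.index, cov]
    df = df.dropna()
    if df["y"].nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has a single level after filtering")

    exposure = encode_model(df["codes"].to_numpy(), model)
    geno_cols, contrasts = _design_for_model(exposure, model)
    covs = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    X_full = np.column_stack([np.ones(len(df)), geno_cols, covs])
    X_null = np.column_stack([np.ones(len(df)), covs])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design matrix")
    yv = df["y"].to_numpy(dtype=float)

    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(yv, X_full).fit(disp=0, maxiter=200)
            null = sm.Logit(yv, X_null).fit(disp=0, maxiter=200)
            converged = full.mle_retvals.get("converged", True)
        except Exception:
            full = null = None
            converged = False
    if full is None or not converged or np.abs(full.params).max() > 30:
        flags.append("separation")

    results = []
    k = geno_cols.shape[1]
    if full is not None and null is not None:
        lr = 2 * (full.llf - null.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), k))
        ses = np.sqrt(np.diag(full.cov_params()))
        z = stats.norm.ppf(0.975)
        for j, contrast in enumerate(contrasts, start=1):
            beta, se = full.params[j], ses[j]
            results.append(
                EffectEstimate(
                    or_=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - z * se)),
                    ci_high=float(np.exp(beta + z * se)),
                    p=p,
                    model=model,
                    contrast=contrast,
                    estimator="adjusted" if covariates else "logistic",
                    flags=list(flags),
                )
            )
    else:
        for contrast in contrasts:
            results.append(
                EffectEstimate(
                    or_=math.nan, ci_low=None, ci_high=None, p=None,
                    model=model, contrast=contrast, flags=list(flags),
                )
            )
    return results


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def tables_from_counts(
    counts: pd.DataFrame | np.ndarray, model: str
) -> list[tuple[str, ContingencyTable2x2]]:
    """Collapse a 2x3 genotype count table (levels 0/1 x codes 1/2/3) into the
    2x2 contrast table(s) of a genetic model."""
    m = np.asarray(counts, dtype=int)
    (r1, r2, r3), (s1, s2, s3) = m[0], m[1]  # level0, level1 counts by code
    def t(exp1, exp0):  # exposed / unexposed counts -> (a, b, c, d)
        return ContingencyTable2x2(exp1[1], exp1[0], exp0[1], exp0[0])
    if model == "codominant":
        return [
            ("het_vs_ref", t((r2, s2), (r1, s1))),
            ("hom_vs_ref", t((r3, s3), (r1, s1))),
        ]
    if model == "dominant":
        return [(_contrast_name(model), t((r2 + r3, s2 + s3), (r1, s1)))]
    if model == "recessive":
        return [(_contrast_name(model), t((r3, s3), (r1 + r2, s1 + s2)))]
    if model == "overdominant":
        return [(_contrast_name(model), t((r2, s2), (r1 + r3, s1 + s3)))]
    raise ValueError(f"no 2x2 collapse for model {model!r}")


def crude_model_scan(
    counts: pd.DataFrame | np.ndarray, model: str, p_method: str = "lrt"
) -> list[EffectEstimate]:
    """Crude OR/CI per contrast of a model from a 2x3 count table, with one
    shared model-level p (2 df for codominant, 1 df otherwise)."""
    m = np.asarray(counts, dtype=float)
    if model == "codominant":
        p = _table_test_p(m, p_method)
    else:
        first = tables_from_counts(m, model)[0][1]
        p = association_p(first, p_method)
    out = []
    for contrast, tab in tables_from_counts(m, model):
        est = crude_odds_ratio(tab, model=model, contrast=contrast, p_method=p_method)
        est.p = p
        out.append(est)
    return out


def run_single_locus_scan(
    c,
    outcomes: tuple[str, ...] = ("status",),
    models: tuple[str, ...] = ("codominant", "dominant", "recessive", "overdominant"),
    covariates: tuple[str, ...] = (),
    estimator: str = "crude",
    p_method: str = "lrt",
) -> pd.DataFrame:
    """One estimate per SNP x outcome x model x contrast, with BH adjustment
    applied within the two declared families (case-control vs within-case).

    Per-cell failures (empty strata, separation) become flagged rows, not
    aborts.  The codominant model contributes a single p per family member.
    """
    from .io import genotype_counts

    rows = []
    for snp in c.genotypes.snps:
        for outcome in outcomes:
            family = "case_control" if outcome == "status" else "within_case"
            for model in models:
                base = {
                    "snp": snp.id, "outcome": outcome, "model": model,
                    "family": family,
                }
                try:
                    counts = genotype_counts(c, snp.id, outcome)
                    if estimator == "crude":
                        ests = crude_model_scan(counts, model, p_method)
                    else:
                        ests = logistic_association(
                            c, snp.id, outcome, model, covariates
                        )
                    cm = np.asarray(counts, dtype=int)
                    tabs = (
                        tables_from_counts(cm, model)
                        if model != "log_additive" else None
                    )
                    for k, est in enumerate(ests):
                        cells = (
                            {
                                "n_unexposed_0": tabs[k][1].d,
                                "n_unexposed_1": tabs[k][1].c,
                                "n_exposed_0": tabs[k][1].b,
                                "n_exposed_1": tabs[k][1].a,
                            }
                            if tabs is not None else {}
                        )
                        rows.append(
                            base | cells | {
                                "contrast": est.contrast,
                                "or": est.or_, "ci_low": est.ci_low,
                                "ci_high": est.ci_high, "p": est.p,
                                "estimator": est.estimator,
                                "flags": ";".join(est.flags),
                            }
                        )
                except (ValueError, KeyError) as exc:
                    rows.append(
                        base | {
                            "contrast": "", "or": np.nan, "p": np.nan,
                            "estimator": estimator, "flags": f"error:{exc}",
                        }
                    )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for family in out["family"].unique():
        # one p per (snp, outcome, model) cell; codominant counts once
        cells = out[out["family"] == family].groupby(
            ["snp", "outcome", "model"], sort=False
        )["p"].first()
        valid = cells.dropna()
        if valid.empty:
            continue
        adjusted = pd.Series(bh_adjust(valid.to_numpy()), index=valid.index)
        for idx, row in out[out["family"] == family].iterrows():
            key = (row["snp"], row["outcome"], row["model"])
            if key in adjusted.index:
                out.at[idx, "p_fdr"] = adjusted.loc[key]
    return out
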