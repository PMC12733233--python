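"""EM haplotype-frequency estimation and haplotype-outcome GLM.

Unphased multilocus genotypes are ambiguous: an individual heterozygous at h
loci is compatible with 2^(h-1) unordered haplotype pairs.  The EM algorithm
treats the phase as missing data: the E-step assigns each compatible pair a
posterior proportional to the product of current haplotype frequencies (times
two for heterogeneous pairs), and the M-step re-estimates frequencies from
the expected haplotype counts.  The log-likelihood is non-decreasing across
iterations and is asserted at every step.

The haplotype-outcome GLM expands each individual's design row over their
compatible pairs with posterior weights (additive haplotype-dose coding,
most-frequent haplotype as reference, rare haplotypes pooled), then
alternates a weighted logistic fit with a posterior update that folds in the
outcome model, until the coefficients stabilise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io import Cohort, GenotypeTable

Haplotype = tuple[int, ...]  # 0 = major allele, 1 = minor allele per locus


@dataclass
class HaplotypeSet:
    """EM-estimated haplotype frequencies plus per-individual phase posteriors."""

    haplotypes: list[Haplotype]        # lexicographic order
    freqs: np.ndarray                  # sums to 1
    samples: list[str]                 # individuals retained (no missing codes)
    pair_indices: list[list[tuple[int, int]]]  # compatible (h1, h2) per sample
    posteriors: list[np.ndarray]       # one distribution per sample
    loglik: float
    n_iter: int
    converged: bool

    def labels(self, snps) -> list[str]:
        """Allele-string labels, e.g. 'I-C-A', in haplotype order."""
        out = []
        for hap in self.haplotypes:
            out.append("-".join(
                (s.minor_allele if a else s.major_allele)
                for s, a in zip(snps, hap)
            ))
        return out

    def frequency_table(self, snps) -> pd.DataFrame:
        return pd.DataFrame(
            {"haplotype": self.labels(snps), "frequency": self.freqs}
        ).sort_values("frequency", ascending=False, ignore_index=True)


def _compatible_pairs(codes: tuple[int, ...]) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with a multilocus 1/2/3 code."""
    per_locus = []
    for c in codes:
        if c == 1:
            per_locus.append([(0, 0)])
        elif c == 3:
            per_locus.append([(1, 1)])
        else:
            per_locus.append([(0, 1), (1, 0)])
    pairs = set()
    for combo in itertools.product(*per_locus):
        h1 = tuple(x[0] for x in combo)
        h2 = tuple(x[1] for x in combo)
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


def em_haplotype_frequencies(
    g: GenotypeTable,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    n_restarts: int = 0,
) -> HaplotypeSet:
    """Maximum-likelihood haplotype frequencies by EM over phase assignments.

    Individuals missing any panel genotype are dropped listwise.  The default
    start is uniform over the haplotypes compatible with the data; ``seed``
    only matters when ``n_restarts`` random restarts are requested (the best
    log-likelihood wins).
    """
    if not g.snps:
        raise ValueError("need at least one SNP")
    complete = ~np.isnan(g.codes).any(axis=1)
    samples = [s for s, keep in zip(g.samples, complete) if keep]
    codes = g.codes[complete].astype(int)
    if len(samples) == 0:
        raise ValueError("no individuals with complete genotypes")

    # group identical multilocus genotypes; EM cost then scales with the
    # number of distinct genotypes, not with n
    geno_keys, inverse, weights = np.unique(
        codes, axis=0, return_inverse=True, return_counts=True
    )
    pair_sets = [_compatible_pairs(tuple(row)) for row in geno_keys]
    haplotypes = sorted({h for ps in pair_sets for pair in ps for h in pair})
    index = {h: i for i, h in enumerate(haplotypes)}
    pair_idx = [[(index[a], index[b]) for a, b in ps] for ps in pair_sets]

    rng = np.random.default_rng(seed)
    H = len(haplotypes)

    def run(freqs: np.ndarray):
        loglik = -math.inf
        posts = None
        for it in range(1, max_iter + 1):
            # E-step
            new_ll = 0.0
            expected = np.zeros(H)
            posts = []
            for pairs, w in zip(pair_idx, weights):
                probs = np.array([
                    (1.0 if i == j else 2.0) * freqs[i] * freqs[j]
                    for i, j in pairs
                ])
                total = probs.sum()
                if total <= 0:  # degenerate start; re-seed tiny mass
                    probs = np.ones(len(pairs))
                    total = probs.sum()
                post = probs / total
                posts.append(post)
                new_ll += w * math.log(total)
                for (i, j), pk in zip(pairs, post):
                    expected[i] += w * pk
                    expected[j] += w * pk
            assert new_ll >= loglik - 1e-9, "EM log-likelihood decreased"
            gain = new_ll - loglik
            loglik = new_ll
            # M-step
            freqs = expected / expected.sum()
            if gain < tol and it > 1:
                return freqs, posts, loglik, it, True
        return freqs, posts, loglik, max_iter, False

    starts = [np.full(H, 1.0 / H)]
    for _ in range(n_restarts):
        starts.append(rng.dirichlet(np.ones(H)))
    best = None
    for start in starts:
        result = run(start)
        if best is None or result[2] > best[2]:
            best = result
    freqs, group_posts, loglik, n_iter, converged = best
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")

    per_sample_pairs = [pair_idx[k] for k in inverse]
    per_sample_posts = [group_posts[k] for k in inverse]
    return HaplotypeSet(
        haplotypes=haplotypes,
        freqs=freqs,
        samples=samples,
        pair_indices=per_sample_pairs,
        posteriors=per_sample_posts,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
    )


@dataclass
class HaploGLMResult:
    """Per-haplotype effects versus the reference haplotype."""

    reference: str
    table: pd.DataFrame  # haplotype, frequency, coef, or, ci_low, ci_high, p
    converged: bool
    n_glm_iter: int
    flags: list[str] = field(default_factory=list)


def haplo_glm(
    c: Cohort,
    hs: HaplotypeSet | None = None,
    outcome: str = "status",
    covariates: tuple[str, ...] = (),
    rare_threshold: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> HaploGLMResult:
    """Logistic haplotype-dose GLM with phase-uncertainty weighting.

    Each individual contributes one pseudo-row per compatible haplotype pair,
    weighted by the phase posterior; the dose of each non-reference haplotype
    (0/1/2) enters additively.  Haplotypes rarer than ``rare_threshold`` are
    pooled.  Posteriors are updated against the fitted outcome model and the
    GLM re-fit until the coefficients converge.
    """
    if hs is None:
        hs = em_haplotype_frequencies(c.genotypes)
    y_all = c.outcome(outcome)
    keep = [i for i, s in enumerate(hs.samples) if s in y_all.index]
    if not keep:
        raise ValueError("no phased individuals with a defined outcome")
    y = y_all.loc[[hs.samples[i] for i in keep]].to_numpy(dtype=float)

    ref = int(np.argmax(hs.freqs))
    rare = [
        h for h in range(len(hs.haplotypes))
        if hs.freqs[h] < rare_threshold and h != ref
    ]
    groups: dict[int, int] = {}  # haplotype index -> design column
    col_names: list[str] = []
    labels = hs.labels(c.genotypes.snps)
    for h in range(len(hs.haplotypes)):
        if h == ref:
            continue
        if h in rare:
            if "rare_pooled" not in col_names:
                col_names.append("rare_pooled")
            groups[h] = col_names.index("rare_pooled")
        else:
            col_names.append(labels[h])
            groups[h] = col_names.index(labels[h])
    n_hap_cols = len(col_names)
    if n_hap_cols == 0:
        return HaploGLMResult(
            reference=labels[ref],
            table=pd.DataFrame(),
            converged=True,
            n_glm_iter=0,
            flags=["all_reference"],
        )

    rows, prior_w, row_owner, y_rows = [], [], [], []
    for out_i, i in enumerate(keep):
        pairs = hs.pair_indices[i]
        for (a, b), post in zip(pairs, hs.posteriors[i]):
            dose = np.zeros(n_hap_cols)
            for h in (a, b):
                if h != ref:
                    dose[groups[h]] += 1
            rows.append(dose)
            prior_w.append(max(post, 1e-300))
            row_owner.append(out_i)
            y_rows.append(y[out_i])
    X_h = np.asarray(rows)
    prior_w = np.asarray(prior_w)
    row_owner = np.asarray(row_owner)
    y_rows = np.asarray(y_rows)

    cov_data = None
    if covariates:
        cov_df = c.phenotypes.data.loc[
            [hs.samples[i] for i in keep], list(covariates)
        ]
        if cov_df.isna().any().any():
            raise ValueError("missing covariate values among phased samples")
        cov_data = cov_df.to_numpy(dtype=float)[row_owner]
    X = np.column_stack(
        [np.ones(len(X_h)), X_h] + ([cov_data] if cov_data is not None else [])
    )

    def observed_loglik(b: np.ndarray) -> float:
        """Observed-data log-likelihood: per individual, the phase-prior
        mixture of Bernoulli likelihoods (what the EM iteration maximizes)."""
        eta = X @ b
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        lik = np.where(y_rows == 1, mu, 1 - mu)
        per_person = np.bincount(
            row_owner, weights=prior_w * lik, minlength=len(keep)
        )
        return float(np.log(per_person).sum())

    w = prior_w.copy()
    beta = np.zeros(X.shape[1])
    converged = False
    fit = None
    for it in range(1, max_iter + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                y_rows, X, family=sm.families.Binomial(), freq_weights=w
            ).fit(start_params=beta, maxiter=200)
        new_beta = np.asarray(fit.params)
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        # posterior update: fold the outcome likelihood into the phase weights
        mu = np.clip(fit.predict(X), 1e-12, 1 - 1e-12)
        lik = np.where(y_rows == 1, mu, 1 - mu)
        w = prior_w * lik
        sums = np.bincount(row_owner, weights=w, minlength=len(keep))
        w = w / sums[row_owner]
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("haplotype GLM did not converge; best iterate returned")

    # Wald variance from the observed-data information (numerical Hessian of
    # the mixture log-likelihood); the naive weighted-GLM variance ignores the
    # phase-estimation feedback and is anti-conservative.
    k = len(beta)
    h = 1e-4 * np.maximum(1.0, np.abs(beta))
    hess = np.empty((k, k))
    ll0 = observed_loglik(beta)
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k); ea[a] = h[a]
            eb = np.zeros(k); eb[b] = h[b]
            if a == b:
                val = (
                    observed_loglik(beta + ea) - 2 * ll0 + observed_loglik(beta - ea)
                ) / (h[a] ** 2)
            else:
                val = (
                    observed_loglik(beta + ea + eb)
                    - observed_loglik(beta + ea - eb)
                    - observed_loglik(beta - ea + eb)
                    + observed_loglik(beta - ea - eb)
                ) / (4 * h[a] * h[b])
            hess[a, b] = hess[b, a] = val
    try:
        cov = np.linalg.inv(-hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.asarray(fit.bse)

    z = stats.norm.ppf(0.975)
    freq_by_col = np.zeros(n_hap_cols)
    for h, col in groups.items():
        freq_by_col[col] += hs.freqs[h]
    def safe_exp(x: float) -> float:
        return float(np.exp(np.clip(x, -700, 700)))

    records = []
    flags: list[str] = []
    for j, name in enumerate(col_names, start=1):
        b, se = beta[j], ses[j]
        if abs(b) > 30:  # effectively separated haplotype
            flags.append(f"unstable:{name}")
        records.append({
            "haplotype": name,
            "frequency": freq_by_col[j - 1],
            "coef": b,
            "or": safe_exp(b),
            "ci_low": safe_exp(b - z * se),
            "ci_high": safe_exp(b + z * se),
            "p": float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else math.nan,
        })
    return HaploGLMResult(
        reference=labels[ref],
        table=pd.DataFrame(records),
        converged=converged,
        n_glm_iter=it,
        flags=flags,
    )
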