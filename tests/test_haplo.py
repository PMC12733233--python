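import itertools

import numpy as np
import pandas as pd
import pytest

import mmpassoc as m


def _two_snp_table(freqs: dict, n: int, seed: int) -> m.GenotypeTable:
    """Draw n individuals as random haplotype pairs from a 2-SNP frequency map."""
    rng = np.random.default_rng(seed)
    haps = list(freqs)
    pairs = rng.choice(len(haps), size=(n, 2), p=list(freqs.values()))
    codes = np.array(
        [[1 + haps[a][j] + haps[b][j] for j in range(2)] for a, b in pairs],
        dtype=float,
    )
    snps = [m.SNPDef("locusA", "A", "a"), m.SNPDef("locusB", "B", "b")]
    return m.GenotypeTable([f"s{i}" for i in range(n)], snps, codes)


def _grid_maximizer(table: m.GenotypeTable, rounds: int = 8) -> dict:
    """Brute-force multinomial-likelihood maximizer over the 4-haplotype
    simplex for 2 SNPs, by iteratively zoomed grid search."""
    counts = {}
    for row in table.codes.astype(int):
        counts[tuple(row)] = counts.get(tuple(row), 0) + 1

    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]

    def genotype_prob(f, codes):
        total = 0.0
        for i, j in itertools.product(range(4), repeat=2):
            if all(1 + haps[i][k] + haps[j][k] == codes[k] for k in range(2)):
                total += f[i] * f[j]
        return total

    def loglik(f):
        ll = 0.0
        for codes, k in counts.items():
            p = genotype_prob(f, codes)
            if p <= 0:
                return -np.inf
            ll += k * np.log(p)
        return ll

    best = np.full(4, 0.25)
    width = 0.5  # first pass spans the whole simplex
    for _ in range(rounds):
        axes = [np.linspace(max(c - width, 0), min(c + width, 1), 13) for c in best[:3]]
        top_ll = -np.inf
        for f1 in axes[0]:
            for f2 in axes[1]:
                for f3 in axes[2]:
                    f4 = 1 - f1 - f2 - f3
                    if f4 < 0:
                        continue
                    f = np.array([f1, f2, f3, f4])
                    ll = loglik(f)
                    if ll > top_ll:
                        top_ll, best = ll, f
        width /= 3
    return dict(zip(haps, best))


class TestEMFrequencies:
    def test_single_snp_equals_allele_frequency(self):
        g = m.GenotypeTable(
            [f"s{i}" for i in range(6)],
            [m.SNPDef("x", "A", "a")],
            np.array([[1], [2], [2], [3], [1], [2]], float),
        )
        hs = m.em_haplotype_frequencies(g)
        assert hs.haplotypes == [(0,), (1,)]
        assert hs.freqs[1] == pytest.approx(5 / 12)

    def test_fully_phased_equals_direct_counts(self):
        # doubly homozygous individuals: no phase ambiguity at all
        codes = np.array([[1, 1], [1, 1], [3, 3], [1, 3], [3, 1]], float)
        g = m.GenotypeTable(
            [f"s{i}" for i in range(5)],
            [m.SNPDef("x", "A", "a"), m.SNPDef("y", "B", "b")],
            codes,
        )
        hs = m.em_haplotype_frequencies(g)
        freqs = dict(zip(hs.haplotypes, hs.freqs))
        assert freqs[(0, 0)] == pytest.approx(4 / 10)
        assert freqs[(1, 1)] == pytest.approx(2 / 10)
        assert freqs[(0, 1)] == pytest.approx(2 / 10)
        assert freqs[(1, 0)] == pytest.approx(2 / 10)

    def test_matches_grid_likelihood_maximizer(self):
        truth = {(0, 0): 0.5, (0, 1): 0.3, (1, 0): 0.15, (1, 1): 0.05}
        table = _two_snp_table(truth, n=50, seed=11)
        hs = m.em_haplotype_frequencies(table, tol=1e-12)
        em = dict(zip(hs.haplotypes, hs.freqs))
        grid = _grid_maximizer(table)
        for hap, f in grid.items():
            assert em.get(hap, 0.0) == pytest.approx(f, abs=2e-4)

    def test_invariant_to_sample_and_column_order(self, rng):
        truth = {(0, 0): 0.4, (0, 1): 0.25, (1, 0): 0.2, (1, 1): 0.15}
        table = _two_snp_table(truth, n=80, seed=3)
        hs = m.em_haplotype_frequencies(table)

        order = rng.permutation(len(table.samples))
        shuffled = m.GenotypeTable(
            [table.samples[i] for i in order], table.snps, table.codes[order]
        )
        hs_shuffled = m.em_haplotype_frequencies(shuffled)
        np.testing.assert_allclose(hs.freqs, hs_shuffled.freqs, atol=1e-9)

        flipped = m.GenotypeTable(
            table.samples, table.snps[::-1], table.codes[:, ::-1]
        )
        hs_flipped = m.em_haplotype_frequencies(flipped)
        relabeled = {h[::-1]: f for h, f in zip(hs_flipped.haplotypes, hs_flipped.freqs)}
        for hap, f in zip(hs.haplotypes, hs.freqs):
            assert relabeled[hap] == pytest.approx(f, abs=1e-9)

    def test_missing_dropped_listwise(self):
        codes = np.array([[1, 2], [np.nan, 2], [3, 3]])
        g = m.GenotypeTable(
            ["a", "b", "c"], [m.SNPDef("x", "A", "a"), m.SNPDef("y", "B", "b")], codes
        )
        hs = m.em_haplotype_frequencies(g)
        assert hs.samples == ["a", "c"]

    def test_loglik_monotone_under_random_data(self, rng):
        # the internal per-iteration assertion would fail on any decrease
        for seed in range(5):
            truth = rng.dirichlet(np.ones(4))
            table = _two_snp_table(
                dict(zip([(0, 0), (0, 1), (1, 0), (1, 1)], truth)), n=40, seed=seed
            )
            hs = m.em_haplotype_frequencies(table)
            assert np.isfinite(hs.loglik)


def _planted_haplotype_cohort(n0, n1, freqs, target_hap, or_, seed):
    """Retrospective draw of haplotype pairs: level 1 tilted by OR per copy
    of the target haplotype."""
    rng = np.random.default_rng(seed)
    haps = list(freqs)
    base = np.outer(list(freqs.values()), list(freqs.values())).ravel()
    dose = np.array(
        [(haps[i] == target_hap) + (haps[j] == target_hap)
         for i in range(len(haps)) for j in range(len(haps))]
    )
    tilted = base * or_ ** dose
    tilted /= tilted.sum()
    idx0 = rng.choice(len(base), size=n0, p=base / base.sum())
    idx1 = rng.choice(len(base), size=n1, p=tilted)
    L = len(target_hap)

    def codes_for(flat_idx):
        i, j = divmod(flat_idx, len(haps))
        return [1 + haps[i][k] + haps[j][k] for k in range(L)]

    codes = np.array([codes_for(i) for i in np.concatenate([idx0, idx1])], float)
    snps = [m.SNPDef(f"snp{k}", "A", "B") for k in range(L)]
    samples = [f"s{i}" for i in range(n0 + n1)]
    g = m.GenotypeTable(samples, snps, codes)
    p = m.PhenotypeTable(
        pd.DataFrame({"status": [0] * n0 + [1] * n1}, index=samples)
    )
    return m.Cohort(g, p)


class TestHaploGLM:
    def test_single_snp_equals_log_additive_logistic(self):
        cfg = m.SimulationConfig(
            seed=5, effects=(m.GenotypeEffect("rs486055", "log_additive", 2.0),)
        )
        cohort = m.simulate_cohort(cfg)
        one = m.GenotypeTable(
            cohort.samples, [cohort.genotypes.snps[1]], cohort.genotypes.codes[:, [1]]
        )
        c1 = m.Cohort(one, cohort.phenotypes)
        glm = m.haplo_glm(c1, outcome="status")
        logit = m.logistic_association(c1, "rs486055", "status", "log_additive")[0]
        assert glm.table.iloc[0]["or"] == pytest.approx(logit.or_, abs=1e-6)

    def test_zero_ambiguity_equals_known_dose_logistic(self):
        # doubly homozygous individuals only: posteriors are degenerate and
        # each person carries exactly two copies of one known haplotype
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        codes = rng.choice([1.0, 3.0], size=(120, 2))
        snps = [m.SNPDef("x", "A", "a"), m.SNPDef("y", "B", "b")]
        samples = [f"s{i}" for i in range(120)]
        dose_11 = ((codes[:, 0] == 3) & (codes[:, 1] == 3)).astype(float) * 2
        logits = -0.5 + 0.8 * dose_11
        y = (rng.random(120) < 1 / (1 + np.exp(-logits))).astype(int)
        c = m.Cohort(
            m.GenotypeTable(samples, snps, codes),
            m.PhenotypeTable(pd.DataFrame({"status": y}, index=samples)),
        )
        hs = m.em_haplotype_frequencies(c.genotypes)
        glm = m.haplo_glm(c, hs, rare_threshold=0.0)

        ref = hs.haplotypes[int(np.argmax(hs.freqs))]
        others = [h for h in hs.haplotypes if h != ref]
        dose_cols = [
            2.0 * ((codes[:, 0] == 1 + 2 * h[0]) & (codes[:, 1] == 1 + 2 * h[1]))
            for h in others
        ]
        direct = sm.Logit(y, np.column_stack([np.ones(120)] + dose_cols)).fit(disp=0)
        labels = dict(zip(hs.haplotypes, hs.labels(snps)))
        table_ors = glm.table.set_index("haplotype")["or"]
        for h, beta in zip(others, direct.params[1:]):
            assert table_ors[labels[h]] == pytest.approx(np.exp(beta), rel=1e-4)

    def test_planted_or_recovered(self):
        freqs = {(0, 0): 0.45, (0, 1): 0.25, (1, 0): 0.2, (1, 1): 0.1}
        estimates = []
        for seed in range(8):
            cohort = _planted_haplotype_cohort(
                1000, 1000, freqs, target_hap=(1, 0), or_=2.0, seed=seed
            )
            glm = m.haplo_glm(cohort)
            target = glm.table[glm.table["haplotype"] == "B-A"]
            estimates.append(float(target["or"].iloc[0]))
        median = float(np.median(estimates))
        assert 2.0 * 0.85 <= median <= 2.0 * 1.15

    def test_null_type_one_error(self):
        """Wald tests on outcome-independent haplotypes reject at about the
        nominal 5% level (all non-reference haplotypes pooled)."""
        freqs = {(0, 0): 0.5, (0, 1): 0.2, (1, 0): 0.2, (1, 1): 0.1}
        rejections = total = 0
        for seed in range(80):
            cohort = _planted_haplotype_cohort(
                150, 150, freqs, target_hap=(1, 1), or_=1.0, seed=100 + seed
            )
            glm = m.haplo_glm(cohort, rare_threshold=0.05)
            for p in glm.table["p"].dropna():
                total += 1
                rejections += p < 0.05
        # 240 weakly dependent tests: binomial(240, 0.05) 3-sigma band
        assert 0.005 <= rejections / total <= 0.115

    def test_all_reference_flagged(self):
        codes = np.ones((10, 1))
        g = m.GenotypeTable([f"s{i}" for i in range(10)], [m.SNPDef("x", "A", "a")], codes)
        p = m.PhenotypeTable(
            pd.DataFrame({"status": [0, 1] * 5}, index=g.samples)
        )
        res = m.haplo_glm(m.Cohort(g, p))
        assert "all_reference" in res.flags
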