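"""Synthetic cohort generation with the statistical structure of the study.

The generator emulates the study conditions: 160 cases / 136 controls, the
three-SNP MMP panel with control-group allele frequencies taken from the
published count tables, Hardy-Weinberg genotype proportions, group-specific
age and body-mass distributions, and binary injury sub-phenotypes at the
published prevalences.  Genetic effects are planted retrospectively: controls
are drawn from the Hardy-Weinberg joint genotype distribution and cases from
that distribution tilted by exp(beta * encoding), which is exactly the
case-control sampling a logistic disease model induces.

Everything is driven by one mandatory seed; a fixed seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import study
from .assoc import encode_model
from .io import Cohort, GenotypeTable, PhenotypeTable, SNPDef


@dataclass(frozen=True)
class GenotypeEffect:
    """A planted per-SNP genotype odds ratio under a genetic-model encoding."""

    snp_id: str
    model: str
    or_: float
    outcome: str = "status"


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults reproduce the study conditions: group sizes, control-group
    frequencies of the declared minor alleles, group covariate moments, and
    the sub-phenotype prevalences implied by the within-case table margins.
    ``minor_allele_freqs`` are frequencies of the declared minor allele (the
    rs1799750 I allele is the majority allele in controls, so its value
    exceeds 0.5).  SNPs are independent unless ``haplotype_freqs`` supplies a
    joint distribution.  Covariate effects on the outcome default to zero:
    the groups then differ in covariates without confounding the genetics.
    """

    n_cases: int = study.N_CASES
    n_controls: int = study.N_CONTROLS
    snps: tuple[SNPDef, ...] = study.SNPS
    minor_allele_freqs: dict = field(
        default_factory=lambda: {
            s.id: study.control_minor_allele_freq(s.id) for s in study.SNPS
        }
    )
    haplotype_freqs: dict | None = None  # haplotype tuple -> probability
    effects: tuple[GenotypeEffect, ...] = ()
    covariates: dict = field(
        default_factory=lambda: {
            "age": {0: study.DEMOGRAPHICS["age"]["controls"],
                    1: study.DEMOGRAPHICS["age"]["cases"]},
            "body_mass": {0: study.DEMOGRAPHICS["body_mass"]["controls"],
                          1: study.DEMOGRAPHICS["body_mass"]["cases"]},
        }
    )
    subtype_prevalence: dict = field(
        default_factory=lambda: dict(study.SUBTYPE_PREVALENCE)
    )
    subtype_effects: tuple[GenotypeEffect, ...] = ()
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("simulation seed is mandatory")
        for f in self.minor_allele_freqs.values():
            if not 0 <= f <= 1:
                raise ValueError("allele frequencies must be in [0, 1]")
        for prev in self.subtype_prevalence.values():
            if not 0 <= prev <= 1:
                raise ValueError("subtype prevalences must be in [0, 1]")
        if self.haplotype_freqs is not None:
            total = sum(self.haplotype_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("haplotype frequencies must sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")


def simulate_genotypes(
    n: int, maf: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw n genotype codes from Hardy-Weinberg proportions at allele
    frequency ``maf`` (maf -> 0 gives all code 1; maf -> 1 all code 3)."""
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = 1.0 - maf
    probs = np.array([p * p, 2 * p * maf, maf * maf])
    return rng.choice(np.array([1.0, 2.0, 3.0]), size=n, p=probs)


def _joint_genotype_distribution(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all joint genotype code vectors and their probabilities."""
    L = len(cfg.snps)
    combos = np.array(list(itertools.product((1, 2, 3), repeat=L)), dtype=float)
    if cfg.haplotype_freqs is not None:
        probs = np.zeros(len(combos))
        haps = list(cfg.haplotype_freqs)
        for (h1, f1), (h2, f2) in itertools.product(
            cfg.haplotype_freqs.items(), repeat=2
        ):
            codes = tuple(1 + a + b for a, b in zip(h1, h2))
            probs[_combo_index(codes, L)] += f1 * f2
    else:
        probs = np.ones(len(combos))
        for j, snp in enumerate(cfg.snps):
            q = cfg.minor_allele_freqs[snp.id]
            p = 1.0 - q
            per = {1: p * p, 2: 2 * p * q, 3: q * q}
            probs *= np.array([per[int(c)] for c in combos[:, j]])
    return combos, probs / probs.sum()


def _combo_index(codes: tuple[int, ...], L: int) -> int:
    idx = 0
    for c in codes:
        idx = idx * 3 + (int(c) - 1)
    return idx


def _tilt(
    combos: np.ndarray,
    probs: np.ndarray,
    effects: tuple[GenotypeEffect, ...],
    snps: tuple[SNPDef, ...],
    expression: Callable[[np.ndarray], np.ndarray] | None = None,
    expression_or: float = 1.0,
) -> np.ndarray:
    """Case-group genotype distribution: controls' tilted by exp(beta * x)."""
    snp_ids = [s.id for s in snps]
    weight = np.ones(len(combos))
    for eff in effects:
        x = encode_model(combos[:, snp_ids.index(eff.snp_id)], eff.model)
        weight *= eff.or_ ** x
    if expression is not None:
        carrier = np.asarray(expression(combos), dtype=float)
        weight *= expression_or ** carrier
    tilted = probs * weight
    return tilted / tilted.sum()


def simulate_case_control_genotypes(
    n_level0: int,
    n_level1: int,
    cfg: SimulationConfig,
    effects: tuple[GenotypeEffect, ...] = (),
    rng: np.random.Generator | None = None,
    expression: Callable[[np.ndarray], np.ndarray] | None = None,
    expression_or: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective draw: level-0 rows from the base joint genotype
    distribution, level-1 rows from the effect-tilted one.  Returns
    (codes matrix ordered level-0 then level-1, outcome vector)."""
    rng = rng or np.random.default_rng(cfg.seed)
    combos, probs = _joint_genotype_distribution(cfg)
    case_probs = _tilt(combos, probs, effects, cfg.snps, expression, expression_or)
    idx0 = rng.choice(len(combos), size=n_level0, p=probs)
    idx1 = rng.choice(len(combos), size=n_level1, p=case_probs)
    codes = np.vstack([combos[idx0], combos[idx1]])
    y = np.concatenate([np.zeros(n_level0, dtype=int), np.ones(n_level1, dtype=int)])
    return codes, y


def simulate_cohort(
    cfg: SimulationConfig,
    expression: Callable[[np.ndarray], np.ndarray] | None = None,
    expression_or: float = 1.0,
) -> Cohort:
    """Generate a full cohort: genotypes, case status, covariates, subtypes.

    Case/control genotypes are drawn retrospectively (fixed group sizes) from
    the configured joint distribution, with cases tilted by the configured
    status effects and, optionally, a planted Boolean ``expression`` over the
    genotype code vectors with odds ratio ``expression_or``.  Subtypes are
    assigned among cases as Bernoulli draws whose log-odds shift with any
    configured subtype effects.
    """
    rng = np.random.default_rng(cfg.seed)
    status_effects = tuple(e for e in cfg.effects if e.outcome == "status")
    codes, status = simulate_case_control_genotypes(
        cfg.n_controls, cfg.n_cases, cfg, status_effects, rng,
        expression, expression_or,
    )
    if expression is not None:
        carrier = np.asarray(expression(codes), dtype=bool)
        if carrier.all() or not carrier.any():
            warnings.warn("planted expression is constant in this draw")

    n = len(status)
    samples = [f"S{i:04d}" for i in range(n)]
    pheno = pd.DataFrame({"status": status}, index=samples)
    for cov, moments in cfg.covariates.items():
        values = np.empty(n)
        for level, (mean, sd) in moments.items():
            mask = status == level
            values[mask] = rng.normal(mean, sd, mask.sum())
        pheno[cov] = values

    snp_ids = [s.id for s in cfg.snps]
    case_mask = status == 1
    for subtype, prev in cfg.subtype_prevalence.items():
        base_logit = np.log(prev / (1 - prev)) if 0 < prev < 1 else np.inf
        logits = np.full(n, base_logit)
        for eff in cfg.subtype_effects:
            if eff.outcome != subtype:
                continue
            x = encode_model(codes[:, snp_ids.index(eff.snp_id)], eff.model)
            logits = logits + np.log(eff.or_) * x
        prob = 1.0 / (1.0 + np.exp(-logits))
        draw = (rng.random(n) < prob).astype(float)
        draw[~case_mask] = np.nan
        pheno[subtype] = draw

    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes = codes.copy()
        codes[mask] = np.nan

    genotypes = GenotypeTable(samples, list(cfg.snps), codes)
    phenotypes = PhenotypeTable(pheno)
    return Cohort(genotypes, phenotypes)


def plant_logic_interaction(
    cfg: SimulationConfig,
    expression: Callable[[np.ndarray], np.ndarray],
    or_: float,
) -> Cohort:
    """Cohort whose case status is tilted by ln(or_) for carriers of a
    Boolean expression over the genotype code vectors.

    ``expression`` receives an (m, n_snps) code matrix and returns a boolean
    carrier vector; ``or_ = 1`` reduces to the null cohort.
    """
    return simulate_cohort(cfg, expression=expression, expression_or=or_)
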