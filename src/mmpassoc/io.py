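"""Data model and readers/writers for genotype-phenotype cohorts.

Genotypes are stored as numeric codes relative to a declared minor allele:
1 = homozygous major, 2 = heterozygous, 3 = homozygous minor, NaN = missing.
Phenotypes carry a binary case/control ``status``, optional binary injury
sub-phenotypes that are defined only for cases, and the age / body-mass
covariates used for adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SUBTYPE_COLUMNS = ("ACLF", "ACLS", "ACLRP", "ACLRC")


class ValidationError(ValueError):
    """Input violates the cohort data model."""


class ParseError(ValueError):
    """Malformed input file; message carries the offending line."""


@dataclass(frozen=True)
class SNPDef:
    """A biallelic locus with its declared major (reference) and minor allele."""

    id: str
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("SNP id must be non-empty")
        if self.major_allele == self.minor_allele:
            raise ValidationError(
                f"{self.id}: major and minor allele must differ"
            )

    def code_from_alleles(self, a1: str, a2: str) -> int:
        """Map an unordered allele pair to the 1/2/3 code."""
        pair = {a1, a2}
        if not pair <= {self.major_allele, self.minor_allele}:
            bad = pair - {self.major_allele, self.minor_allele}
            raise ValidationError(
                f"{self.id}: allele(s) {sorted(bad)} not in "
                f"{{{self.major_allele}, {self.minor_allele}}}"
            )
        n_minor = (a1 == self.minor_allele) + (a2 == self.minor_allele)
        return 1 + n_minor

    def alleles_from_code(self, code: int) -> str:
        n_minor = int(code) - 1
        return "/".join(
            [self.major_allele] * (2 - n_minor) + [self.minor_allele] * n_minor
        )

    def genotype_labels(self) -> tuple[str, str, str]:
        return tuple(self.alleles_from_code(c) for c in (1, 2, 3))


@dataclass
class GenotypeTable:
    """Per-sample genotype codes over a SNP panel.

    ``codes`` is an (n_samples, n_snps) float array with values in
    {1, 2, 3, NaN}; rows follow ``samples`` and columns follow ``snps``.
    """

    samples: list[str]
    snps: list[SNPDef]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise ValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids in genotype table")
        if len({s.id for s in self.snps}) != len(self.snps):
            raise ValidationError("duplicate SNP ids in panel")
        valid = np.isnan(self.codes) | np.isin(self.codes, (1.0, 2.0, 3.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValidationError(
                f"invalid genotype code {self.codes[tuple(bad)]} for sample "
                f"{self.samples[bad[0]]}, SNP {self.snps[bad[1]].id}"
            )

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp(self, snp_id: str) -> SNPDef:
        for s in self.snps:
            if s.id == snp_id:
                return s
        raise KeyError(f"SNP {snp_id!r} not in panel {self.snp_ids}")

    def column(self, snp_id: str) -> np.ndarray:
        return self.codes[:, self.snp_ids.index(snp_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.samples, columns=self.snp_ids)


@dataclass
class PhenotypeTable:
    """Binary outcome, optional sub-phenotypes, and covariates per sample.

    Sub-phenotype labels are defined only for cases (controls, who have no
    previous injury, carry NaN there).
    """

    data: pd.DataFrame  # index = sample id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in phenotype table")
        if "status" not in df.columns:
            raise ValidationError("phenotype table must have a 'status' column")
        status = df["status"]
        if not status.isin((0, 1)).all():
            bad = status[~status.isin((0, 1))]
            raise ValidationError(
                f"status must be 0/1; offending value(s) {bad.unique()[:3]}"
            )
        for col in SUBTYPE_COLUMNS:
            if col not in df.columns:
                continue
            sub = df[col]
            if not sub.dropna().isin((0, 1)).all():
                raise ValidationError(f"{col} must be binary where present")
            on_controls = sub.notna() & (status == 0)
            if on_controls.any():
                raise ValidationError(
                    f"{col} label set on control sample(s) "
                    f"{list(df.index[on_controls][:3])}; sub-phenotypes are "
                    "defined only for cases"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def status(self) -> pd.Series:
        return self.data["status"]

    @property
    def subtypes(self) -> list[str]:
        return [
            c for c in SUBTYPE_COLUMNS
            if c in self.data.columns and self.data[c].notna().any()
        ]


@dataclass
class Cohort:
    """Genotypes and phenotypes joined on sample id (the analysis unit)."""

    genotypes: GenotypeTable
    phenotypes: PhenotypeTable
    n_dropped_genotype_only: int = 0
    n_dropped_phenotype_only: int = 0

    def __post_init__(self) -> None:
        if self.genotypes.samples != self.phenotypes.samples:
            raise ValidationError("cohort sample ids are not aligned")

    @property
    def samples(self) -> list[str]:
        return self.genotypes.samples

    @property
    def n(self) -> int:
        return len(self.samples)

    def frame(self) -> pd.DataFrame:
        """Joined per-sample view: genotype codes + phenotype columns."""
        return pd.concat([self.genotypes.to_frame(), self.phenotypes.data], axis=1)

    def outcome(self, label: str) -> pd.Series:
        """Binary outcome vector: 'status' over everyone, or a sub-phenotype
        over cases only (controls excluded)."""
        if label == "status":
            return self.phenotypes.status
        if label not in self.phenotypes.data.columns:
            raise ValidationError(f"outcome {label!r} not in phenotype table")
        sub = self.phenotypes.data[label]
        sub = sub[self.phenotypes.status == 1].dropna()
        if sub.empty:
            raise ValidationError(f"outcome {label!r} has no defined samples")
        return sub


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def load_genotypes(
    path: str | Path,
    snps: list[SNPDef],
    format: str = "delimited",
) -> GenotypeTable:
    """Read genotypes into the 1/2/3 coding relative to each declared minor allele.

    Delimited dialect: one row per sample, a ``sample`` column, one column per
    SNP id with alleles separated by "/" (empty/NA = missing).  VCF genotypes
    are mapped through REF/ALT against the declared alleles, never by
    frequency.
    """
    if format == "delimited":
        return _load_genotypes_delimited(path, snps)
    if format == "vcf":
        return _load_genotypes_vcf(path, snps)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_genotypes_delimited(path: str | Path, snps: list[SNPDef]) -> GenotypeTable:
    df = _read_delimited(path)
    if "sample" not in df.columns:
        raise ParseError(f"{path}: genotype file must have a 'sample' column")
    missing_cols = [s.id for s in snps if s.id not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing SNP column(s) {missing_cols}")
    samples = df["sample"].tolist()
    codes = np.full((len(samples), len(snps)), np.nan)
    for j, snp in enumerate(snps):
        for i, cell in enumerate(df[snp.id]):
            if pd.isna(cell) or cell == "" or cell.upper() in ("NA", "./."):
                continue
            parts = cell.split("/")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}, line {i + 2}: malformed genotype {cell!r} "
                    f"for {snp.id} (expected 'X/Y')"
                )
            codes[i, j] = snp.code_from_alleles(*parts)
    return GenotypeTable(samples, list(snps), codes)


def _load_genotypes_vcf(path: str | Path, snps: list[SNPDef]) -> GenotypeTable:
    from cyvcf2 import VCF

    panel = {s.id: s for s in snps}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    codes = np.full((len(samples), len(snps)), np.nan)
    order = [s.id for s in snps]
    seen = set()
    for variant in vcf:
        snp = panel.get(variant.ID)
        if snp is None:
            continue
        if len(variant.ALT) != 1:
            raise ValidationError(f"{variant.ID}: multi-allelic sites unsupported")
        ref, alt = variant.REF, variant.ALT[0]
        if {ref, alt} != {snp.major_allele, snp.minor_allele}:
            raise ValidationError(
                f"{variant.ID}: VCF alleles {ref}/{alt} do not match declared "
                f"{snp.major_allele}/{snp.minor_allele}"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        alt_is_minor = alt == snp.minor_allele
        col = order.index(snp.id)
        for i, gt in enumerate(variant.gt_types):
            if gt == 2:
                continue
            n_alt = {0: 0, 1: 1, 3: 2}[gt]
            n_minor = n_alt if alt_is_minor else 2 - n_alt
            codes[i, col] = 1 + n_minor
        seen.add(snp.id)
    vcf.close()
    absent = set(panel) - seen
    if absent:
        warnings.warn(f"panel SNP(s) absent from VCF: {sorted(absent)}")
    return GenotypeTable(samples, list(snps), codes)


def write_genotypes(g: GenotypeTable, path: str | Path, sep: str = "\t") -> None:
    """Write the delimited allele-pair dialect (round-trips with load_genotypes)."""
    rows = []
    for i, sample in enumerate(g.samples):
        row = {"sample": sample}
        for j, snp in enumerate(g.snps):
            c = g.codes[i, j]
            row[snp.id] = "" if np.isnan(c) else snp.alleles_from_code(int(c))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_delimited(path)
    if "sample" not in df.columns:
        raise ParseError(f"{path}: phenotype file must have a 'sample' column")
    df = df.set_index("sample")
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path: str | Path, sep: str = "\t") -> None:
    p.data.to_csv(path, sep=sep, index=True, index_label="sample")


def join_cohort(g: GenotypeTable, p: PhenotypeTable) -> Cohort:
    """Inner join on sample id; drop counts are reported on the Cohort."""
    g_ids, p_ids = set(g.samples), set(p.samples)
    common = sorted(g_ids & p_ids)
    if not common:
        raise ValidationError("no overlapping sample ids between tables")
    g_idx = [g.samples.index(s) for s in common]
    g_joined = GenotypeTable(common, g.snps, g.codes[g_idx])
    p_joined = PhenotypeTable(p.data.loc[common])
    return Cohort(
        g_joined,
        p_joined,
        n_dropped_genotype_only=len(g_ids - p_ids),
        n_dropped_phenotype_only=len(p_ids - g_ids),
    )


# ---------------------------------------------------------------------------
# Descriptive operations
# ---------------------------------------------------------------------------

def genotype_counts(c: Cohort, snp_id: str, stratum: str = "status") -> pd.DataFrame:
    """2x3 genotype count table (outcome level 0/1 x codes 1/2/3).

    Missing genotypes are excluded per SNP (complete-case per locus), so row
    totals can differ between SNPs.
    """
    y = c.outcome(stratum)
    codes = pd.Series(c.genotypes.column(snp_id), index=c.samples).loc[y.index]
    mask = codes.notna()
    if not mask.any():
        raise ValidationError(f"{snp_id}: all genotypes missing in stratum {stratum}")
    codes, y = codes[mask], y[mask]
    labels = c.genotypes.snp(snp_id).genotype_labels()
    table = pd.DataFrame(0, index=[0, 1], columns=list(labels))
    for level in (0, 1):
        sub = codes[y == level]
        for k, lab in enumerate(labels, start=1):
            table.loc[level, lab] = int((sub == k).sum())
    return table


def demographics_compare(
    c: Cohort,
    continuous: tuple[str, ...] = ("age", "body_mass"),
    categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-variable group comparison: Wilcoxon rank-sum for continuous
    variables, Fisher's exact test for categorical ones."""
    status = c.phenotypes.status
    rows = []
    for var in continuous:
        x = c.phenotypes.data[var]
        g0, g1 = x[status == 0].dropna(), x[status == 1].dropna()
        if len(g0) < 2 or len(g1) < 2:
            raise ValidationError(f"{var}: need >=2 samples per group")
        if x.dropna().nunique() == 1:
            warnings.warn(f"{var} is constant; p reported as 1")
            stat, p = np.nan, 1.0
        else:
            res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "variable": var,
                "test": "wilcoxon_rank_sum",
                "control_mean": g0.mean(),
                "control_sd": g0.std(ddof=1),
                "case_mean": g1.mean(),
                "case_sd": g1.std(ddof=1),
                "statistic": stat,
                "p": p,
            }
        )
    for var in categorical:
        x = c.phenotypes.data[var]
        tab = pd.crosstab(status, x)
        if tab.shape != (2, 2):
            warnings.warn(f"{var}: not a 2x2 comparison; p reported as 1")
            p = 1.0
        else:
            p = float(stats.fisher_exact(tab.values)[1])
        rows.append(
            {"variable": var, "test": "fisher_exact", "statistic": np.nan, "p": p}
        )
    return pd.DataFrame(rows)


def rank_sum_statistic(g1: np.ndarray, g0: np.ndarray) -> float:
    """Rank-sum W of group 1 in the pooled mid-rank ordering (the classic
    Wilcoxon statistic; equals Mann-Whitney U + n1(n1+1)/2)."""
    pooled = np.concatenate([g1, g0])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(g1)].sum())
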