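"""Genotype-phenotype association and Hardy-Weinberg phenotype prediction.

Works on a 2 phenotypes x 3 genotypes count table (rows: non-melanistic,
melanistic; columns: ancestral homozygote, heterozygote, derived
homozygote). The chi-square statistic is uncorrected Pearson on a 2x2
collapse chosen by the inheritance mode: under a recessive model the
derived homozygotes are contrasted with everyone else, under a dominant
model the carriers are. For a perfectly associated table (both discordant
cells zero) the statistic equals the total sample size n.

All computation is carried at full precision; rounding to the two decimals
used in reports happens only in :func:`render_frequency`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hapio import CoreVariant, HaplotypeMatrix, SampleMeta, PHENOTYPES

GENOTYPE_LABELS = ("hom_ancestral", "het", "hom_derived")
COLLAPSES = ("hom_derived_vs_rest", "carrier_vs_noncarrier")


@dataclass
class GenotypeCountTable:
    """Phenotype x genotype counts; rows (non_melanistic, melanistic),
    columns (hom_ancestral, het, hom_derived)."""

    counts: np.ndarray
    species: str = ""
    variant: CoreVariant | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 3):
            raise ValueError(
                f"counts must be 2 phenotypes x 3 genotypes, got "
                f"{self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("count table is empty")

    @property
    def n_individuals(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AssociationResult:
    chi2: float
    dof: int
    collapse_rule: str

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.chi2, self.dof))


def derived_allele_frequency(table: GenotypeCountTable) -> float:
    """Derived (melanism) allele frequency q = (2 hom_der + het) / 2n."""
    n = table.n_individuals
    het = int(table.counts[:, 1].sum())
    hom_der = int(table.counts[:, 2].sum())
    return (2 * hom_der + het) / (2 * n)


def predicted_phenotype_frequency(q: float, mode: str) -> float:
    """Hardy-Weinberg phenotype frequency from derived allele frequency q:
    q^2 for a recessive trait, 1 - (1 - q)^2 for a dominant one."""
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"allele frequency must be in [0, 1], got {q}")
    if mode == "recessive":
        return q * q
    if mode == "dominant":
        return 1.0 - (1.0 - q) ** 2
    raise ValueError(f"mode must be recessive or dominant, got {mode!r}")


def _collapse_2x2(table: GenotypeCountTable, collapse: str) -> np.ndarray:
    c = table.counts
    if collapse == "hom_derived_vs_rest":
        grouped = np.column_stack([c[:, 2], c[:, 0] + c[:, 1]])
    elif collapse == "carrier_vs_noncarrier":
        grouped = np.column_stack([c[:, 1] + c[:, 2], c[:, 0]])
    else:
        raise ValueError(f"collapse must be one of {COLLAPSES}, got {collapse!r}")
    return grouped


def association_chi2(table: GenotypeCountTable, collapse: str) -> AssociationResult:
    """Uncorrected Pearson chi-square on the collapsed 2x2 table (dof = 1)."""
    grouped = _collapse_2x2(table, collapse)
    if (grouped.sum(axis=0) == 0).any() or (grouped.sum(axis=1) == 0).any():
        raise ValueError(
            f"degenerate table: a margin of the collapsed 2x2 is zero "
            f"({grouped.tolist()})"
        )
    chi2, _, dof, _ = stats.chi2_contingency(grouped, correction=False)
    return AssociationResult(float(chi2), int(dof), collapse)


def genotype_table_from_calls(
    hap: HaplotypeMatrix,
    core: CoreVariant,
    meta: list[SampleMeta],
    species: str = "",
) -> GenotypeCountTable:
    """Tally per-individual derived-allele dosage at the core site against
    phenotype labels."""
    j = hap.site_index(core.chrom, core.pos)
    pheno = {m.sample_id: m.phenotype for m in meta}
    col = hap.data[:, j]
    counts = np.zeros((2, 3), dtype=np.int64)
    if hap.n_chrom % 2:
        raise ValueError("matrix has an odd number of chromosomes")
    for i in range(0, hap.n_chrom, 2):
        sample = hap.sample_of(hap.chrom_ids[i])
        if hap.sample_of(hap.chrom_ids[i + 1]) != sample:
            raise ValueError(f"rows {i},{i + 1} are not one sample's pair")
        if sample not in pheno:
            raise ValueError(f"sample {sample} missing from metadata")
        dosage = int(col[i] == core.derived_allele_code) + int(
            col[i + 1] == core.derived_allele_code
        )
        row = PHENOTYPES.index(pheno[sample])
        counts[row, dosage] += 1
    return GenotypeCountTable(counts, species=species, variant=core)


def render_frequency(x: float) -> str:
    """Report-layer rendering of a proportion to two decimals."""
    return f"{x:.2f}"
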