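"""End-to-end sweep scan: classify -> diversity -> EHH -> association.

`run_scan` composes the library modules over one phased VCF + metadata +
window set + core-variant spec, writes every table/JSON output to the
configured directory, and is deterministic: identical inputs and config
produce byte-identical outputs (a config hash is recorded in the run log
so any table can be traced to the exact configuration that produced it).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import (
    association_chi2,
    derived_allele_frequency,
    genotype_table_from_calls,
    predicted_phenotype_frequency,
    render_frequency,
)
from .divstats import (
    ChromosomeClassing,
    diversity_profile,
    haplotype_count,
)
from .ehh import bifurcation_tree, ehh_curve, ehh_table
from .hapio import (
    CoreVariant,
    HaplotypeMatrix,
    SampleMeta,
    read_metadata,
    read_phased_vcf,
    read_windows,
)

_FLOAT_FMT = "%.10g"


def classify(
    hap: HaplotypeMatrix, core: CoreVariant, meta: list[SampleMeta]
) -> ChromosomeClassing:
    """Label every chromosome by its core allele and every individual by
    phenotype, and list genotype/phenotype inconsistencies under the core
    variant's inheritance mode (violations are reported, never dropped)."""
    j = hap.site_index(core.chrom, core.pos)
    col = hap.data[:, j]
    chrom_class = {
        cid: ("derived" if col[i] == core.derived_allele_code else "ancestral")
        for i, cid in enumerate(hap.chrom_ids)
    }
    pheno = {m.sample_id: m.phenotype for m in meta}
    for cid in hap.chrom_ids:
        s = hap.sample_of(cid)
        if s not in pheno:
            raise ValueError(f"sample {s} missing from metadata")
    individual_class = {s: pheno[s] for s in hap.sample_ids}

    violations: list[str] = []
    for i in range(0, hap.n_chrom, 2):
        sample = hap.sample_of(hap.chrom_ids[i])
        dosage = int(col[i] == core.derived_allele_code) + int(
            col[i + 1] == core.derived_allele_code
        )
        observed = pheno[sample]
        if core.mode == "recessive":
            expected = "melanistic" if dosage == 2 else "non_melanistic"
        else:
            expected = "melanistic" if dosage >= 1 else "non_melanistic"
        if observed != expected:
            violations.append(
                f"{sample}: {observed} with derived dosage {dosage} under "
                f"{core.mode} model (expected {expected})"
            )
    return ChromosomeClassing(chrom_class, individual_class, violations)


@dataclass
class ScanConfig:
    vcf: str
    metadata: str
    windows: str
    core: CoreVariant
    out_dir: str
    denominator: str = "bp"
    bifurcation_max_sites: int = 30
    plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        core = raw.pop("core")
        if isinstance(core, str):
            core_v = CoreVariant.from_string(core)
        else:
            core_v = CoreVariant(**core)
        return cls(core=core_v, **raw)

    def canonical(self) -> dict:
        d = asdict(self)
        d["core"] = asdict(self.core)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScanReport:
    association: pd.DataFrame
    diversity_by_chromosome: pd.DataFrame
    diversity_by_individual: pd.DataFrame
    haplotype_counts: pd.DataFrame
    ehh: pd.DataFrame
    bifurcations: dict[str, dict]
    classification: pd.DataFrame
    violations: list[str]
    core_window: str | None
    config_hash: str
    paths: dict[str, Path] = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_scan(config: ScanConfig) -> ScanReport:
    """Run the full pipeline and write all outputs under ``config.out_dir``."""
    for label, p in (
        ("VCF", config.vcf),
        ("metadata", config.metadata),
        ("windows", config.windows),
    ):
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hap = read_phased_vcf(config.vcf)
    meta = read_metadata(config.metadata)
    windows = read_windows(config.windows)
    core = config.core

    classing = classify(hap, core, meta)

    # --- association (Table-1-style single-variant summary) ---------------
    species = meta[0].species if meta else ""
    table = genotype_table_from_calls(hap, core, meta, species=species)
    q = derived_allele_frequency(table)
    predicted = predicted_phenotype_frequency(q, core.mode)
    observed = table.counts[1].sum() / table.n_individuals
    collapse = (
        "hom_derived_vs_rest" if core.mode == "recessive"
        else "carrier_vs_noncarrier"
    )
    try:
        assoc_res = association_chi2(table, collapse)
        chi2, pval = assoc_res.chi2, assoc_res.p_value
    except ValueError:
        chi2, pval = float("nan"), float("nan")
    association = pd.DataFrame(
        [
            {
                "species": species,
                "variant": core.name or f"{core.chrom}:{core.pos}",
                "mode": core.mode,
                "n_individuals": table.n_individuals,
                "hom_ancestral_nonmel": table.counts[0, 0],
                "het_nonmel": table.counts[0, 1],
                "hom_derived_nonmel": table.counts[0, 2],
                "hom_ancestral_mel": table.counts[1, 0],
                "het_mel": table.counts[1, 1],
                "hom_derived_mel": table.counts[1, 2],
                "allele_frequency": q,
                "allele_frequency_2dp": render_frequency(q),
                "predicted_phenotype_frequency": predicted,
                "predicted_phenotype_frequency_2dp": render_frequency(predicted),
                "observed_phenotype_frequency": observed,
                "chi2": chi2,
                "p_value": pval,
                "collapse": collapse,
            }
        ]
    )

    # --- diversity ---------------------------------------------------------
    div_chrom = diversity_profile(
        hap, windows, classing, by="chromosome_class",
        denominator=config.denominator,
    )
    div_indiv = diversity_profile(
        hap, windows, classing, by="individual_class",
        denominator=config.denominator,
    )

    hap_counts = pd.DataFrame.from_records(
        [
            {
                "window": w.label,
                "class": cls,
                "n_chrom": int(rows.size),
                "n_haplotypes": (
                    haplotype_count(hap, w, rows) if rows.size else 0
                ),
            }
            for w in windows
            for cls, rows in (
                ("derived", classing.chromosomes_in(hap, "derived")),
                ("ancestral", classing.chromosomes_in(hap, "ancestral")),
            )
        ]
    )

    # --- EHH + bifurcation ---------------------------------------------------
    up, down = ehh_curve(hap, core)
    ehh_df = ehh_table(up, down)
    bifurcations = {
        f"{cls}_{direction}": bifurcation_tree(
            hap, core, cls, direction, max_sites=config.bifurcation_max_sites
        ).to_dict()
        for cls in ("derived", "ancestral")
        for direction in ("upstream", "downstream")
    }

    classification = pd.DataFrame(
        {
            "chrom_id": list(hap.chrom_ids),
            "chromosome_class": [
                classing.chromosome_class[c] for c in hap.chrom_ids
            ],
            "phenotype": [
                classing.individual_class[hap.sample_of(c)]
                for c in hap.chrom_ids
            ],
        }
    )

    # core-containing window with the minimum derived-class pi
    der = div_chrom[div_chrom["class"] == "derived"].dropna(subset=["pi"])
    core_window = None
    if not der.empty:
        core_window = str(der.loc[der["pi"].idxmin(), "window"])

    report = ScanReport(
        association=association,
        diversity_by_chromosome=div_chrom,
        diversity_by_individual=div_indiv,
        haplotype_counts=hap_counts,
        ehh=ehh_df,
        bifurcations=bifurcations,
        classification=classification,
        violations=classing.violations,
        core_window=core_window,
        config_hash=config.config_hash(),
    )

    # --- write -------------------------------------------------------------
    paths = {
        "association": out / "association.tsv",
        "diversity_by_chromosome": out / "diversity_by_chromosome.tsv",
        "diversity_by_individual": out / "diversity_by_individual.tsv",
        "haplotype_counts": out / "haplotype_counts.tsv",
        "ehh": out / "ehh.tsv",
        "classification": out / "classification.tsv",
        "run_log": out / "run.json",
    }
    _write_tsv(association, paths["association"])
    _write_tsv(div_chrom, paths["diversity_by_chromosome"])
    _write_tsv(div_indiv, paths["diversity_by_individual"])
    _write_tsv(hap_counts, paths["haplotype_counts"])
    _write_tsv(ehh_df, paths["ehh"])
    _write_tsv(classification, paths["classification"])
    for key, tree in bifurcations.items():
        p = out / f"bifurcation_{key}.json"
        p.write_text(json.dumps(tree, indent=1, sort_keys=True))
        paths[f"bifurcation_{key}"] = p
    paths["run_log"].write_text(
        json.dumps(
            {
                "sweepwatch_version": __version__,
                "config": config.canonical(),
                "config_hash": report.config_hash,
                "n_chromosomes": hap.n_chrom,
                "n_sites": hap.n_sites,
                "violations": report.violations,
                "min_derived_pi_window": report.core_window,
            },
            indent=1,
            sort_keys=True,
        )
    )
    report.paths = paths

    if config.plots:
        from . import plotting

        plotting.plot_diversity_profile(
            div_chrom, out / "diversity_by_chromosome.png"
        )
        plotting.plot_ehh(ehh_df, core, out / "ehh.png")
        from .ehh import BifurcationTree  # noqa: F401  (plot uses dicts)

        plotting.plot_bifurcation_pair(
            bifurcations["derived_upstream"],
            bifurcations["derived_downstream"],
            out / "bifurcation_derived.png",
        )
    return report
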