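"""Genotype-phenotype association and Hardy-Weinberg phenotype prediction.

Uses the published genotype counts for three melanistic wild cat
populations: pampas cat (ASIP R120C, recessive), kodkod (ASIP C126Y,
recessive) and Geoffroy's cat (MC1R C125R, dominant).
"""

from sweepwatch import GenotypeCountTable, derived_allele_frequency, predicted_phenotype_frequency
from sweepwatch.assoc import association_chi2, render_frequency

tables = {
    # rows: (non-melanistic, melanistic) x (hom ancestral, het, hom derived)
    "pampas cat (recessive)": (GenotypeCountTable([[2, 6, 0], [0, 0, 9]]), "recessive"),
    "kodkod (recessive)": (GenotypeCountTable([[5, 6, 0], [0, 0, 5]]), "recessive"),
    "Geoffroy's cat (dominant)": (GenotypeCountTable([[16, 0, 0], [0, 7, 0]]), "dominant"),
}

for name, (table, mode) in tables.items():
    q = derived_allele_frequency(table)
    pred = predicted_phenotype_frequency(q, mode)
    print(f"{name}: n={table.n_individuals}, melanism allele freq "
          f"{render_frequency(q)}, HWE-predicted melanism freq {render_frequency(pred)}")

# The association statistic uses the full genotyped panels (the pampas
# panel includes one extra animal of unknown origin that the frequency
# table above excludes).
pampas_full = GenotypeCountTable([[2, 6, 0], [0, 0, 10]])
res = association_chi2(pampas_full, "hom_derived_vs_rest")
print(f"pampas cat association: chi2={res.chi2:.0f} on {res.dof} df, "
      f"p={res.p_value:.4f}")
# A perfectly associated 2x2 (no discordant individuals) gives chi2 = n,
# here 18: melanism and ASIP R120C homozygosity never separate.
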