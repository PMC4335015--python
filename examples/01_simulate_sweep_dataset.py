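"""Simulate a founder-sweep haplotype panel and write it to disk.

Builds an 80-chromosome panel (40 ancestral mosaics, 40 chromosomes
descended from one sweep founder), pairs the chromosomes into diploid
individuals under a recessive model, and emits phased VCF + metadata TSV +
window BED + ground-truth JSON.
"""

from pathlib import Path

import sweepwatch as sw

out = Path("scratch/example_sweep")
params = sw.SweepSimParams(seed=1)
result = sw.emit_dataset(params, out, mode="recessive")

truth = result["truth_obj"]
print(f"wrote {result['vcf']}")
print(f"chromosomes: {result['matrix'].n_chrom}, sites: {result['matrix'].n_sites}")
print(f"founder chromosome index: {truth.founder_index}")
bl, br = truth.breakpoints[0]
print(f"first derived chromosome breakpoints: {bl:.0f} bp left, {br:.0f} bp right")
print(f"expected ancestral diversity: {sw.expected_pi_per_bp(params) * 100:.4f} %/bp")
# The breakpoints are the distances from the causal site out to which each
# derived chromosome still copies the founder haplotype; diversity inside
# that span is what the sweep scan detects as a reduction.
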