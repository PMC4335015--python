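# sweepwatch

Selective-sweep scan toolkit for phased haplotype panels from targeted
resequencing.

Population geneticists studying a candidate causal variant — here
motivated by melanism variants (*ASIP*, *MC1R*) segregating in small wild
felid populations, but applicable to any phased biallelic panel — need a
small set of haplotype statistics computed consistently around that site:

* **stratified nucleotide diversity** π per window, contrasting
  chromosomes that carry the derived (causal) allele with ancestral
  chromosomes, and melanistic with non-melanistic individuals;
* **extended haplotype homozygosity** (EHH), relative EHH, and haplotype
  **bifurcation trees** with origin at the core variant;
* **genotype–phenotype association** (uncorrected Pearson χ² on the
  mode-appropriate 2×2 collapse) and **Hardy–Weinberg phenotype
  prediction** (q² recessive, 1−(1−q)² dominant);
* **capture-enrichment arithmetic** (theoretical per-sample coverage and
  fold enrichment);
* a **founder-sweep simulator** producing phased panels with background LD
  plus a derived class descended from a single founder, with ground truth
  for recovery tests — so the whole pipeline runs with no external data.

Definitions, in the field's standard notation: for `n` chromosomes in a
window of length `L` bp, `π = Σ_pairs d_ij / C(n,2) / L`; EHH at target
`t` for a core-allele class is `Σ_h C(c_h,2)/C(n,2)` over extended
haplotypes spanning core→t; relative EHH is the derived/ancestral ratio.
See `docs/methods.md` for conventions and the simulator model.

## Worked example

```python
import sweepwatch as sw

# simulate: 40 ancestral + 40 sweep-descended chromosomes, 500 kb, recessive
data = sw.emit_dataset(sw.SweepSimParams(seed=4), "scratch/demo")

hap = sw.read_phased_vcf(data["vcf"])
meta = sw.read_metadata(data["metadata"])
windows = sw.read_windows(data["windows"])
classing = sw.classify(hap, data["core"], meta)

profile = sw.diversity_profile(hap, windows, classing, by="chromosome_class")
wide = profile.pivot(index="window", columns="class", values="pi_percent")
print((wide["derived"] / wide["ancestral"]).round(3).to_string())
```

prints the derived/ancestral π ratio per window:

```
window
W01    0.810
W02    0.802
W03    0.769
W04    0.525
W05    0.165
W06    0.348
W07    0.669
W08    0.793
W09    0.924
```

The ratio collapses to 0.165 in W05 — the window containing the causal
site — and recovers toward 1 at the edges: the diversity trough a sweep
carves on derived chromosomes. The same dataset gives derived-class EHH
0.950 at ~10 kb from the core against 0.059 for ancestral chromosomes
(relative EHH ≈ 16), and the association stage reproduces the
perfect-association identity χ² = n.

The `examples/` scripts walk each capability (`01` simulator, `02`
association/HWE, `03` stratified π, `04` EHH/bifurcation, `05` capture
enrichment, `06` full pipeline); each prints its numbers with a note on
what they mean. A thin CLI mirrors the pipeline:

```bash
sweepwatch simulate --seed 1 --out demo/
sweepwatch scan --config scan.yaml
```

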