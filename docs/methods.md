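# Methods

`sweepwatch` implements the haplotype-based statistics used to detect a
selective sweep around a candidate causal variant in a small resequenced
population panel, together with a generative model that produces panels
with exactly the structure those statistics assume. This note records the
models, the conventions, and the design choices that were genuinely open.

## The analysis model

The substrate is a phased haplotype matrix: `2 x n_samples` chromosomes by
biallelic SNPs with physical positions, read from a phased VCF. One site is
designated the *core variant* — the putatively causal allele (here, a
melanism variant in a wild felid, but nothing is species-specific) with a
declared inheritance mode. Every chromosome is classed *derived* or
*ancestral* purely by its allele at the core; every individual is classed
by its recorded phenotype. A heterozygous individual therefore contributes
one chromosome to each allele class, while the phenotype stratification
keeps both of its chromosomes together — the latter is less sensitive to
the sweep but lets linked and unlinked loci be compared on the same
footing.

### Nucleotide diversity

For a window `[start, end)` (BED convention; site positions are 1-based
VCF coordinates, converted only at this boundary) and a chromosome set of
size `n`:

    pi = sum_{pairs} d_ij / C(n,2) / (end - start)

where `d_ij` counts differing sites of the pair inside the window. The
denominator is window length in bp, so monomorphic positions count
implicitly; this is the only convention that produces per-bp percentages
on the order of 0.02–0.06%, the empirical range for these panels. Window
lengths are taken exactly as supplied — if repeat-masked effective lengths
are wanted, the user supplies masked lengths (the package does not mask).
A per-variant-site denominator is exposed for debugging
(`denominator="sites"`).

The reported SEM is `sd(d_ij / length) / sqrt(C(n,2))` (sample sd, one
pair gives SEM 0). Pairs share chromosomes and are positively correlated,
so this understates true sampling error; it is the conventional error bar
for such figures, and the test suite never uses it for inference — the
neutral-null check instead uses the SEM across independent simulation
replicates, which is a valid standard error.

Classes with fewer than two chromosomes get NaN ("undefined"), never 0.

### EHH and bifurcation

EHH of an allele class at target site `t` is the probability that two
randomly drawn class chromosomes are identical at every site from the core
to `t` inclusive: `sum_h C(c_h,2)/C(n,2)` over extended-haplotype classes.
Including the core site makes EHH(core) exactly 1. EHH is evaluated at
observed sites only — the data are SNP-indexed, so no interpolation.
Relative EHH is derived/ancestral at the same site; where the ancestral
EHH has decayed to 0 the ratio is undefined (NaN, never 0 or inf) and the
first such position is recorded as the curve's truncation point.

The bifurcation tree refines the class chromosome set site by site away
from the core; node counts are branch thicknesses, child order is allele 0
before 1, and a non-splitting branch is extended with a single child
(membership preserved). Summing `C(c,2)/C(n,2)` over any tree level equals
the EHH at that depth — an internal-consistency identity the tests assert.
Tree depth is capped (default 30 sites) in pipeline output only, since the
full tree is O(class size x sites).

### Association and Hardy–Weinberg prediction

From a 2 phenotypes x 3 genotypes table: derived allele frequency
`q = (2 hom_der + het) / 2n`; predicted phenotype frequency `q^2`
(recessive) or `1 - (1-q)^2` (dominant); association is uncorrected
Pearson chi-square on a 2x2 collapse (derived homozygote vs rest under a
recessive model, carrier vs non-carrier under a dominant one). No
continuity correction and no exact test: for a perfectly associated 2x2
the uncorrected statistic equals the sample size n, which is precisely the
convention behind the published values 18 and 16 for the two recessive
panels (n = 18 and 16, fully concordant). The table used for the
chi-square is an explicit argument, distinct from the table used for
frequencies: the source data genotype one more pampas cat (of unknown
geographic origin) than the frequency table includes, and the package
takes both tables rather than guessing. Note the analogous dominant-panel
statistic printed as 16 in the source is not reproducible under this
convention (a perfectly associated 23-individual table gives 23); the
package documents rather than replicates that value. Rounding to two
decimals is report-layer only (`render_frequency`).

### Capture arithmetic

Theoretical per-sample coverage is
`reads x bp_per_read_pair / (n_samples x region_bp)` with 150 bp per pair
(75 bp aligned per end) by default; enrichment is the ratio of unrounded
coverages. Published tables of this kind mix truncation and rounding cell
by cell (0.79, 2051, 2564 are truncations; 492 is a rounding), so the
summary exposes both renderings of every cell and the math is never
rounded internally.

### Variant-density thinning

The upstream variant-calling practice this pipeline consumes retains ~1
variant per kb. `thin_variants` partitions a region into consecutive 1 kb
bins from a given origin and keeps the highest-quality site per bin (tie
or missing quality: smallest position). It is provided as an explicit
operation, not applied implicitly.

## The simulator

The generator produces the minimal structure the statistics respond to; it
is deliberately not a coalescent:

* **Ancestral class.** `k_founders` (default 8) founder haplotypes carry
  alleles i.i.d. Bernoulli(f_s) per site, f_s drawn from the neutral 1/i
  frequency spectrum (P(i) proportional to 1/i, f = i/k). Each ancestral
  chromosome is a Li–Stephens-style mosaic of the founders with per-bp
  template-switch probability `switch_rate` (default 5e-5, i.e. ~20 kb LD
  scale — short enough that ancestral EHH decays within a window, as the
  contrast requires). Site positions are uniform on the region (default
  L = 500 kb, the spatial scale of the observed sweep signal).
* **Derived class.** One ancestral chromosome is the sweep founder and
  carries the derived allele at the core (a dedicated column; the panel
  never places a site at the core position). Each derived chromosome
  copies the founder out to an Exponential(1/rG) breakpoint distance on
  each side of the core (single crossover per side, no gene conversion),
  copies one uniformly chosen ancestral chromosome beyond it, and gains
  Poisson(muG x L) private mutations at fresh positions (new columns, code
  0 in everyone else). `rG` and `muG` are compound rate-x-age parameters
  per bp — the species' sweep age and recombination rate are unknown, so
  these are free parameters, not calibrated to any taxon. Defaults
  rG = 5e-6 (mean breakpoint 200 kb) and muG = 2e-7.
* **Diversity level.** E[pi]/bp of the mosaic model has the closed form
  `n_sites x E[2 f (1-f)] (k-1)/k / L` (`expected_pi_per_bp`); the default
  n_sites = 760 puts it at ~0.045%/bp, the middle of the observed
  0.018–0.057% range, and a Monte Carlo test checks realized pi against
  the closed form within 3 SE.
* **Pairing.** Chromosomes are paired into diploids by explicit genotype
  counts (hom-ancestral, het, hom-derived) consistent with the class
  totals; phenotypes follow the inheritance mode (recessive: melanistic =
  derived homozygote; dominant: melanistic = carrier). The default split
  puts about half of the rarer class into heterozygotes. Windows default
  to 9 equal tiles of [0, L): an odd count so the central window is
  centred on the core — a causal variant sits inside its capture segment,
  not on an edge.

Everything is deterministic given the seed (separate child streams for the
ancestral and derived stages), and `emit_dataset` writes VCF + metadata +
BED + ground-truth JSON whose reload reproduces the truth object exactly.

**What the simulator does not emulate:** coalescent genealogies and their
variance, demography, gene conversion, mutation-rate heterogeneity,
genotyping/phasing error, ascertainment. Passing recovery tests therefore
demonstrates that the statistics read out the generative structure they
target (founder identity decaying as e^(-rG d), hence pairwise EHH
~ e^(-2 rG d)), not that they are calibrated for any real population.

## Numerical and interface conventions

* Coordinates: 0-based half-open internally and in BED; 1-based in
  VCF-facing types; conversion only at the boundary.
* Missing/unphased genotypes, multiallelic records and non-SNP alleles are
  hard errors naming the record — phasing and imputation belong upstream.
* Ploidy is fixed at 2; chromosome ids are `<sample>_A/_B`.
* Genotype/phenotype inconsistencies under the declared inheritance mode
  are reported by `classify` as violations, never dropped or repaired.
* Pipeline outputs are plain TSV/JSON written with fixed float formatting;
  two runs over the same inputs are byte-identical, and every run records
  a SHA-256 config hash.
* The chi-square requires non-degenerate margins; a degenerate collapse
  (e.g. a panel with no derived homozygotes) raises, and the pipeline
  reports NaN for that cell instead of failing the run.

## Test-suite problem sizes

The oracle checks fuzz 200 matrices of up to 12 chromosomes x 50 sites
against brute-force pair enumeration (and, for pi, the independent
allele-frequency identity `sum 2 p(1-p) n/(n-1) / L`). Simulation-based
checks use 10 replicates at 200 derived chromosomes for EHH slope recovery
(within 20% of 2 rG) and 20 replicates at the default 40+40 panel for
sweep detection (core-window derived/ancestral pi ratio < 0.2) and for the
neutral null (random 40/40 split of an 80-chromosome neutral panel; mean
per-window class difference within 3 cross-replicate SEM of zero). These
sizes give stable verdicts while keeping the whole suite in seconds.

## Known limitations

* The per-pair SEM is biased low (correlated pairs); use replicate-level
  error for inference.
* The simulator's mosaic LD has a single exponential scale; real LD decay
  is heterogeneous.
* Relative EHH depends on the ancestral class size; with few ancestral
  chromosomes it hits 0 (undefined ratio) quickly.
* `thin_variants` anchors bins at a caller-supplied origin; different
  origins can retain different sites near bin edges.
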