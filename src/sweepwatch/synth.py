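"""Founder-sweep haplotype simulator.

Generates phased panels with the two-class structure a sweep scan assumes:

* an *ancestral* class with background linkage disequilibrium, built as
  Li–Stephens-style mosaics of a small founder panel whose site frequencies
  follow the neutral 1/i spectrum;
* a *derived* class descended from a single founder chromosome that carries
  the derived allele at the core site, with exponentially distributed
  recombination breakpoints onto the ancestral panel on each side of the
  core and Poisson-distributed private new mutations.

The compound rates fold sweep age into per-bp intensities: ``rG`` is the
expected recombination breakpoints per bp since founding (so the unrecombined
fraction at distance d is e^(-rG d) and pairwise derived-class EHH decays
roughly as e^(-2 rG d)), and ``muG`` is expected new mutations per bp per
lineage. Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .hapio import (
    CoreVariant,
    HaplotypeMatrix,
    VariantSite,
    Window,
    WindowSet,
    write_phased_vcf,
)

_CONTIG = "chr1"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepSimParams:
    """Simulation parameters; defaults emulate the pampas-cat-like regime.

    L : window length in bp (500 kb, the scale of the observed sweep signal).
    core_pos : 1-based position of the causal site (window midpoint).
    n_anc, n_der : chromosomes per class (40 + 40, i.e. 40 diploids).
    n_sites : segregating sites in the ancestral panel; the default of 760
        puts expected per-bp diversity near 0.045% (see ``expected_pi_per_bp``).
    k_founders : founder haplotypes behind the ancestral mosaic.
    switch_rate : per-bp probability of switching copy template (ancestral
        LD length scale ~ 1/switch_rate = 20 kb).
    rG : recombination-rate x sweep-age, per bp.
    muG : mutation-rate x sweep-age, per bp per derived lineage.
    """

    L: int = 500_000
    core_pos: int = 250_000
    n_anc: int = 40
    n_der: int = 40
    n_sites: int = 760
    k_founders: int = 8
    switch_rate: float = 5e-5
    rG: float = 5e-6
    muG: float = 2e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.core_pos < self.L):
            raise ValueError("core_pos must lie strictly inside (0, L)")
        if self.n_der < 2:
            raise ValueError("n_der must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.k_founders < 1:
            raise ValueError("k_founders must be >= 1")
        if not (0.0 <= self.switch_rate <= 1.0):
            raise ValueError("switch_rate must be a per-bp probability in [0, 1]")
        if self.rG < 0 or self.muG < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SweepSimTruth:
    """Ground truth for recovery tests: founder, breakpoints, new mutations."""

    founder_haplotype: list[int]
    founder_index: int
    breakpoints: list[tuple[float, float]]  # (left_bp, right_bp) from core
    new_mutation_positions: list[list[int]]  # per derived chromosome
    params: SweepSimParams

    def to_json(self, path: str | Path) -> None:
        payload = {
            "founder_haplotype": self.founder_haplotype,
            "founder_index": self.founder_index,
            "breakpoints": [list(bp) for bp in self.breakpoints],
            "new_mutation_positions": self.new_mutation_positions,
            "params": asdict(self.params),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SweepSimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            founder_haplotype=[int(x) for x in payload["founder_haplotype"]],
            founder_index=int(payload["founder_index"]),
            breakpoints=[tuple(bp) for bp in payload["breakpoints"]],
            new_mutation_positions=[
                [int(p) for p in lst] for lst in payload["new_mutation_positions"]
            ],
            params=SweepSimParams(**payload["params"]),
        )


def _spectrum_frequencies(rng: np.random.Generator, n_sites: int, k: int) -> np.ndarray:
    """Founder-panel allele frequencies from the 1/i neutral spectrum."""
    if k == 1:
        # single founder: every "segregating" site is fixed ancestral
        return np.zeros(n_sites)
    i = np.arange(1, k)
    w = (1.0 / i) / np.sum(1.0 / i)
    counts = rng.choice(i, size=n_sites, p=w)
    return counts / k


def expected_pi_per_bp(params: SweepSimParams) -> float:
    """Closed-form E[pi]/bp of the ancestral mosaic model.

    At any site, two mosaic chromosomes copy independent uniform founders,
    so P(differ) = 2 m (k - m) / k^2 given m derived founders; in expectation
    over the Binomial(k, f) founder draw this is 2 f (1 - f) (k - 1) / k.
    """
    k = params.k_founders
    if k == 1:
        return 0.0
    i = np.arange(1, k)
    w = (1.0 / i) / np.sum(1.0 / i)
    f = i / k
    per_site = np.sum(w * 2.0 * f * (1.0 - f) * (k - 1) / k)
    return float(params.n_sites * per_site / params.L)


def _draw_positions(rng: np.random.Generator, params: SweepSimParams) -> np.ndarray:
    """Distinct integer site positions, uniform on [1, L], avoiding the core."""
    candidates = np.arange(1, params.L + 1)
    candidates = candidates[candidates != params.core_pos]
    if params.n_sites > candidates.size:
        raise ValueError("n_sites exceeds available positions")
    pos = rng.choice(candidates, size=params.n_sites, replace=False)
    pos.sort()
    return pos


def _alleles_for(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _make_sites(rng: np.random.Generator, positions: np.ndarray) -> list[VariantSite]:
    ref, alt = _alleles_for(rng, len(positions))
    return [
        VariantSite(_CONTIG, int(p), r, a)
        for p, r, a in zip(positions, ref, alt)
    ]


def simulate_ancestral_panel(params: SweepSimParams) -> HaplotypeMatrix:
    """Neutral-ish ancestral panel: founder haplotypes + mosaic copying.

    Deterministic given ``params.seed``. Positions are uniform on the window
    (the core position itself is kept free for the sweep class).
    """
    rng = np.random.default_rng([params.seed, 0])
    positions = _draw_positions(rng, params)
    sites = _make_sites(rng, positions)

    f = _spectrum_frequencies(rng, params.n_sites, params.k_founders)
    founders = (rng.random((params.k_founders, params.n_sites)) < f).astype(np.uint8)

    n, m, k = params.n_anc, params.n_sites, params.k_founders
    gaps = np.diff(positions)
    p_switch = 1.0 - np.power(1.0 - params.switch_rate, gaps)
    idx = np.empty((n, m), dtype=np.intp)
    idx[:, 0] = rng.integers(0, k, size=n)
    for j in range(1, m):
        switch = rng.random(n) < p_switch[j - 1]
        fresh = rng.integers(0, k, size=n)
        idx[:, j] = np.where(switch, fresh, idx[:, j - 1])
    data = founders[idx, np.arange(m)]

    ids = [f"anc{i:03d}" for i in range(n)]
    return HaplotypeMatrix(sites, data, ids)


def simulate_sweep_class(
    params: SweepSimParams, ancestral: HaplotypeMatrix
) -> tuple[HaplotypeMatrix, SweepSimTruth]:
    """Derived class descended from one founder chromosome.

    Each derived chromosome copies the founder out to an Exponential(rG)
    breakpoint distance on each side of the core, copies one uniformly
    chosen ancestral chromosome beyond each breakpoint, and gains
    Poisson(muG * L) private new mutations at fresh positions. Every
    derived chromosome carries the derived allele (code 1) at the core.
    """
    if ancestral.n_chrom == 0:
        raise ValueError("ancestral panel is empty")
    rng = np.random.default_rng([params.seed, 1])
    positions = ancestral.positions
    n_anc, m = ancestral.n_chrom, ancestral.n_sites

    founder_index = int(rng.integers(0, n_anc))
    founder = ancestral.data[founder_index].copy()

    scale = np.inf if params.rG == 0 else 1.0 / params.rG
    rows = np.empty((params.n_der, m), dtype=np.uint8)
    breakpoints: list[tuple[float, float]] = []
    for i in range(params.n_der):
        bl = float(rng.exponential(scale)) if np.isfinite(scale) else np.inf
        br = float(rng.exponential(scale)) if np.isfinite(scale) else np.inf
        row = founder.copy()
        left = positions < params.core_pos - bl
        right = positions > params.core_pos + br
        if left.any():
            row[left] = ancestral.data[int(rng.integers(0, n_anc)), left]
        if right.any():
            row[right] = ancestral.data[int(rng.integers(0, n_anc)), right]
        rows[i] = row
        breakpoints.append((bl, br))

    # private new mutations on the derived lineage, at fresh positions
    used = set(int(p) for p in positions) | {params.core_pos}
    new_positions: list[list[int]] = []
    all_new: list[tuple[int, int]] = []  # (pos, owner chromosome)
    for i in range(params.n_der):
        n_mut = int(rng.poisson(params.muG * params.L))
        mine: list[int] = []
        for _ in range(n_mut):
            p = int(rng.integers(1, params.L + 1))
            while p in used:
                p = int(rng.integers(1, params.L + 1))
            used.add(p)
            mine.append(p)
            all_new.append((p, i))
        new_positions.append(sorted(mine))

    # build the full (ancestral sites + core + new mutations) site list
    extra = [(params.core_pos, -1)] + all_new
    extra_sites: list[VariantSite] = []
    ref_e, alt_e = _alleles_for(rng, len(extra))
    for (p, _), r, a in zip(extra, ref_e, alt_e):
        extra_sites.append(VariantSite(_CONTIG, int(p), r, a))

    all_sites = list(ancestral.sites) + extra_sites
    order = np.argsort([s.pos for s in all_sites], kind="stable")
    all_sites = [all_sites[j] for j in order]

    full = np.zeros((params.n_der, m + len(extra)), dtype=np.uint8)
    full[:, :m] = rows
    full[:, m] = 1  # derived allele at core, all derived chromosomes
    for col, (_, owner) in enumerate(all_new, start=m + 1):
        full[owner, col] = 1
    full = full[:, order]

    ids = [f"der{i:03d}" for i in range(params.n_der)]
    derived = HaplotypeMatrix(all_sites, full, ids)

    core_col = int(np.searchsorted(positions, params.core_pos))
    founder_with_core = np.insert(founder, core_col, 1)
    truth = SweepSimTruth(
        founder_haplotype=[int(x) for x in founder_with_core],
        founder_index=founder_index,
        breakpoints=breakpoints,
        new_mutation_positions=new_positions,
        params=params,
    )
    return derived, truth


def merge_panels(
    ancestral: HaplotypeMatrix, derived: HaplotypeMatrix
) -> HaplotypeMatrix:
    """Union of the two panels; ancestral chromosomes carry code 0 at sites
    private to the derived class (the core and new mutations)."""
    anc_pos = {(s.chrom, s.pos) for s in ancestral.sites}
    for s in ancestral.sites:
        if (s.chrom, s.pos) not in {(t.chrom, t.pos) for t in derived.sites}:
            raise ValueError("derived panel must contain all ancestral sites")
    n_total = derived.n_chrom + ancestral.n_chrom
    data = np.zeros((n_total, derived.n_sites), dtype=np.uint8)
    data[: derived.n_chrom] = derived.data
    anc_cols = [
        j for j, s in enumerate(derived.sites) if (s.chrom, s.pos) in anc_pos
    ]
    data[derived.n_chrom :, anc_cols] = ancestral.data
    return HaplotypeMatrix(
        derived.sites, data, list(derived.chrom_ids) + list(ancestral.chrom_ids)
    )


def _default_genotype_counts(n_anc: int, n_der: int) -> tuple[int, int, int]:
    """(hom_ancestral, het, hom_derived) individual counts pairing all
    chromosomes into a mixture: about half of the rarer class's chromosomes
    end up in heterozygotes (parity-adjusted so everything pairs)."""
    if (n_anc + n_der) % 2:
        raise ValueError("total chromosome count must be even to form diploids")
    n_het = min(n_anc, n_der) // 2
    if (n_der - n_het) % 2:
        n_het -= 1 if n_het > 0 else -1
    return (n_anc - n_het) // 2, n_het, (n_der - n_het) // 2


def pair_into_individuals(
    merged: HaplotypeMatrix,
    n_der: int,
    mode: str,
    genotype_counts: tuple[int, int, int] | None = None,
) -> tuple[HaplotypeMatrix, list[tuple[str, str]]]:
    """Pair class chromosomes into diploid individuals.

    ``merged`` must hold the derived chromosomes first (as produced by
    :func:`merge_panels`). ``genotype_counts`` is (hom_ancestral, het,
    hom_derived); phenotypes follow the inheritance mode (recessive:
    melanistic = derived homozygote; dominant: melanistic = carrier).
    Returns the re-ordered matrix with ``<sample>_<A|B>`` ids and a list of
    (sample_id, phenotype).
    """
    n_anc = merged.n_chrom - n_der
    if genotype_counts is None:
        genotype_counts = _default_genotype_counts(n_anc, n_der)
    n_aa, n_het, n_dd = genotype_counts
    if 2 * n_dd + n_het != n_der or 2 * n_aa + n_het != n_anc:
        raise ValueError(
            f"cannot pair {n_der} derived + {n_anc} ancestral chromosomes into "
            f"genotype counts (hom_anc={n_aa}, het={n_het}, hom_der={n_dd})"
        )
    der_rows = list(range(n_der))
    anc_rows = list(range(n_der, merged.n_chrom))
    order: list[int] = []
    phenos: list[tuple[str, str]] = []
    genotypes = ["dd"] * n_dd + ["da"] * n_het + ["aa"] * n_aa
    for i, g in enumerate(genotypes):
        sid = f"S{i + 1:03d}"
        if g == "dd":
            order += [der_rows.pop(0), der_rows.pop(0)]
            melanistic = True
        elif g == "da":
            order += [der_rows.pop(0), anc_rows.pop(0)]
            melanistic = mode == "dominant"
        else:
            order += [anc_rows.pop(0), anc_rows.pop(0)]
            melanistic = False
        phenos.append((sid, "melanistic" if melanistic else "non_melanistic"))
    reordered = merged.data[np.asarray(order, dtype=np.intp)]
    ids = [f"{sid}_{h}" for sid, _ in phenos for h in ("A", "B")]
    return HaplotypeMatrix(merged.sites, reordered, ids), phenos


def default_windows(params: SweepSimParams, n_windows: int = 9) -> WindowSet:
    """Equal-width windows tiling [0, L), labelled W01..Wnn.

    The default is odd so that the middle window is centred on the core
    position (the causal site sits inside its window, not on an edge, as a
    causal variant sits inside its capture segment)."""
    edges = np.linspace(0, params.L, n_windows + 1).astype(int)
    return WindowSet(
        tuple(
            Window(f"W{i + 1:02d}", _CONTIG, int(a), int(b))
            for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
        )
    )


def emit_dataset(
    params: SweepSimParams,
    out_dir: str | Path,
    mode: str = "recessive",
    genotype_counts: tuple[int, int, int] | None = None,
    n_windows: int = 9,
    species: str = "synthetic",
) -> dict:
    """Simulate a full dataset and write VCF + metadata TSV + BED + truth JSON.

    Returns a dict with the file paths, the paired matrix, the core variant
    and the ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ancestral = simulate_ancestral_panel(params)
    derived, truth = simulate_sweep_class(params, ancestral)
    merged = merge_panels(ancestral, derived)
    paired, phenos = pair_into_individuals(
        merged, params.n_der, mode, genotype_counts
    )
    core = CoreVariant(
        _CONTIG, params.core_pos, derived_allele_code=1, mode=mode,
        name="sim core",
    )
    windows = default_windows(params, n_windows)

    vcf_path = out_dir / "panel.vcf"
    write_phased_vcf(vcf_path, paired)
    meta_path = out_dir / "samples.tsv"
    meta_lines = ["sample_id\tspecies\tphenotype"] + [
        f"{sid}\t{species}\t{ph}" for sid, ph in phenos
    ]
    meta_path.write_text("\n".join(meta_lines) + "\n")
    bed_path = out_dir / "windows.bed"
    bed_path.write_text(
        "".join(f"{w.chrom}\t{w.start}\t{w.end}\t{w.label}\n" for w in windows)
    )
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)

    return {
        "vcf": vcf_path,
        "metadata": meta_path,
        "windows": bed_path,
        "truth": truth_path,
        "matrix": paired,
        "core": core,
        "truth_obj": truth,
        "window_set": windows,
    }
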