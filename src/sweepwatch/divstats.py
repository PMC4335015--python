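"""Windowed nucleotide diversity, haplotype counts, and density thinning.

Nucleotide diversity pi is the mean per-site pairwise difference among a
set of chromosomes over a window:

    pi = sum over unordered pairs of differing-site counts / C(n, 2) / D

where the denominator D defaults to the window length in bp, so monomorphic
positions are counted implicitly and the values land on the per-bp scale
reported as small percentages (~0.02-0.06%). A per-variant-site denominator
is available for debugging (``denominator="sites"``).

SEM is the standard deviation of the per-pair per-site differences divided
by sqrt(C(n, 2)). Pairs are not independent, so this understates true
sampling error; it is a display quantity, matching the error bars the
figures carry, not a basis for formal inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix, VariantSite, Window, WindowSet


class PiResult(NamedTuple):
    pi: float
    sem: float
    n_pairs: int
    n_sites: int


@dataclass
class ChromosomeClassing:
    """Class labels for every chromosome (by core allele) and every
    individual (by phenotype), plus any genotype/phenotype inconsistencies
    found under the inheritance mode."""

    chromosome_class: dict[str, str]  # chrom_id -> derived | ancestral
    individual_class: dict[str, str]  # sample_id -> melanistic | non_melanistic
    violations: list[str]

    def chromosomes_in(self, hap: HaplotypeMatrix, cls: str) -> np.ndarray:
        return np.array(
            [i for i, cid in enumerate(hap.chrom_ids)
             if self.chromosome_class[cid] == cls],
            dtype=np.intp,
        )

    def chromosomes_of_phenotype(self, hap: HaplotypeMatrix, phenotype: str) -> np.ndarray:
        return np.array(
            [i for i, cid in enumerate(hap.chrom_ids)
             if self.individual_class[hap.sample_of(cid)] == phenotype],
            dtype=np.intp,
        )


def _pairwise_differences(X: np.ndarray) -> np.ndarray:
    """Upper-triangle vector of pairwise differing-site counts."""
    X = X.astype(np.int64)
    D = X @ (1 - X).T + (1 - X) @ X.T
    iu = np.triu_indices(X.shape[0], k=1)
    return D[iu]


def nucleotide_diversity(
    hap: HaplotypeMatrix,
    window: Window,
    chrom_subset: Sequence[int],
    denominator: str = "bp",
) -> PiResult:
    """Pairwise nucleotide diversity of ``chrom_subset`` within ``window``."""
    rows = np.asarray(chrom_subset, dtype=np.intp)
    if rows.size < 2:
        raise ValueError(
            f"need at least 2 chromosomes for pi, got {rows.size}"
        )
    if window.length <= 0:
        raise ValueError(f"window {window.label} has zero length")
    mask = hap.window_site_mask(window)
    n_sites = int(mask.sum())
    X = hap.data[np.ix_(rows, np.flatnonzero(mask))]
    diffs = _pairwise_differences(X)
    if denominator == "bp":
        denom = float(window.length)
    elif denominator == "sites":
        denom = float(max(n_sites, 1))
    else:
        raise ValueError("denominator must be 'bp' or 'sites'")
    per_pair = diffs / denom
    pi = float(per_pair.mean())
    n_pairs = per_pair.size
    sem = (
        float(per_pair.std(ddof=1) / math.sqrt(n_pairs)) if n_pairs > 1 else 0.0
    )
    return PiResult(pi, sem, n_pairs, n_sites)


def diversity_profile(
    hap: HaplotypeMatrix,
    windows: WindowSet,
    classing: ChromosomeClassing,
    by: str = "chromosome_class",
    denominator: str = "bp",
) -> pd.DataFrame:
    """Per-window pi for each class under one of the two stratifications.

    ``by="chromosome_class"`` contrasts derived vs ancestral chromosomes
    (heterozygous individuals contribute one chromosome to each class);
    ``by="individual_class"`` contrasts both chromosomes of melanistic vs
    non-melanistic individuals. Classes with fewer than 2 chromosomes get
    NaN (undefined), never 0.
    """
    if by == "chromosome_class":
        groups = {
            cls: classing.chromosomes_in(hap, cls)
            for cls in ("derived", "ancestral")
        }
    elif by == "individual_class":
        groups = {
            ph: classing.chromosomes_of_phenotype(hap, ph)
            for ph in ("melanistic", "non_melanistic")
        }
    else:
        raise ValueError(
            "by must be 'chromosome_class' or 'individual_class'"
        )
    records = []
    for w in windows:
        for cls, rows in groups.items():
            if rows.size >= 2:
                r = nucleotide_diversity(hap, w, rows, denominator=denominator)
                pi, sem, n_sites = r.pi, r.sem, r.n_sites
            else:
                pi, sem = float("nan"), float("nan")
                n_sites = int(hap.window_site_mask(w).sum())
            records.append(
                {
                    "window": w.label,
                    "class": cls,
                    "n_chrom": int(rows.size),
                    "pi": pi,
                    "pi_percent": pi * 100.0,
                    "sem": sem,
                    "n_sites": n_sites,
                }
            )
    return pd.DataFrame.from_records(records)


def haplotype_count(
    hap: HaplotypeMatrix, window: Window, chrom_subset: Sequence[int]
) -> int:
    """Number of distinct allele strings over the window's sites.

    A window with no sites holds a single (empty) haplotype by convention.
    """
    rows = np.asarray(chrom_subset, dtype=np.intp)
    if rows.size == 0:
        raise ValueError("empty chromosome subset")
    mask = hap.window_site_mask(window)
    if not mask.any():
        return 1
    X = hap.data[np.ix_(rows, np.flatnonzero(mask))]
    return int(np.unique(X, axis=0).shape[0])


def thin_variants(
    sites: Sequence[VariantSite], bin_bp: int = 1000, origin: int = 0
) -> list[VariantSite]:
    """Density filter: one site per ``bin_bp`` bin, keeping the highest
    quality (ties and missing quality resolve to the smallest position).

    Bins are consecutive from ``origin`` (a window start, 0-based); input
    must be position-sorted within one contig.
    """
    best: dict[tuple[str, int], VariantSite] = {}
    prev = None
    for s in sites:
        if prev is not None and (s.chrom, s.pos) < prev:
            raise ValueError("sites must be sorted by (chrom, pos)")
        prev = (s.chrom, s.pos)
        b = (s.chrom, (s.pos - 1 - origin) // bin_bp)
        cur = best.get(b)
        if cur is None:
            best[b] = s
            continue
        q_new = -math.inf if s.quality is None else s.quality
        q_cur = -math.inf if cur.quality is None else cur.quality
        if q_new > q_cur:
            best[b] = s  # strict improvement only: ties keep smaller pos
    return sorted(best.values(), key=lambda s: (s.chrom, s.pos))
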